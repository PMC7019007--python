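"""Resolution matching between modalities.

A high-resolution tomogram (µm-scale) must be brought to the grid of the
low-resolution MRI-derived map (~125 µm) before registration.  Two routes are
provided: anti-aliased (Gaussian low-pass + trilinear) down-sampling and
volumetric nearest-neighbour down-sampling, plus percentile intensity
saturation and a data-driven selection of the down-sampling factor that
maximizes the image gradient at the sample–medium interface.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .core import BinaryMask, Volume

__all__ = [
    "saturate_intensity",
    "antialias_downsample",
    "nn_downsample",
    "interface_gradient_score",
    "select_downsample_scale",
]


def saturate_intensity(
    volume: Volume, lower_frac: float = 0.003, upper_frac: float = 0.003
) -> Volume:
    """Clip intensities at the lower/upper fractional quantiles (nearest rank).

    With the defaults the top and bottom 0.3 % of voxel values are saturated
    to the respective quantile value.  Idempotent at fixed fractions.
    """
    if not (0 <= lower_frac < 0.5 and 0 <= upper_frac < 0.5):
        raise ValueError("fractions must lie in [0, 0.5)")
    data = volume.data
    if lower_frac == 0 and upper_frac == 0:
        return volume.copy()
    sorted_vals = np.sort(data.ravel())
    n = sorted_vals.size
    # nearest-rank quantile: with k = ceil(frac * n), the k lowest (highest)
    # values are clipped to the (k+1)-th order statistic
    lo_k = int(np.ceil(lower_frac * n))
    hi_k = int(np.ceil(upper_frac * n))
    lo_q = sorted_vals[min(lo_k, n - 1)]
    hi_q = sorted_vals[max(n - 1 - hi_k, 0)]
    out = np.clip(data, lo_q if lower_frac > 0 else -np.inf, hi_q if upper_frac > 0 else np.inf)
    return volume.with_data(out)


def _target_grid_shape(vol: Volume, target_spacing: np.ndarray) -> tuple[int, ...]:
    # keep the world extent: last voxel centre must not exceed the source extent
    extent = (np.array(vol.shape) - 1) * vol.spacing
    return tuple(int(np.floor(extent[a] / target_spacing[a])) + 1 for a in range(3))


def antialias_downsample(volume: Volume, target_spacing) -> Volume:
    """Gaussian low-pass then trilinear resampling onto a coarser grid.

    The per-axis Gaussian sigma is ``factor / 2`` source voxels with
    ``factor = target_spacing / source_spacing`` (filter cutoff near the new
    Nyquist limit).  The world position of voxel (0,0,0) is preserved.
    """
    target_spacing = np.atleast_1d(np.asarray(target_spacing, dtype=float))
    if target_spacing.size == 1:
        target_spacing = np.repeat(target_spacing, 3)
    factors = target_spacing / volume.spacing
    if np.any(factors < 1 - 1e-9):
        raise ValueError(
            f"target spacing {target_spacing} finer than source {volume.spacing}; "
            "this operation only down-samples"
        )
    sigma = factors / 2.0
    smoothed = ndi.gaussian_filter(volume.data, sigma=sigma, mode="nearest")
    new_shape = _target_grid_shape(volume, target_spacing)
    idx = np.meshgrid(
        *[np.arange(new_shape[a]) * factors[a] for a in range(3)], indexing="ij"
    )
    out = ndi.map_coordinates(smoothed, np.stack(idx), order=1, mode="nearest")
    return Volume(out, spacing=target_spacing, origin=volume.origin.copy())


def nn_downsample(volume: Volume, factor) -> Volume:
    """Volumetric nearest-neighbour down-sampling by an integer factor per axis.

    Output voxel ``(i, j, k)`` takes the value of the nearest source voxel to
    its centre; with the package's voxel-centre convention that source voxel is
    exactly ``(i·fx, j·fy, k·fz)``.  No new intensity values are created.
    """
    factor = np.atleast_1d(np.asarray(factor))
    if factor.size == 1:
        factor = np.repeat(factor, 3)
    if factor.size != 3 or np.any(factor != np.round(factor)) or np.any(factor < 1):
        raise ValueError(
            f"factor must be integer >= 1 per axis (got {factor}); "
            "use antialias_downsample for fractional factors"
        )
    f = factor.astype(int)
    out = volume.data[:: f[0], :: f[1], :: f[2]].copy()
    return Volume(out, spacing=volume.spacing * f, origin=volume.origin.copy())


def interface_gradient_score(
    volume: Volume, interface_band: BinaryMask, slices: list[int]
) -> float:
    """Mean central-difference gradient magnitude over a band on selected xy-slices.

    Used to judge how sharply a down-sampled volume preserves the
    sample–medium interface: higher is sharper.
    """
    if volume.shape != interface_band.shape:
        raise ValueError("volume and band must share a grid")
    slices = [int(z) for z in slices]
    for z in slices:
        if not 0 <= z < volume.shape[2]:
            raise ValueError(f"slice index {z} out of range for shape {volume.shape}")
    sel = np.zeros(volume.shape, dtype=bool)
    sel[:, :, slices] = True
    sel &= interface_band.data
    if not sel.any():
        raise ValueError("interface band is empty on all listed slices")
    grads = np.gradient(volume.data)  # central differences, intensity per voxel
    mag = np.sqrt(sum(g**2 for g in grads))
    return float(mag[sel].mean())


def select_downsample_scale(
    volume: Volume,
    candidate_factors: list[int],
    interface_band: BinaryMask,
    slices: list[int],
) -> int:
    """Pick the NN down-sampling factor maximizing the interface gradient score.

    Each candidate factor is applied to both the volume and the band (band by
    NN as well, slice indices divided accordingly); ties break toward the
    smaller factor.
    """
    if len(candidate_factors) < 2:
        raise ValueError("need at least 2 candidate factors")
    best_factor = None
    best_score = -np.inf
    for f in sorted(set(int(c) for c in candidate_factors)):
        down = nn_downsample(volume, f)
        band_down = nn_downsample(interface_band.to_volume(), f)
        band_mask = BinaryMask.like(down, band_down.data > 0.5)
        zs = sorted(set(z // f for z in slices if z // f < down.shape[2]))
        score = interface_gradient_score(down, band_mask, zs)
        if score > best_score + 1e-12:
            best_score = score
            best_factor = f
    assert best_factor is not None
    return best_factor
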
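"""Foreground masking for high-resolution tomography volumes.

Phase-contrast tomograms show alternating bright/dark ring artifacts at the
sample–medium interface, so a single intensity threshold cannot isolate the
sample.  The recipe implemented here builds an outline mask from a *bimodal*
threshold (everything outside the medium-intensity band, which catches tissue
plus both ring polarities), closes it morphologically, fills in-slice holes,
erodes until exterior debris disappears, and re-dilates to restore the margin.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import ball

from .core import BinaryMask, DegenerateInputError, Volume

__all__ = [
    "threshold_otsu",
    "bimodal_foreground",
    "auto_band",
    "dilate_ball",
    "erode_ball",
    "fill_holes_2d",
    "erode_until_single_component",
    "keep_largest_component",
    "brain_mask_pipeline",
    "ErosionCollapseError",
]

#: 26-connectivity structuring element for 3D component labelling
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class ErosionCollapseError(RuntimeError):
    """The mask vanished before reaching a single connected component."""

    def __init__(self, last_nonempty_iteration: int):
        self.last_nonempty_iteration = last_nonempty_iteration
        super().__init__(
            f"mask vanished during erosion; last non-empty iteration was "
            f"{last_nonempty_iteration}"
        )


def threshold_otsu(volume: Volume | np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold of a volume over a 256-bin histogram of finite values.

    Returns the threshold (a bin centre, on the original intensity scale) that
    maximizes the between-class variance, with values ≤ threshold in the lower
    class.  When several splits maximize the variance — which happens whenever
    the histogram has an empty gap between the two modes — the *middle* of the
    maximizing plateau is returned, so binarizing the raw values at the
    threshold actually separates the modes (a first-maximizer convention can
    sit inside the lower mode's bin).

    Raises
    ------
    DegenerateInputError
        If the volume is constant (no threshold can separate two classes).
    """
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume)
    vals = data[np.isfinite(data)].ravel()
    if vals.size == 0 or vals.min() == vals.max():
        raise DegenerateInputError("constant volume: Otsu threshold undefined")
    hist, edges = np.histogram(vals, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    p = hist.astype(float) / hist.sum()
    w0 = np.cumsum(p)
    mu0 = np.cumsum(p * centers)
    mu_t = mu0[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma_b = (mu_t * w0 - mu0) ** 2 / (w0 * (1.0 - w0))
    sigma_b = sigma_b[:-1]  # a split must leave both classes non-empty
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    best = np.flatnonzero(sigma_b >= sigma_b.max() - 1e-12 * abs(sigma_b.max()))
    return float(centers[best[len(best) // 2]])


def bimodal_foreground(volume: Volume, band: tuple[float, float]) -> BinaryMask:
    """Mask of voxels *outside* the medium-intensity band ``(low, high)``.

    Selects ``intensity < low`` OR ``intensity > high`` so that the tissue and
    both ring-artifact polarities land in the mask while the embedding medium
    does not.  An empty result is returned (not raised) with a provenance flag
    so callers can warn.
    """
    low, high = band
    if not low < high:
        raise ValueError(f"band must satisfy low < high, got {band}")
    data = volume.data
    mask = (data < low) | (data > high)
    prov = f"bimodal_foreground(band=({low!r},{high!r}))"
    if not mask.any():
        prov += " [EMPTY]"
    return BinaryMask.like(volume, mask, provenance=prov)


def auto_band(volume: Volume) -> tuple[float, float]:
    """Derive a medium-intensity band from a two-stage Otsu analysis.

    The global Otsu threshold ``t`` separates the medium from the tissue-and-
    brighter class; a second Otsu restricted to the sub-threshold values
    separates dark artifacts from the medium and gives the lower band edge.
    When the sub-threshold values are (nearly) constant there is no dark class
    and the band degenerates to plain Otsu foreground (``low`` below the data
    minimum).
    """
    t = threshold_otsu(volume)
    below = volume.data[volume.data <= t]
    low = float(volume.data.min()) - 1.0
    if below.size > 0 and below.min() != below.max():
        cand = threshold_otsu(below)
        # a genuine dark-artifact class sits below the medium peak; when the
        # sub-threshold distribution is just the medium plus a partial-volume
        # tail, its Otsu split lands above the peak and must be rejected
        hist, edges = np.histogram(below, bins=256)
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        if cand < mode:
            low = cand
    return (low, t)


def _check_radius(radius: int) -> int:
    if radius < 0 or int(radius) != radius:
        raise ValueError(f"radius must be a non-negative integer, got {radius}")
    return int(radius)


def dilate_ball(mask: BinaryMask, radius: int) -> BinaryMask:
    """Morphological dilation with a discrete Euclidean ball (||v||₂ ≤ radius)."""
    radius = _check_radius(radius)
    if radius == 0:
        return mask.copy()
    out = ndi.binary_dilation(mask.data, structure=ball(radius))
    return BinaryMask.like(mask, out, provenance=f"dilate_ball(r={radius})")


def erode_ball(mask: BinaryMask, radius: int) -> BinaryMask:
    """Morphological erosion with a discrete Euclidean ball; dual of dilation."""
    radius = _check_radius(radius)
    if radius == 0:
        return mask.copy()
    out = ndi.binary_erosion(mask.data, structure=ball(radius), border_value=0)
    return BinaryMask.like(mask, out, provenance=f"erode_ball(r={radius})")


def fill_holes_2d(mask: BinaryMask, slice_axis: int = 2) -> BinaryMask:
    """Per-slice 2D hole filling along ``slice_axis`` (4-connected background).

    Background regions of a slice not reachable from the slice border become
    foreground; slices are processed independently, so a tunnel that is open
    only at the volume's top/bottom faces still gets filled (unlike 3D filling
    from the volume border).
    """
    if slice_axis not in (0, 1, 2):
        raise ValueError(f"slice_axis must be 0, 1 or 2, got {slice_axis}")
    data = np.moveaxis(mask.data.copy(), slice_axis, 0)
    for z in range(data.shape[0]):
        data[z] = ndi.binary_fill_holes(data[z])
    out = np.moveaxis(data, 0, slice_axis)
    return BinaryMask.like(mask, out, provenance=f"fill_holes_2d(axis={slice_axis})")


def _n_components(data: np.ndarray) -> int:
    return ndi.label(data, structure=STRUCT_26)[1]


def erode_until_single_component(
    mask: BinaryMask, radius: int = 2
) -> tuple[BinaryMask, int]:
    """Erode with ``ball(radius)`` until exactly one 26-connected component remains.

    Returns the eroded mask and the number of erosion iterations performed
    (needed to size the matching re-dilation).

    Raises
    ------
    ErosionCollapseError
        If the mask becomes empty before reaching a single component.
    """
    radius = _check_radius(max(radius, 1))
    if mask.is_empty():
        raise ValueError("cannot erode an empty mask to a single component")
    current = mask.data.copy()
    n_iter = 0
    while _n_components(current) != 1:
        nxt = ndi.binary_erosion(current, structure=ball(radius), border_value=0)
        n_iter += 1
        if not nxt.any():
            raise ErosionCollapseError(last_nonempty_iteration=n_iter - 1)
        current = nxt
    out = BinaryMask.like(mask, current, provenance=f"erode_until_single(r={radius}, n={n_iter})")
    return out, n_iter


def keep_largest_component(mask: BinaryMask) -> BinaryMask:
    """Keep only the largest 26-connected component."""
    labels, n = ndi.label(mask.data, structure=STRUCT_26)
    if n <= 1:
        return mask.copy()
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    out = labels == int(np.argmax(counts))
    return BinaryMask.like(mask, out, provenance="keep_largest_component")


def brain_mask_pipeline(
    volume: Volume,
    band: tuple[float, float] | str = "auto",
    dilate_radius: int = 2,
) -> BinaryMask:
    """Full sample-outline masking recipe for an artifact-bearing volume.

    Composition: bimodal threshold → dilation (ball ``dilate_radius``) →
    per-slice hole filling → erosion until a single component → largest
    component → re-dilation by ``dilate_radius × (1 + n_erosions)`` intersected
    with the hole-filled pre-dilation support, with a final in-slice hole fill
    so the output is one connected, hole-free component.

    ``band="auto"`` derives the medium band via :func:`auto_band`.
    """
    if isinstance(band, str):
        if band != "auto":
            raise ValueError(f"band must be a (low, high) pair or 'auto', got {band!r}")
        band = auto_band(volume)
    initial = bimodal_foreground(volume, band)
    if initial.is_empty():
        raise DegenerateInputError("bimodal threshold selected no voxels")
    support = fill_holes_2d(initial)
    dilated = dilate_ball(initial, dilate_radius)
    filled = fill_holes_2d(dilated)
    eroded, n_iter = erode_until_single_component(filled, radius=dilate_radius)
    core = keep_largest_component(eroded)
    restored = dilate_ball(core, dilate_radius * (1 + n_iter))
    combined = BinaryMask.like(
        volume, restored.data & support.data, provenance="brain_mask_pipeline"
    )
    final = keep_largest_component(fill_holes_2d(combined))
    final.provenance = (
        f"brain_mask_pipeline(band=({band[0]:.6g},{band[1]:.6g}), "
        f"radius={dilate_radius}, n_erosions={n_iter})"
    )
    return final
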
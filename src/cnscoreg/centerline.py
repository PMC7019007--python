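"""Spinal-cord centerline and mask extraction from a high-resolution volume.

The cord's position is recovered from its contours: a 3D two-threshold
(hysteresis) edge detector marks the tissue–medium interface, then either

* the per-slice centre of mass of the contour voxels yields the centerline
  directly (``com`` route), or
* 3D seeded region growing inside the edge shell yields a binary cord mask
  (``grow`` route), whose per-slice centroids give the centerline.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .core import BinaryMask, Centerline, Volume, moving_average_polyline
from .masking import STRUCT_26, threshold_otsu

__all__ = [
    "detect_edges_3d",
    "centerline_from_slices",
    "region_grow_mask",
    "resample_centerline",
]

#: 6-connectivity structuring element (face neighbours only)
STRUCT_6 = ndi.generate_binary_structure(3, 1)


def detect_edges_3d(
    volume: Volume,
    sigma: float,
    low_thr: float | str = "auto",
    high_thr: float | str = "auto",
) -> BinaryMask:
    """3D edge detection with two thresholds for strong and weak edges.

    The gradient magnitude of the Gaussian-smoothed volume (``sigma`` in µm,
    converted per axis to voxels) is thresholded twice: voxels above
    ``high_thr`` are strong edges; voxels between the thresholds are weak and
    are kept only when 26-connected to a strong voxel (hysteresis linking).
    Thresholds are fractions of the maximal gradient magnitude; ``"auto"``
    sets the high threshold from Otsu's method on the gradient magnitude and
    the low one to 0.4 × high.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0 µm")
    sigma_vox = sigma / volume.spacing
    gm = ndi.gaussian_gradient_magnitude(volume.data, sigma=sigma_vox, mode="nearest")
    gmax = float(gm.max())
    if gmax == 0.0:
        return BinaryMask.like(volume, np.zeros(volume.shape, bool), "detect_edges_3d")
    if high_thr == "auto":
        high_val = threshold_otsu(gm)
    else:
        high_val = float(high_thr) * gmax
    if low_thr == "auto":
        low_val = 0.4 * high_val
    else:
        low_val = float(low_thr) * gmax
    if low_val > high_val:
        raise ValueError(f"low threshold {low_val:.4g} exceeds high {high_val:.4g}")
    strong = gm > high_val
    weak = gm > low_val
    labels, _ = ndi.label(weak, structure=STRUCT_26)
    keep = np.unique(labels[strong])
    keep = keep[keep > 0]
    edges = np.isin(labels, keep)
    return BinaryMask.like(volume, edges, provenance=f"detect_edges_3d(sigma={sigma})")


def centerline_from_slices(
    contours: BinaryMask,
    smooth_window: int = 5,
    slice_axis: int = 2,
    min_count_frac: float = 0.5,
) -> Centerline:
    """Centerline from per-slice centroids of contour voxels.

    For every slice along ``slice_axis`` with a non-empty contour the sample
    is the (unweighted) centroid of the contour voxels, in world coordinates;
    empty slices are skipped, as are slices whose contour holds fewer than
    ``min_count_frac`` × the median per-slice count (a sliver of a contour —
    e.g. the blurred rim of the sample's end face — has a meaningless
    centroid).  The raw polyline is then smoothed with a centred moving
    average (default window 5 samples).
    """
    if slice_axis not in (0, 1, 2):
        raise ValueError(f"slice_axis must be 0, 1 or 2, got {slice_axis}")
    data = np.moveaxis(contours.data, slice_axis, 2)
    in_plane = [a for a in range(3) if a != slice_axis]
    counts = data.sum(axis=(0, 1))
    nonempty = counts > 0
    if nonempty.sum() >= 2 and min_count_frac > 0:
        cutoff = min_count_frac * np.median(counts[nonempty])
    else:
        cutoff = 0.0
    pts = []
    for z in range(data.shape[2]):
        sl = data[:, :, z]
        if counts[z] == 0 or counts[z] < cutoff:
            continue
        ij = np.argwhere(sl).mean(axis=0)
        idx = np.empty(3)
        idx[in_plane] = ij
        idx[slice_axis] = z
        pts.append(idx)
    if len(pts) < 2:
        raise ValueError("need contour voxels on at least 2 slices")
    pts = contours.index_to_world(np.asarray(pts))
    smoothed = moving_average_polyline(pts, smooth_window)
    return Centerline(smoothed)


def region_grow_mask(
    edges: BinaryMask, seed: tuple[int, int, int], closing_radius: int = 1
) -> BinaryMask:
    """3D seeded region growing of the non-edge space containing ``seed``.

    The mask is the 6-connected component of non-edge voxels containing the
    seed (edge voxels themselves are excluded), morphologically closed with a
    ball of radius 1 to absorb the edge shell.  6-connectivity prevents the
    growth from leaking diagonally through one-voxel-thick edge shells.
    """
    seed = tuple(int(s) for s in seed)
    if len(seed) != 3 or any(not 0 <= seed[a] < edges.shape[a] for a in range(3)):
        raise ValueError(f"seed {seed} outside grid {edges.shape}")
    if edges.data[seed]:
        raise ValueError(f"seed {seed} lies on an edge voxel")
    labels, _ = ndi.label(~edges.data, structure=STRUCT_6)
    region = labels == labels[seed]
    if closing_radius > 0:
        from skimage.morphology import ball

        region = ndi.binary_closing(region, structure=ball(closing_radius))
    return BinaryMask.like(edges, region, provenance=f"region_grow_mask(seed={seed})")


def find_interior_seeds(
    edges: BinaryMask,
    near_world: np.ndarray,
    search_radius_vox: int = 15,
    n_candidates: int = 5,
) -> list[tuple[int, int, int]]:
    """Candidate region-growing seeds near a point, deepest-inside-first.

    Within a ball of ``search_radius_vox`` voxels around ``near_world``,
    non-edge voxels are ranked by their Euclidean distance to the nearest edge
    voxel; up to ``n_candidates`` well-separated maxima are returned.  Useful
    when the exact seed is not hand-picked: growing from each candidate and
    keeping the largest filled region is robust to a seed landing in a small
    internal compartment.
    """
    center = np.round(edges.world_to_index(np.asarray(near_world, dtype=float))).astype(int)
    dist = ndi.distance_transform_edt(~edges.data)
    idx = np.indices(edges.shape)
    ball_sel = ((idx - center.reshape(3, 1, 1, 1)) ** 2).sum(axis=0) <= search_radius_vox**2
    cand_dist = np.where(ball_sel & ~edges.data, dist, -1.0)
    seeds: list[tuple[int, int, int]] = []
    min_sep = max(search_radius_vox // 3, 2)
    flat_order = np.argsort(cand_dist.ravel())[::-1]
    for flat in flat_order:
        if cand_dist.ravel()[flat] <= 0:
            break
        vox = np.unravel_index(flat, edges.shape)
        if all(np.linalg.norm(np.subtract(vox, s)) >= min_sep for s in seeds):
            seeds.append(tuple(int(v) for v in vox))
        if len(seeds) >= n_candidates:
            break
    if not seeds:
        raise ValueError("no non-edge voxel found near the given point")
    return seeds


def resample_centerline(centerline: Centerline, step: float) -> Centerline:
    """Equal-arc-length resampling of a centerline polyline.

    Both endpoints are preserved: the actual step is the requested one rounded
    so that an integer number of equal steps spans the total arc length.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    total = centerline.total_length
    if step > total:
        raise ValueError(f"step {step} exceeds total arc length {total:.3g}")
    n = max(int(round(total / step)), 1)
    s = centerline.arclength[0] + np.linspace(0.0, total, n + 1)
    return Centerline(centerline.point_at(s))
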
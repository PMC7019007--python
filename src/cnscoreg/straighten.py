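"""Spinal-cord straightening: an invertible curved↔straight mapping.

A straightening transform is built from a cord centerline and a field of
rotation-minimizing orthonormal frames along it.  Image planes perpendicular
to the centerline are resampled into a straight (u, v, s) grid — u, v the
in-plane offsets along the frame's normal/binormal, s the arc length — and
the mapping is inverted by projecting world points back onto the centerline.
The mapping is injective (and therefore invertible) inside a tube of radius
r as long as r·κ_max < 1, where κ_max is the maximal centerline curvature;
configurations violating this are rejected, never silently folded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .core import Centerline, Volume

__all__ = [
    "build_frames",
    "StraighteningTransform",
    "straighten_volume",
    "unstraighten_volume",
    "apply_transform_to_map",
]


def build_frames(centerline: Centerline) -> np.ndarray:
    """Rotation-minimizing frames along a centerline via the double-reflection method.

    Returns an ``(N, 3, 3)`` array; ``frames[i] = (t, n, b)`` rows form a
    right-handed orthonormal triad at sample ``i`` with ``t`` the unit tangent.
    The initial normal is deterministic: the world x-axis projected orthogonal
    to ``t₀``, falling back to the y-axis when nearly parallel.  Successive
    frames minimize twist, so on a planar curve the binormal stays equal to
    the plane normal.
    """
    if centerline.n_samples < 3:
        raise ValueError("need >= 3 centerline samples to build frames")
    pts = centerline.points
    tangents = centerline.tangents()

    t0 = tangents[0]
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(t0, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n0 = ref - np.dot(ref, t0) * t0
    n0 /= np.linalg.norm(n0)

    n_samples = centerline.n_samples
    frames = np.empty((n_samples, 3, 3))
    normal = n0
    for i in range(n_samples):
        t = tangents[i]
        normal = normal - np.dot(normal, t) * t
        normal /= np.linalg.norm(normal)
        frames[i, 0] = t
        frames[i, 1] = normal
        frames[i, 2] = np.cross(t, normal)
        if i == n_samples - 1:
            break
        # double reflection: reflect (normal, t) in the chord plane, then in
        # the bisecting plane of the reflected and next tangents
        v1 = pts[i + 1] - pts[i]
        c1 = np.dot(v1, v1)
        if c1 == 0:
            raise ValueError("coincident consecutive centerline samples")
        rL = normal - (2.0 / c1) * np.dot(v1, normal) * v1
        tL = t - (2.0 / c1) * np.dot(v1, t) * v1
        v2 = tangents[i + 1] - tL
        c2 = np.dot(v2, v2)
        normal = rL if c2 < 1e-30 else rL - (2.0 / c2) * np.dot(v2, rL) * v2
    return frames


@dataclass
class StraighteningTransform:
    """Centerline + frame field defining the invertible curved↔straight mapping.

    The straight frame's world coordinates are ``(u, v, s)`` µm: ``s`` runs
    along the arc length starting at 0 at the first centerline sample, and
    ``(u, v)`` are offsets along the rotation-minimizing normal/binormal.
    """

    centerline: Centerline
    frames: np.ndarray = field(default=None)  # type: ignore[assignment]
    radius: float = 500.0
    in_plane_spacing: tuple[float, float] = (None, None)  # type: ignore[assignment]
    axial_step: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.frames is None:
            self.frames = build_frames(self.centerline)
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.shape != (self.centerline.n_samples, 3, 3):
            raise ValueError("frames must be (n_samples, 3, 3)")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        kmax = float(self.centerline.curvature().max())
        if self.radius * kmax >= 1.0:
            raise ValueError(
                f"in-plane radius {self.radius:.3g} µm violates injectivity: "
                f"r * max curvature = {self.radius * kmax:.3g} >= 1"
            )
        steps = np.diff(self.centerline.arclength)
        default_step = float(np.median(steps))
        if self.axial_step is None:
            self.axial_step = default_step
        if self.in_plane_spacing[0] is None:
            self.in_plane_spacing = (default_step, default_step)
        self.in_plane_spacing = (
            float(self.in_plane_spacing[0]),
            float(self.in_plane_spacing[1]),
        )

    # -- straight grid ------------------------------------------------------
    def straight_grid(self) -> tuple[tuple[int, int, int], np.ndarray, np.ndarray]:
        """Shape, spacing and origin of the canonical straight output grid."""
        su, sv = self.in_plane_spacing
        nu = 2 * int(np.floor(self.radius / su)) + 1
        nv = 2 * int(np.floor(self.radius / sv)) + 1
        ns = 1 + int(np.floor(self.centerline.total_length / self.axial_step + 1e-9))
        spacing = np.array([su, sv, self.axial_step])
        origin = np.array([-(nu // 2) * su, -(nv // 2) * sv, 0.0])
        return (nu, nv, ns), spacing, origin

    def s_values(self) -> np.ndarray:
        (_, _, ns), _, _ = self.straight_grid()
        return self.centerline.arclength[0] + np.arange(ns) * self.axial_step

    def frame_at(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Interpolated orthonormal (t, n, b) at arbitrary arc lengths."""
        arcl = self.centerline.arclength
        s = np.clip(np.asarray(s, dtype=float), arcl[0], arcl[-1])
        k = np.clip(np.searchsorted(arcl, s, side="right") - 1, 0, len(arcl) - 2)
        w = ((s - arcl[k]) / (arcl[k + 1] - arcl[k]))[..., None]
        t = (1 - w) * self.frames[k, 0] + w * self.frames[k + 1, 0]
        t /= np.linalg.norm(t, axis=-1, keepdims=True)
        n = (1 - w) * self.frames[k, 1] + w * self.frames[k + 1, 1]
        n -= np.sum(n * t, axis=-1, keepdims=True) * t
        n /= np.linalg.norm(n, axis=-1, keepdims=True)
        b = np.cross(t, n)
        return t, n, b

    # -- forward / inverse point maps ---------------------------------------
    def straight_to_world(self, uvs: np.ndarray) -> np.ndarray:
        """Map straight-frame (u, v, s) points (..., 3) to curved world µm."""
        uvs = np.asarray(uvs, dtype=float)
        s = self.centerline.arclength[0] + uvs[..., 2]
        c = self.centerline.point_at(s)
        _, n, b = self.frame_at(s)
        return c + uvs[..., 0:1] * n + uvs[..., 1:2] * b

    def world_to_straight(self, pts: np.ndarray) -> np.ndarray:
        """Map curved world points (..., 3) to straight-frame (u, v, s)."""
        pts = np.asarray(pts, dtype=float)
        flat = pts.reshape(-1, 3)
        s = self.centerline.nearest_arclength(flat)
        c = self.centerline.point_at(s)
        _, n, b = self.frame_at(s)
        d = flat - c
        u = np.sum(d * n, axis=-1)
        v = np.sum(d * b, axis=-1)
        out = np.stack([u, v, s - self.centerline.arclength[0]], axis=-1)
        return out.reshape(pts.shape)


def transform_for_volume(
    centerline: Centerline,
    volume: Volume,
    radius: float,
    supersample: float = 2.0,
) -> StraighteningTransform:
    """Straightening transform sized for a given source volume.

    The straight grid is supersampled (default 2×: spacing = source in-plane
    spacing / 2) so that the straighten→unstraighten round trip loses as
    little as possible to the double trilinear interpolation.
    """
    step = float(min(volume.spacing)) / supersample
    return StraighteningTransform(
        centerline, radius=radius, in_plane_spacing=(step, step), axial_step=step
    )


def _sample(volume: Volume, world_pts: np.ndarray, order: int, fill: float) -> np.ndarray:
    idx = volume.world_to_index(world_pts)
    coords = np.moveaxis(idx, -1, 0)
    return ndi.map_coordinates(
        volume.data, coords, order=order, mode="constant", cval=fill
    )


def straighten_volume(
    volume: Volume,
    transform: StraighteningTransform,
    fill: float = 0.0,
    order: int = 1,
) -> Volume:
    """Resample a curved volume into the straight (u, v, s) frame.

    Each output plane ``s = const`` is the image plane perpendicular to the
    centerline at arc length ``s``, sampled trilinearly; points outside the
    source grid take ``fill``.  The axial extent equals the centerline arc
    length (to within one axial step) by construction.
    """
    shape, spacing, origin = transform.straight_grid()
    uu = origin[0] + np.arange(shape[0]) * spacing[0]
    vv = origin[1] + np.arange(shape[1]) * spacing[1]
    ss = np.arange(shape[2]) * spacing[2]
    U, V, S = np.meshgrid(uu, vv, ss, indexing="ij")
    uvs = np.stack([U, V, S], axis=-1)
    world = transform.straight_to_world(uvs)
    out = _sample(volume, world, order=order, fill=fill)
    return Volume(out, spacing=spacing, origin=origin)


def unstraighten_volume(
    straight: Volume,
    transform: StraighteningTransform,
    target_grid: Volume | tuple,
    fill: float = 0.0,
    order: int = 1,
) -> Volume:
    """Map a straight-frame volume back onto a curved-world grid.

    For each target voxel the arc-length parameter is found by exact
    projection onto the centerline polyline (nearest sample, then projection
    onto the adjacent segments); the in-plane offsets follow from the frame at
    that parameter.  Points beyond the transform radius take ``fill``.
    """
    if isinstance(target_grid, Volume):
        shape, spacing, origin = target_grid.shape, target_grid.spacing, target_grid.origin
    else:
        shape, spacing, origin = target_grid
        spacing = np.asarray(spacing, dtype=float)
        origin = np.asarray(origin, dtype=float)
    axes = [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    world = np.stack([X, Y, Z], axis=-1)
    uvs = transform.world_to_straight(world)
    r = np.hypot(uvs[..., 0], uvs[..., 1])
    idx = (uvs - straight.origin) / straight.spacing
    coords = np.moveaxis(idx, -1, 0)
    out = ndi.map_coordinates(straight.data, coords, order=order, mode="constant", cval=fill)
    out = np.where(r <= transform.radius, out, fill)
    return Volume(out, spacing=spacing, origin=origin)


def apply_transform_to_map(
    map_volume: Volume,
    transform: StraighteningTransform,
    direction: str,
    interpolation: str = "trilinear",
    target_grid: Volume | tuple | None = None,
    fill: float = 0.0,
) -> Volume:
    """Carry a parametric map (FA, labels, masks) through the straightening.

    ``direction`` is ``"curved_to_straight"`` or ``"straight_to_curved"``;
    ``interpolation`` is ``"trilinear"`` or ``"nearest"`` (use nearest for
    label maps so no new labels are invented).
    """
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "trilinear" else 0
    if direction == "curved_to_straight":
        return straighten_volume(map_volume, transform, fill=fill, order=order)
    if direction == "straight_to_curved":
        if target_grid is None:
            raise ValueError("straight_to_curved requires a target_grid")
        return unstraighten_volume(map_volume, transform, target_grid, fill=fill, order=order)
    raise ValueError(f"unknown direction {direction!r}")
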
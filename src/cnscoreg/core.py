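"""Core data carriers shared by every stage of the co-registration pipeline.

All world coordinates are in micrometres (µm).  Arrays are indexed ``[i, j, k]``
with axes identified as ``(x, y, z)``; for spinal-cord data the long (axial)
axis is ``z``.  The voxel-centre convention is fixed package-wide: the world
coordinate of voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Volume",
    "BinaryMask",
    "Centerline",
    "DegenerateInputError",
    "InvalidSpecError",
]


class InvalidSpecError(ValueError):
    """A phantom/pipeline specification violates one of its invariants."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable signal (e.g. constant)."""


def _as_triplet(value, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a scalar or length-3 sequence, got {value!r}")
    return arr


@dataclass
class Volume:
    """A 3D scalar grid with per-axis spacing (µm) and world origin (µm).

    Parameters
    ----------
    data:
        3D array of finite scalars, axes ``(x, y, z)``.
    spacing:
        Voxel size per axis in µm (scalar or length-3).
    origin:
        World coordinate of the centre of voxel ``(0, 0, 0)``, in µm.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 2:
            raise ValueError(f"Volume needs >= 2 voxels per axis, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume data must be finite")
        self.spacing = _as_triplet(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        self.origin = _as_triplet(self.origin, "origin")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return float(np.prod(self.spacing))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices ``(..., 3)`` to world µm."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map world µm points ``(..., 3)`` to continuous voxel indices."""
        return (np.asarray(pts, dtype=float) - self.origin) / self.spacing

    def grid_world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1D arrays of voxel-centre world coordinates."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        )

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing.copy(), self.origin.copy())

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same grid, new values."""
        return Volume(np.asarray(data, dtype=np.float64), self.spacing.copy(), self.origin.copy())

    def same_grid(self, other: "Volume | BinaryMask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class BinaryMask:
    """A {0, 1} volume sharing a :class:`Volume` grid.

    ``provenance`` records which operation produced the mask (for reports).
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    provenance: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"BinaryMask data must be 3D, got ndim={data.ndim}")
        if data.dtype != bool:
            uniq = np.unique(data)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("BinaryMask values must be strictly binary")
            data = data.astype(bool)
        self.data = data
        self.spacing = _as_triplet(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        self.origin = _as_triplet(self.origin, "origin")

    @classmethod
    def like(cls, vol: "Volume | BinaryMask", data: np.ndarray, provenance: str = "") -> "BinaryMask":
        if data.shape != vol.shape:
            raise ValueError(f"mask shape {data.shape} != grid shape {vol.shape}")
        return cls(data, vol.spacing.copy(), vol.origin.copy(), provenance)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.data.sum())

    def is_empty(self) -> bool:
        return not self.data.any()

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - self.origin) / self.spacing

    def to_volume(self) -> Volume:
        return Volume(self.data.astype(np.float64), self.spacing.copy(), self.origin.copy())

    def copy(self) -> "BinaryMask":
        return replace(self, data=self.data.copy())


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) between two binary masks."""
    da = a.data if isinstance(a, BinaryMask) else np.asarray(a, dtype=bool)
    db = b.data if isinstance(b, BinaryMask) else np.asarray(b, dtype=bool)
    if da.shape != db.shape:
        raise ValueError(f"shape mismatch {da.shape} vs {db.shape}")
    denom = da.sum() + db.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(da, db).sum() / denom)


@dataclass
class Centerline:
    """An ordered 3D polyline in world coordinates (µm) with arc-length parameterization."""

    points: np.ndarray
    #: cumulative arc length per sample, ``arclength[0] == 0``
    arclength: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"Centerline points must be (N, 3), got {self.points.shape}")
        if self.points.shape[0] < 2:
            raise ValueError("Centerline needs >= 2 samples")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(steps <= 0):
            raise ValueError("coincident consecutive centerline samples")
        if self.arclength is None:
            self.arclength = np.concatenate([[0.0], np.cumsum(steps)])
        else:
            self.arclength = np.asarray(self.arclength, dtype=np.float64)
            if self.arclength.shape != (self.points.shape[0],):
                raise ValueError("arclength must have one entry per sample")
            if np.any(np.diff(self.arclength) <= 0):
                raise ValueError("arclength must be strictly increasing")
        med = np.median(steps)
        if np.any(steps > 10.0 * med):
            raise ValueError("centerline has a gap > 10x the median step")

    @property
    def n_samples(self) -> int:
        return self.points.shape[0]

    @property
    def total_length(self) -> float:
        return float(self.arclength[-1] - self.arclength[0])

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of the polyline at arc length(s) ``s``."""
        s = np.clip(np.asarray(s, dtype=float), self.arclength[0], self.arclength[-1])
        out = np.empty(np.shape(s) + (3,))
        for a in range(3):
            out[..., a] = np.interp(s, self.arclength, self.points[:, a])
        return out

    def tangents(self) -> np.ndarray:
        """Unit tangents per sample (central differences, second-order
        one-sided at the ends — first-order end tangents would rotate the
        initial frame of any construction built on them by O(step))."""
        t = np.gradient(self.points, self.arclength, axis=0, edge_order=2)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    def curvature(self) -> np.ndarray:
        """Discrete curvature magnitude per sample (1/µm)."""
        d1 = np.gradient(self.points, self.arclength, axis=0)
        d2 = np.gradient(d1, self.arclength, axis=0)
        cross = np.cross(d1, d2)
        denom = np.linalg.norm(d1, axis=1) ** 3
        return np.linalg.norm(cross, axis=1) / np.maximum(denom, 1e-30)

    def nearest_arclength(self, pts: np.ndarray) -> np.ndarray:
        """Exact nearest arc-length parameter on the polyline for each point.

        Nearest-sample lookup followed by exact projection onto the adjacent
        segments (the polyline is piecewise linear, so this is the true local
        minimizer of the distance).
        """
        from scipy.spatial import cKDTree

        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        tree = cKDTree(self.points)
        _, k = tree.query(pts)
        best_s = self.arclength[k].astype(float)
        best_d2 = np.sum((pts - self.points[k]) ** 2, axis=1)
        for seg in (np.maximum(k - 1, 0), np.minimum(k, self.n_samples - 2)):
            p0 = self.points[seg]
            d = self.points[seg + 1] - p0
            L2 = np.sum(d * d, axis=1)
            t = np.clip(np.sum((pts - p0) * d, axis=1) / L2, 0.0, 1.0)
            proj = p0 + t[:, None] * d
            d2 = np.sum((pts - proj) ** 2, axis=1)
            better = d2 < best_d2
            seg_len = self.arclength[seg + 1] - self.arclength[seg]
            best_s = np.where(better, self.arclength[seg] + t * seg_len, best_s)
            best_d2 = np.minimum(best_d2, d2)
        return best_s if best_s.size > 1 else best_s


def moving_average_polyline(points: np.ndarray, window: int) -> np.ndarray:
    """Smooth an (N, 3) polyline with a centred moving average.

    Near the ends the window shrinks symmetrically so endpoints stay close to
    the data (no zero-padding bias).
    """
    points = np.asarray(points, dtype=float)
    if window <= 1:
        return points.copy()
    n = points.shape[0]
    half = window // 2
    out = np.empty_like(points)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = points[i - h : i + h + 1].mean(axis=0)
    return out
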
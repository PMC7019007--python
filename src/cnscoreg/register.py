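"""Intermodal registration: landmark initialization, Mattes mutual information,
affine optimization and a diffeomorphic (stationary-velocity demons) refinement.

Conventions
-----------
A transform maps **fixed-image world coordinates to moving-image world
coordinates** (the pull-back convention: to resample the moving image onto the
fixed grid, each fixed voxel centre is pushed through the transform and the
moving image is interpolated there).  Affine transforms are parameterized as
(3 Euler angles, 3 translations, 3 log-scales, 3 shears) about a configurable
centre; the diffeomorphic refinement integrates a stationary velocity field by
scaling and squaring, so its displacement field has positive Jacobian
determinant by construction (and this is asserted, not assumed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .core import Volume
from .resample import antialias_downsample

__all__ = [
    "AffineTransform",
    "DisplacementField",
    "RegistrationResult",
    "OverlapError",
    "landmark_init",
    "mattes_mi",
    "register_affine",
    "register_diffeomorphic",
    "apply_transform",
    "jacobian_determinant",
]


class OverlapError(RuntimeError):
    """The transform leaves too little of the fixed image inside the moving image."""


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def _euler_matrix(angles: np.ndarray) -> np.ndarray:
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


@dataclass
class AffineTransform:
    """A 4×4 homogeneous affine mapping fixed world µm → moving world µm."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if abs(np.linalg.det(self.matrix[:3, :3])) <= 1e-12:
            raise ValueError("affine 3x3 block is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_params(
        cls,
        params: np.ndarray,
        center: np.ndarray | None = None,
    ) -> "AffineTransform":
        """Affine from 12 parameters (3 Euler angles rad, 3 translations µm,
        3 log-scales, 3 shears), rotating/scaling about ``center`` (µm)."""
        p = np.asarray(params, dtype=float)
        if p.shape != (12,):
            raise ValueError("need 12 parameters")
        R = _euler_matrix(p[0:3])
        S = np.diag(np.exp(p[6:9]))
        H = np.eye(3)
        H[0, 1], H[0, 2], H[1, 2] = p[9], p[10], p[11]
        A = R @ H @ S
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        m = np.eye(4)
        m[:3, :3] = A
        m[:3, 3] = c - A @ c + p[3:6]
        return cls(m)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return AffineTransform(self.matrix @ other.matrix)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))


@dataclass
class DisplacementField:
    """Dense displacement (µm) on the fixed grid: x ↦ x + u(x), then optionally
    an affine tail (for fields composed with an affine pre-alignment)."""

    field: np.ndarray  # (nx, ny, nz, 3) µm
    spacing: np.ndarray
    origin: np.ndarray
    integration_steps: int = 0

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        if self.field.ndim != 4 or self.field.shape[-1] != 3:
            raise ValueError("field must be (nx, ny, nz, 3)")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        """x + u(x), u trilinearly interpolated (zero beyond the grid edge)."""
        pts = np.asarray(pts, dtype=float)
        idx = (pts - self.origin) / self.spacing
        coords = np.moveaxis(idx, -1, 0)
        disp = np.stack(
            [
                ndi.map_coordinates(self.field[..., a], coords, order=1, mode="nearest")
                for a in range(3)
            ],
            axis=-1,
        )
        return pts + disp


@dataclass
class RegistrationResult:
    transform: AffineTransform | DisplacementField
    metric_value: float
    trace: list = field(default_factory=list)  # (level, iteration, metric)
    converged: bool = True
    message: str = ""


# ---------------------------------------------------------------------------
# landmark initialization
# ---------------------------------------------------------------------------

def landmark_init(
    fixed_points: np.ndarray,
    moving_points: np.ndarray,
    allow_scale: bool = True,
) -> AffineTransform:
    """Similarity transform mapping a fixed two-point segment onto a moving one.

    Midpoints are matched by translation; the minimal rotation aligns the
    segment directions (roll about the segment axis stays 0 — two points
    cannot determine it); uniform scale is the length ratio when
    ``allow_scale``.  With these conventions the fixed endpoints land exactly
    on the moving endpoints (when scaling is allowed).
    """
    f = np.asarray(fixed_points, dtype=float).reshape(2, 3)
    m = np.asarray(moving_points, dtype=float).reshape(2, 3)
    df, dm = f[1] - f[0], m[1] - m[0]
    lf, lm = np.linalg.norm(df), np.linalg.norm(dm)
    if lf == 0 or lm == 0:
        raise ValueError("landmark segments must have nonzero length")
    uf, um = df / lf, dm / lm
    v = np.cross(uf, um)
    c = float(np.dot(uf, um))
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else _flip_rotation(uf)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx / (1.0 + c)
    s = lm / lf if allow_scale else 1.0
    cf, cm = f.mean(axis=0), m.mean(axis=0)
    mat = np.eye(4)
    mat[:3, :3] = s * R
    mat[:3, 3] = cm - s * R @ cf
    return AffineTransform(mat)


def _flip_rotation(axis_dir: np.ndarray) -> np.ndarray:
    """180° rotation about any axis perpendicular to ``axis_dir``."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis_dir)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    perp = ref - np.dot(ref, axis_dir) * axis_dir
    perp /= np.linalg.norm(perp)
    return 2.0 * np.outer(perp, perp) - np.eye(3)


# ---------------------------------------------------------------------------
# Mattes mutual information
# ---------------------------------------------------------------------------

def _cubic_bspline(t: np.ndarray) -> np.ndarray:
    at = np.abs(t)
    out = np.zeros_like(at)
    m1 = at < 1
    m2 = (at >= 1) & (at < 2)
    out[m1] = (4 - 6 * at[m1] ** 2 + 3 * at[m1] ** 3) / 6.0
    out[m2] = (2 - at[m2]) ** 3 / 6.0
    return out


def _sample_points(fixed: Volume, n_samples, rng: np.random.Generator | None):
    """Fixed-grid voxel centres, all or a seeded random subset."""
    shape = fixed.shape
    total = int(np.prod(shape))
    if n_samples == "all" or n_samples >= total:
        idx = np.indices(shape).reshape(3, -1).T
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        flat = rng.choice(total, size=int(n_samples), replace=False)
        idx = np.stack(np.unravel_index(flat, shape), axis=-1)
    return fixed.index_to_world(idx)


def mattes_mi(
    fixed: Volume,
    moving: Volume,
    transform,
    bins: int = 32,
    n_samples="all",
    rng: np.random.Generator | None = None,
    min_overlap: float = 0.1,
) -> float:
    """Negative Mattes mutual information of ``moving ∘ transform`` vs ``fixed``.

    The joint density is a Parzen-window histogram: a zero-order (box) kernel
    on the fixed intensities and a cubic B-spline kernel on the moving
    intensities; both intensity axes are min–max normalized to the bin range.
    MI is reported in bits and returned negated (lower = better aligned).

    Raises
    ------
    OverlapError
        If fewer than ``min_overlap`` of the sampled fixed points land inside
        the moving image (a diagnosably wrong initialization, as opposed to a
        merely bad metric value).
    """
    pts = _sample_points(fixed, n_samples, rng)
    fvals = ndi.map_coordinates(
        fixed.data, np.moveaxis(fixed.world_to_index(pts), -1, 0), order=1
    )
    mapped = transform.apply(pts) if hasattr(transform, "apply") else transform(pts)
    midx = moving.world_to_index(mapped)
    inside = np.all((midx >= 0) & (midx <= np.array(moving.shape) - 1), axis=-1)
    if inside.mean() < min_overlap:
        raise OverlapError(
            f"only {inside.mean():.1%} of fixed samples map inside the moving "
            f"image (minimum {min_overlap:.0%})"
        )
    fvals = fvals[inside]
    mvals = ndi.map_coordinates(moving.data, np.moveaxis(midx[inside], -1, 0), order=1)

    def to_bins(v, lo, hi):
        if hi == lo:
            return np.zeros_like(v)
        # keep the cubic kernel support inside [0, bins)
        return 1.0 + np.clip((v - lo) / (hi - lo), 0, 1) * (bins - 4.0)

    # binning is fixed from the full volumes, not the current sample set:
    # the metric must not change its own intensity normalization as the
    # transform moves
    fb = np.floor(to_bins(fvals, fixed.data.min(), fixed.data.max())).astype(int)
    mb = to_bins(mvals, moving.data.min(), moving.data.max())
    m0 = np.floor(mb).astype(int)
    joint = np.zeros((bins, bins))
    for off in (-1, 0, 1, 2):
        w = _cubic_bspline(mb - (m0 + off))
        np.add.at(joint, (fb, np.clip(m0 + off, 0, bins - 1)), w)
    joint /= joint.sum()
    pf = joint.sum(axis=1, keepdims=True)
    pm = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / (pf @ pm)[nz])))
    return -mi


# ---------------------------------------------------------------------------
# affine registration
# ---------------------------------------------------------------------------

def _param_scales(fixed: Volume) -> np.ndarray:
    """Per-parameter internal units for the optimizer.

    Translations move in units of one fixed voxel; angles, log-scales and
    shears in units sized so one internal step displaces a point at the image
    half-extent by about one voxel — this keeps the finite-difference gradient
    comparably conditioned across parameter types.
    """
    radius = 0.5 * float(np.mean((np.array(fixed.shape) - 1) * fixed.spacing))
    ang = float(min(fixed.spacing)) / radius
    return np.array([ang] * 3 + [float(min(fixed.spacing))] * 3 + [ang] * 6)


def register_affine(
    fixed: Volume,
    moving: Volume,
    init: AffineTransform | None = None,
    levels: int = 3,
    iters_per_level: int = 120,
    bins: int = 32,
    sample_frac_finest: float = 0.2,
    seed: int = 0,
    optimize_shear: bool = False,
) -> RegistrationResult:
    """Multi-resolution Mattes-MI affine registration.

    An image pyramid (anti-aliased, factors 4/2/1) is optimized coarse to
    fine with adaptive-step finite-difference gradient descent on the 12
    affine parameters (angles, translations, log-scales, shears; shears are
    frozen unless ``optimize_shear``).  Parameters are scaled to comparable
    units (0.01 rad, one voxel, 0.01 log-scale).  Metric sampling is full at
    the coarse levels and a seeded 20 % random subset at the finest; the run
    is deterministic given ``seed``.  Convergence: relative metric
    improvement < 1e-5 over 10 iterations, or step collapse.
    """
    if init is None:
        init = AffineTransform.identity()
    center = fixed.index_to_world((np.array(fixed.shape) - 1) / 2.0)
    scales = _param_scales(fixed)
    active = np.ones(12, dtype=bool)
    if not optimize_shear:
        active[9:] = False

    factors = [2 ** (levels - 1 - k) for k in range(levels)]  # e.g. 4, 2, 1
    p = np.zeros(12)
    trace: list[tuple[int, int, float]] = []
    converged = True
    message = ""
    rng = np.random.default_rng(seed)
    worsened_levels = 0

    for li, fac in enumerate(factors):
        if fac > 1:
            fx = antialias_downsample(fixed, fixed.spacing * fac)
            mv = antialias_downsample(moving, moving.spacing * fac)
            n_samp = "all"
        else:
            fx, mv = fixed, moving
            n_samp = max(2000, int(sample_frac_finest * np.prod(fixed.shape)))
        # one sampling seed per level: the metric must be a fixed deterministic
        # function of the parameters while the level is being optimized
        level_seed = int(rng.integers(2**31 - 1))

        def metric(params):
            t = init.compose(AffineTransform.from_params(params, center=center))
            return mattes_mi(
                fx, mv, t, bins=bins, n_samples=n_samp,
                rng=np.random.default_rng(level_seed),
            )

        current = metric(p)
        trace.append((li, 0, current))
        step = 1.0
        history: list[float] = [current]
        for it in range(1, iters_per_level + 1):
            grad = np.zeros(12)
            for j in np.flatnonzero(active):
                dp = np.zeros(12)
                dp[j] = 0.5 * scales[j]
                grad[j] = metric(p + dp) - metric(p - dp)
            gnorm = np.linalg.norm(grad)
            if gnorm == 0:
                break
            direction = -(grad / gnorm) * scales
            trial = p + step * direction
            val = metric(trial)
            if val < current:
                p, current = trial, val
                step = min(step * 1.2, 4.0)
            else:
                step *= 0.5
            trace.append((li, it, current))
            history.append(current)
            if step < 1e-4:
                break
            if len(history) > 10 and abs(history[-11] - current) < 1e-5 * max(abs(current), 1e-12):
                break
        if history[-1] > history[0] + 1e-12:
            worsened_levels += 1
            if worsened_levels >= 3:
                converged = False
                message = "metric worsened at three successive levels"
                break

    final = init.compose(AffineTransform.from_params(p, center=center))
    final_metric = mattes_mi(fixed, moving, final, bins=bins, n_samples="all")
    return RegistrationResult(
        transform=final, metric_value=final_metric, trace=trace,
        converged=converged, message=message,
    )


# ---------------------------------------------------------------------------
# diffeomorphic refinement (stationary-velocity demons)
# ---------------------------------------------------------------------------

def _exp_field(vel: np.ndarray, spacing: np.ndarray, steps: int = 6) -> np.ndarray:
    """Integrate a stationary velocity field by scaling and squaring."""
    disp = vel / (2.0**steps)
    for _ in range(steps):
        disp = disp + _warp_field(disp, disp, spacing)
    return disp


def _warp_field(f: np.ndarray, disp: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Sample vector field ``f`` at x + disp(x) (nearest beyond the edge)."""
    shape = f.shape[:3]
    idx = np.indices(shape).astype(float)
    coords = [idx[a] + disp[..., a] / spacing[a] for a in range(3)]
    return np.stack(
        [ndi.map_coordinates(f[..., a], coords, order=1, mode="nearest") for a in range(3)],
        axis=-1,
    )


def jacobian_determinant(field: DisplacementField) -> Volume:
    """Determinant of the Jacobian of x ↦ x + u(x), per voxel.

    Central differences in world units; 1 everywhere for a zero field, > 0
    everywhere iff the map is locally invertible and orientation-preserving.
    """
    u = field.field
    J = np.empty(u.shape[:3] + (3, 3))
    for a in range(3):
        for bax in range(3):
            J[..., a, bax] = np.gradient(u[..., a], field.spacing[bax], axis=bax)
        J[..., a, a] += 1.0
    return Volume(np.linalg.det(J), spacing=field.spacing, origin=field.origin)


def register_diffeomorphic(
    fixed: Volume,
    moving: Volume,
    init: AffineTransform | None = None,
    smooth_update_sigma: float = 2.0,
    smooth_field_sigma: float = 1.0,
    iters: int = 50,
    step: float = 0.5,
    integration_steps: int = 6,
    foreground: np.ndarray | None = None,
) -> RegistrationResult:
    """Demons-style diffeomorphic refinement after affine pre-alignment.

    The moving image is first resampled onto the fixed grid through ``init``;
    a stationary velocity field is then optimized with demons forces on
    z-score–normalized intensities, Gaussian smoothing of each update
    (``smooth_update_sigma``, voxels) and of the accumulated field
    (``smooth_field_sigma``), and integrated to a displacement by scaling and
    squaring.  A field whose Jacobian determinant is anywhere ≤ 0 is rejected;
    smoothing is increased once and the attempt repeated before failing.

    The returned :class:`DisplacementField` maps fixed world points into the
    *affinely pre-aligned* moving frame; compose with ``init`` to reach the
    native moving frame.
    """
    if init is None:
        init = AffineTransform.identity()
    warped_init = apply_transform(moving, init, target_grid=fixed)
    f = fixed.data
    m = warped_init.data

    def zscore(x):
        s = x.std()
        return (x - x.mean()) / (s if s > 0 else 1.0)

    fz, mz = zscore(f), zscore(m)
    spacing = fixed.spacing
    if foreground is None:
        foreground = np.ones(f.shape, bool)

    for attempt in range(2):
        upd_sigma = smooth_update_sigma * (1.5**attempt)
        fld_sigma = smooth_field_sigma * (1.5**attempt)
        vel = np.zeros(f.shape + (3,))
        trace = []
        for it in range(iters):
            disp = _exp_field(vel, spacing, steps=integration_steps)
            warped = _warp_volume(mz, disp, spacing)
            diff = warped - fz
            grads = np.stack(np.gradient(fz, *spacing), axis=-1)
            gnorm2 = (grads**2).sum(axis=-1)
            denom = gnorm2 + (diff**2) / (spacing.min() ** 2) + 1e-9
            force = -(diff / denom)[..., None] * grads * foreground[..., None]
            for a in range(3):
                force[..., a] = ndi.gaussian_filter(force[..., a], upd_sigma)
            vel = vel + step * force
            for a in range(3):
                vel[..., a] = ndi.gaussian_filter(vel[..., a], fld_sigma)
            trace.append((attempt, it, float((diff**2)[foreground].mean())))
        disp = _exp_field(vel, spacing, steps=integration_steps)
        dfield = DisplacementField(
            disp, spacing=spacing, origin=fixed.origin, integration_steps=integration_steps
        )
        jd = jacobian_determinant(dfield).data[1:-1, 1:-1, 1:-1]
        if jd.min() > 0:
            return RegistrationResult(
                transform=dfield,
                metric_value=trace[-1][2],
                trace=trace,
                converged=True,
                message=f"min interior Jacobian determinant {jd.min():.4f}",
            )
    return RegistrationResult(
        transform=dfield, metric_value=trace[-1][2], trace=trace,
        converged=False, message="Jacobian non-positive even after extra smoothing",
    )


def _warp_volume(data: np.ndarray, disp: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    idx = np.indices(data.shape).astype(float)
    coords = [idx[a] + disp[..., a] / spacing[a] for a in range(3)]
    return ndi.map_coordinates(data, coords, order=1, mode="nearest")


# ---------------------------------------------------------------------------
# resampling through transforms
# ---------------------------------------------------------------------------

def apply_transform(
    volume: Volume,
    transform,
    target_grid: Volume,
    interpolation: str = "trilinear",
    fill: float = 0.0,
) -> Volume:
    """Pull-back resampling of ``volume`` onto ``target_grid`` through a transform.

    ``transform`` may be an :class:`AffineTransform`, a
    :class:`DisplacementField`, or a sequence of them (applied left to right:
    fixed frame → ... → moving frame).  Use nearest interpolation for label
    maps.
    """
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "trilinear" else 0
    axes = target_grid.grid_world_coords()
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    chain = transform if isinstance(transform, (list, tuple)) else [transform]
    for t in chain:
        pts = t.apply(pts)
    idx = volume.world_to_index(pts)
    out = ndi.map_coordinates(
        volume.data, np.moveaxis(idx, -1, 0), order=order, mode="constant", cval=fill
    )
    return Volume(out, spacing=target_grid.spacing.copy(), origin=target_grid.origin.copy())
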
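"""Synthetic multimodal phantoms with exported ground truth.

Two geometries are generated, each as a *pair* of volumes emulating the two
acquisition branches of the pipeline:

* a **brain-like** phantom — an ellipsoidal sample embedded in medium with
  internal structures (a dark "ventricle", a bright curved "callosum" band and
  a textured "hippocampus" blob) that give a mutual-information metric signal
  in both modalities;
* a **cord-like** phantom — a curved tube of tissue with a two-lobed
  ("butterfly") interior cross-section, embedded in agar-like medium.

The high-resolution modality is rendered on a fine grid in the anatomy frame
and carries an alternating bright/dark ring artifact at the sample–medium
interface, as tomographic reconstructions do.  The low-resolution modality is
rendered on a coarse grid through the *true* inter-modality transform (a
similarity affine plus an optional smooth polynomial bend), so the two
renderings disagree by a known, exported spatial mapping.  All randomness is
seeded; identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BinaryMask, Centerline, InvalidSpecError, Volume
from .straighten import StraighteningTransform

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "TrueTransform",
    "PhantomPair",
    "make_cord_curve",
    "render_cord_phantom",
    "render_brain_phantom",
    "add_ring_artifact",
    "default_cord_spec",
    "default_brain_spec",
]


# ---------------------------------------------------------------------------
# spec / ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Everything needed to render one phantom pair deterministically.

    Intensity levels are in arbitrary units; ``levels_high`` /``levels_low``
    map region names (``background``, ``medium``, ``tissue``, ``butterfly``,
    ``ventricle``, ``callosum``, ``hippocampus``) to levels per modality.
    ``ring_amplitude`` is a fraction of the tissue level; the true
    inter-modality transform maps **low-res world → high-res world**.
    """

    kind: str = "cord"
    shape_high: tuple[int, int, int] = (96, 96, 160)
    spacing_high: tuple[float, float, float] = (20.0, 20.0, 20.0)
    shape_low: tuple[int, int, int] = (24, 24, 40)
    spacing_low: tuple[float, float, float] = (80.0, 80.0, 80.0)
    control_points: tuple = ()
    tube_radius: float = 350.0
    levels_high: dict = field(default_factory=dict)
    levels_low: dict = field(default_factory=dict)
    ring_amplitude: float = 0.5
    ring_width: int = 1
    noise_sigma_high: float = 0.0
    noise_sigma_low: float = 0.0
    true_rotation_deg: float = 0.0
    true_rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    true_translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    true_scale: float = 1.0
    warp_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("brain", "cord"):
            raise InvalidSpecError(f"kind must be 'brain' or 'cord', got {self.kind!r}")
        for name, shape in (("shape_high", self.shape_high), ("shape_low", self.shape_low)):
            if len(shape) != 3 or any(s < 2 for s in shape):
                raise InvalidSpecError(f"{name} must be 3 axes of >= 2 voxels")
            if any(s > 256 for s in shape):
                raise InvalidSpecError(f"{name} exceeds 256 voxels per axis: {shape}")
        for name, sp in (("spacing_high", self.spacing_high), ("spacing_low", self.spacing_low)):
            if any(s <= 0 for s in sp):
                raise InvalidSpecError(f"{name} must be > 0")
        if self.kind == "cord" and self.tube_radius <= 0:
            raise InvalidSpecError("tube_radius must be > 0")
        if self.ring_amplitude < 0 or self.ring_width < 1:
            raise InvalidSpecError("ring_amplitude >= 0 and ring_width >= 1 required")

    def extent_high(self) -> np.ndarray:
        return (np.array(self.shape_high) - 1) * np.array(self.spacing_high)


@dataclass
class TrueTransform:
    """The generating low-res → high-res world mapping: affine + smooth bend.

    ``affine`` is a 4×4 homogeneous matrix; the optional bend displaces points
    along x by a parabolic profile of the axial coordinate (zero at both axial
    extremities), modelling the different curvature the two sample holders
    induce.  The full mapping is ``M(y) = A·y + bend(y)``.
    """

    affine: np.ndarray
    warp_amplitude: float = 0.0
    z_range: tuple[float, float] = (0.0, 1.0)

    def bend(self, pts: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(pts, dtype=float))
        if self.warp_amplitude != 0.0:
            z0, z1 = self.z_range
            zeta = np.clip((pts[..., 2] - z0) / (z1 - z0), 0.0, 1.0)
            out[..., 0] = self.warp_amplitude * 4.0 * zeta * (1.0 - zeta)
        return out

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        lin = pts @ self.affine[:3, :3].T + self.affine[:3, 3]
        return lin + self.bend(pts)

    def inverse_points(self, pts: np.ndarray, tol: float = 1e-9, max_iter: int = 100) -> np.ndarray:
        """Invert the mapping pointwise by fixed-point iteration on the bend."""
        pts = np.asarray(pts, dtype=float)
        ainv = np.linalg.inv(self.affine)
        y = pts @ ainv[:3, :3].T + ainv[:3, 3]
        for _ in range(max_iter):
            target = pts - self.bend(y)
            y_new = target @ ainv[:3, :3].T + ainv[:3, 3]
            if np.max(np.abs(y_new - y)) < tol:
                return y_new
            y = y_new
        return y


@dataclass
class GroundTruth:
    """Exported truth for one phantom pair."""

    mask_high: BinaryMask
    mask_low: BinaryMask
    transform: TrueTransform
    landmarks_high: np.ndarray
    landmarks_low: np.ndarray
    centerline: Centerline | None = None
    centerline_low: Centerline | None = None


@dataclass
class PhantomPair:
    high: Volume
    low: Volume
    truth: GroundTruth


# ---------------------------------------------------------------------------
# cord curve
# ---------------------------------------------------------------------------

def make_cord_curve(control_points, n_samples: int, bc_type="natural") -> Centerline:
    """Smooth interpolating curve through >= 4 control points (world µm).

    A cubic spline in chord-length parameterization, sampled at ``n_samples``
    points; the returned polyline's arc length is strictly increasing.
    ``bc_type`` is passed to the spline ("natural" by default; clamped end
    tangents keep the curve from undershooting near its extremities).
    """
    from scipy.interpolate import CubicSpline

    pts = np.asarray(control_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
        raise InvalidSpecError(f"need >= 4 control points (3D), got shape {pts.shape}")
    if n_samples < 16:
        raise InvalidSpecError(f"n_samples must be >= 16, got {n_samples}")
    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(chord == 0):
        raise InvalidSpecError("coincident consecutive control points")
    t = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(t, pts, axis=0, bc_type=bc_type)
    samples = spline(np.linspace(0.0, t[-1], n_samples))
    return Centerline(samples)


# ---------------------------------------------------------------------------
# ring artifact
# ---------------------------------------------------------------------------

def add_ring_artifact(
    volume: Volume,
    mask: BinaryMask,
    amplitude: float,
    width: int,
    tissue_level: float | None = None,
) -> Volume:
    """Alternating bright/dark perturbation within ``width`` voxels of the mask boundary.

    Shell ``k`` (1-based integer distance from the boundary) is perturbed by
    ``±amplitude × tissue_level`` with the sign alternating between shells and
    flipping across the boundary; voxels further than ``width`` from the
    boundary are untouched.  ``amplitude = 0`` is the identity.
    """
    from scipy import ndimage as ndi

    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if width < 1:
        raise ValueError("width must be >= 1")
    if amplitude == 0:
        return volume.copy()
    if volume.shape != mask.shape:
        raise ValueError("volume and mask must share a grid")
    if tissue_level is None:
        tissue_level = float(volume.data[mask.data].mean()) if mask.data.any() else 1.0
    m = mask.data
    dist_in = ndi.distance_transform_edt(m)
    dist_out = ndi.distance_transform_edt(~m)
    out = volume.data.copy()
    for side, dist in ((1, dist_in), (-1, dist_out)):
        shell = np.ceil(dist).astype(int)
        band = (dist > 0) & (shell <= width)
        sign = side * np.where(shell % 2 == 1, 1.0, -1.0)
        out[band] += amplitude * tissue_level * sign[band]
    return volume.with_data(out)


# ---------------------------------------------------------------------------
# level defaults
# ---------------------------------------------------------------------------

_CORD_LEVELS_HIGH = {"background": 100.0, "medium": 100.0, "tissue": 180.0, "butterfly": 140.0}
_CORD_LEVELS_LOW = {"background": 20.0, "medium": 20.0, "tissue": 140.0, "butterfly": 90.0}
_BRAIN_LEVELS_HIGH = {
    "background": 100.0, "medium": 100.0, "tissue": 180.0,
    "ventricle": 30.0, "callosum": 240.0, "hippocampus": 205.0,
}
_BRAIN_LEVELS_LOW = {
    "background": 20.0, "medium": 20.0, "tissue": 140.0,
    "ventricle": 5.0, "callosum": 220.0, "hippocampus": 175.0,
}


def _default_cord_control_points(spec_extent: np.ndarray) -> tuple:
    # gentle S-bend in the x–z plane; the extra collinear points near the ends
    # keep the end tangents close to the z axis so the tube caps lie almost in
    # the xy-plane
    ex, ey, ez = spec_extent
    cx, cy = ex / 2, ey / 2
    return (
        (cx, cy, 0.06 * ez),
        (cx, cy, 0.14 * ez),
        (cx + 100.0, cy, 0.38 * ez),
        (cx - 100.0, cy, 0.62 * ez),
        (cx, cy, 0.86 * ez),
        (cx, cy, 0.94 * ez),
    )


def default_cord_spec(**overrides) -> PhantomSpec:
    """The study's default curved-cord phantom pair (ratio-4 modalities)."""
    defaults = dict(
        kind="cord",
        levels_high=dict(_CORD_LEVELS_HIGH),
        levels_low=dict(_CORD_LEVELS_LOW),
        true_rotation_deg=2.0,
        true_rotation_axis=(1.0, 0.0, 0.0),
        true_translation=(60.0, -40.0, 80.0),
        true_scale=1.0,
        warp_amplitude=150.0,
    )
    defaults.update(overrides)
    spec = PhantomSpec(**defaults)
    if not spec.control_points:
        spec.control_points = _default_cord_control_points(spec.extent_high())
    return spec


def default_brain_spec(**overrides) -> PhantomSpec:
    """The study's default brain phantom pair (known similarity misalignment)."""
    defaults = dict(
        kind="brain",
        shape_high=(192, 192, 192),
        spacing_high=(31.25, 31.25, 31.25),
        shape_low=(48, 48, 48),
        spacing_low=(125.0, 125.0, 125.0),
        levels_high=dict(_BRAIN_LEVELS_HIGH),
        levels_low=dict(_BRAIN_LEVELS_LOW),
        true_rotation_deg=8.0,
        true_rotation_axis=(0.0, 0.0, 1.0),
        true_translation=(300.0, -400.0, 0.0),
        true_scale=1.05,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


def _true_transform(spec: PhantomSpec) -> TrueTransform:
    """Build the low→high world mapping about the high-grid centre."""
    axis = np.asarray(spec.true_rotation_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    theta = np.deg2rad(spec.true_rotation_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
    c = spec.extent_high() / 2.0
    A = np.eye(4)
    A[:3, :3] = spec.true_scale * R
    A[:3, 3] = c - spec.true_scale * R @ c + np.asarray(spec.true_translation, dtype=float)
    ez = spec.extent_high()[2]
    return TrueTransform(affine=A, warp_amplitude=spec.warp_amplitude, z_range=(0.0, ez))


def _grid_world(shape, spacing) -> np.ndarray:
    axes = [np.arange(shape[a]) * spacing[a] for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return np.stack([X, Y, Z], axis=-1)


# ---------------------------------------------------------------------------
# cord phantom
# ---------------------------------------------------------------------------

def _cord_intensity(points: np.ndarray, tube: StraighteningTransform, spec: PhantomSpec,
                    levels: dict) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the cord geometry at arbitrary anatomy-frame points.

    Returns (intensity, tissue-indicator) arrays of the points' shape.
    """
    uvs = tube.world_to_straight(points)
    u, v = uvs[..., 0], uvs[..., 1]
    dist = np.hypot(u, v)
    r = spec.tube_radius
    # cap the tube at the curve endpoints: beyond them the nearest-arc-length
    # projection clamps, leaving an axial residual along the end tangent
    flat = np.asarray(points, dtype=float).reshape(-1, 3)
    s = tube.centerline.nearest_arclength(flat)
    c = tube.centerline.point_at(s)
    t, _, _ = tube.frame_at(s)
    axial = np.abs(np.sum((flat - c) * t, axis=-1)).reshape(points.shape[:-1])
    inside = (dist <= r) & (axial <= 0.5 * float(np.median(np.diff(tube.centerline.arclength))))
    # butterfly: two mirrored ellipses about the u = 0 (mid-sagittal) plane,
    # spanning a bit over half the cord radius as gray matter does
    u0, a_e, b_e = 0.25 * r, 0.30 * r, 0.22 * r
    fly = (((np.abs(u) - u0) / a_e) ** 2 + (v / b_e) ** 2) <= 1.0
    out = np.full(points.shape[:-1], levels["medium"], dtype=float)
    out[inside] = levels["tissue"]
    out[inside & fly] = levels["butterfly"]
    return out, inside


def render_cord_phantom(spec: PhantomSpec, curve: Centerline | None = None) -> PhantomPair:
    """Render the curved-cord phantom pair plus ground truth.

    The high-res volume is the tube rasterized in the anatomy frame with the
    ring artifact at the tissue–medium interface; the low-res volume samples
    the same geometry through the true inter-modality transform (different
    curvature via the bend term).  Landmarks sit on the centerline near the
    two extremities, as a rater would place them.
    """
    if spec.kind != "cord":
        raise InvalidSpecError(f"spec.kind must be 'cord', got {spec.kind!r}")
    if curve is None:
        cps = spec.control_points or _default_cord_control_points(spec.extent_high())
        # clamp the end tangents to the axial direction so the tube caps lie
        # flat in the xy-plane (no spline undershoot at the extremities)
        axial = ((1, (0.0, 0.0, 1.0)), (1, (0.0, 0.0, 1.0)))
        curve = make_cord_curve(cps, n_samples=max(256, 4 * spec.shape_high[2]), bc_type=axial)
    kmax = float(curve.curvature().max())
    if kmax > 0 and spec.tube_radius >= 1.0 / kmax:
        raise InvalidSpecError(
            f"tube radius {spec.tube_radius} >= minimal curvature radius {1.0 / kmax:.1f}"
        )
    # tube must stay inside the high-res grid
    ext = spec.extent_high()
    margin = curve.points - spec.tube_radius < 0
    margin |= curve.points + spec.tube_radius > ext
    bad = np.any(margin[:, :2], axis=1)  # caps may touch the axial faces
    if np.any(bad):
        s_bad = curve.arclength[int(np.argmax(bad))]
        raise InvalidSpecError(f"tube exits the grid first at arc length {s_bad:.1f} µm")

    tube = StraighteningTransform(
        curve, radius=min(spec.tube_radius * 2.0, 0.99 / max(kmax, 1e-12))
    )
    rng = np.random.default_rng(spec.seed)

    # high-res modality (anatomy frame)
    pts_h = _grid_world(spec.shape_high, spec.spacing_high)
    data_h, inside_h = _cord_intensity(pts_h, tube, spec, spec.levels_high)
    high = Volume(data_h, spacing=spec.spacing_high)
    mask_h = BinaryMask.like(high, inside_h, provenance="phantom truth (cord, high)")
    if spec.ring_amplitude > 0:
        high = add_ring_artifact(
            high, mask_h, spec.ring_amplitude, spec.ring_width,
            tissue_level=spec.levels_high["tissue"],
        )
    if spec.noise_sigma_high > 0:
        high = high.with_data(high.data + rng.normal(0, spec.noise_sigma_high, high.shape))

    # low-res modality through the true transform
    truth_tf = _true_transform(spec)
    pts_l = _grid_world(spec.shape_low, spec.spacing_low)
    mapped = truth_tf(pts_l)
    data_l, inside_l = _cord_intensity(mapped, tube, spec, spec.levels_low)
    low = Volume(data_l, spacing=spec.spacing_low)
    mask_l = BinaryMask.like(low, inside_l, provenance="phantom truth (cord, low)")
    if spec.noise_sigma_low > 0:
        low = low.with_data(low.data + rng.normal(0, spec.noise_sigma_low, low.shape))

    lm_s = np.array([0.05, 0.95]) * curve.total_length
    lm_high = curve.point_at(lm_s)
    lm_low = truth_tf.inverse_points(lm_high)
    cl_low = Centerline(truth_tf.inverse_points(curve.points))
    truth = GroundTruth(
        mask_high=mask_h,
        mask_low=mask_l,
        transform=truth_tf,
        landmarks_high=lm_high,
        landmarks_low=lm_low,
        centerline=curve,
        centerline_low=cl_low,
    )
    return PhantomPair(high=high, low=low, truth=truth)


# ---------------------------------------------------------------------------
# brain phantom
# ---------------------------------------------------------------------------

def _texture(points: np.ndarray, seed: int, n_waves: int = 6,
             wavelength_um: tuple[float, float] = (250.0, 700.0)) -> np.ndarray:
    """Deterministic smooth texture: a few random-phase plane waves.

    Defined as an analytic function of world coordinates so both modalities
    sample the *same* texture regardless of their grids.
    """
    rng = np.random.default_rng(seed)
    out = np.zeros(points.shape[:-1])
    for _ in range(n_waves):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        lam = rng.uniform(*wavelength_um)
        phase = rng.uniform(0, 2 * np.pi)
        out += np.sin(2 * np.pi * (points @ d) / lam + phase)
    return out / np.sqrt(n_waves)


def _brain_intensity(points: np.ndarray, spec: PhantomSpec, levels: dict,
                     texture_amp: float = 18.0) -> tuple[np.ndarray, np.ndarray]:
    ext = spec.extent_high()
    c = ext / 2.0
    semi = 0.90 * ext / 2.0
    rho = np.sqrt((((points - c) / semi) ** 2).sum(axis=-1))
    inside = rho <= 1.0
    out = np.full(points.shape[:-1], levels["medium"], dtype=float)
    out[inside] = levels["tissue"]

    # ventricle: dark ellipsoid offset anteriorly
    vc = c + np.array([0.18, 0.12, 0.0]) * ext
    vsemi = np.array([0.10, 0.08, 0.07]) * ext
    vent = np.sqrt((((points - vc) / vsemi) ** 2).sum(axis=-1)) <= 1.0
    # callosum: bright curved band — a dorsal shell of an inner ellipsoid
    csemi = semi * 0.62
    crho = np.sqrt((((points - c) / csemi) ** 2).sum(axis=-1))
    call = (crho >= 0.80) & (crho <= 1.0) & (points[..., 2] > c[2])
    # hippocampus: textured blob on the other side
    hc = c + np.array([-0.16, -0.10, -0.08]) * ext
    hsemi = np.array([0.14, 0.12, 0.10]) * ext
    hip = np.sqrt((((points - hc) / hsemi) ** 2).sum(axis=-1)) <= 1.0

    out[inside & call] = levels["callosum"]
    out[inside & hip] = levels["hippocampus"]
    out[inside & vent] = levels["ventricle"]
    if texture_amp > 0:
        # smooth intensity texture across the whole tissue (FA-like maps vary
        # everywhere, not only at structure boundaries), stronger in the
        # hippocampus blob; identical spatial pattern in both modalities
        tex = _texture(points, seed=spec.seed + 7919)
        sel = inside & ~vent
        out[sel] += texture_amp * tex[sel]
        out[inside & hip & ~vent] += 0.5 * texture_amp * tex[inside & hip & ~vent]
    return out, inside


def render_brain_phantom(spec: PhantomSpec) -> PhantomPair:
    """Render the brain phantom pair plus ground truth.

    Both modalities share the structural geometry (so intensities are strongly
    rank-correlated inside the sample); the ring artifact is added only to the
    high-res modality's sample–medium interface.  Landmarks are two interior
    points placed off the rotation axis near opposite extremities.
    """
    if spec.kind != "brain":
        raise InvalidSpecError(f"spec.kind must be 'brain', got {spec.kind!r}")
    ext = spec.extent_high()
    semi = 0.90 * ext / 2.0
    if np.any(semi + np.asarray(spec.spacing_high) * (spec.ring_width + 1) > ext / 2.0):
        raise InvalidSpecError("brain ellipsoid (plus artifact band) overlaps the grid boundary")

    rng = np.random.default_rng(spec.seed)
    pts_h = _grid_world(spec.shape_high, spec.spacing_high)
    data_h, inside_h = _brain_intensity(pts_h, spec, spec.levels_high)
    high = Volume(data_h, spacing=spec.spacing_high)
    mask_h = BinaryMask.like(high, inside_h, provenance="phantom truth (brain, high)")
    if spec.ring_amplitude > 0:
        high = add_ring_artifact(
            high, mask_h, spec.ring_amplitude, spec.ring_width,
            tissue_level=spec.levels_high["tissue"],
        )
    if spec.noise_sigma_high > 0:
        high = high.with_data(high.data + rng.normal(0, spec.noise_sigma_high, high.shape))

    truth_tf = _true_transform(spec)
    pts_l = _grid_world(spec.shape_low, spec.spacing_low)
    mapped = truth_tf(pts_l)
    data_l, inside_l = _brain_intensity(mapped, spec, spec.levels_low)
    low = Volume(data_l, spacing=spec.spacing_low)
    mask_l = BinaryMask.like(low, inside_l, provenance="phantom truth (brain, low)")
    if spec.noise_sigma_low > 0:
        low = low.with_data(low.data + rng.normal(0, spec.noise_sigma_low, low.shape))

    c = ext / 2.0
    lm_high = np.stack([
        c + np.array([0.55, 0.25, -0.45]) * semi,
        c + np.array([-0.45, -0.35, 0.55]) * semi,
    ])
    lm_low = truth_tf.inverse_points(lm_high)
    truth = GroundTruth(
        mask_high=mask_h,
        mask_low=mask_l,
        transform=truth_tf,
        landmarks_high=lm_high,
        landmarks_low=lm_low,
    )
    return PhantomPair(high=high, low=low, truth=truth)
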
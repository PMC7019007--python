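"""End-to-end orchestration of the two co-registration branches.

The **brain branch** assumes the two modalities share roughly the same
curvature: down-sample the high-resolution volume to the low-resolution grid,
mask both, then mutual-information affine (optionally + diffeomorphic)
registration in the native frame.

The **cord branch** cannot assume that: each modality's cord centerline is
extracted, both volumes are straightened into their own (u, v, s) frames, a
two-landmark arc-length alignment initializes an affine MI registration in
the straightened frame, and parametric maps can then be carried between the
curved and straight frames of either modality.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .core import BinaryMask, Centerline, Volume, dice
from .masking import brain_mask_pipeline, fill_holes_2d, keep_largest_component, threshold_otsu
from .centerline import (
    centerline_from_slices,
    detect_edges_3d,
    find_interior_seeds,
    region_grow_mask,
    resample_centerline,
)
from .phantom import PhantomSpec  # noqa: F401  (re-exported for config loading)
from .register import (
    AffineTransform,
    apply_transform,
    landmark_init,
    register_affine,
    register_diffeomorphic,
)
from .resample import antialias_downsample, nn_downsample, saturate_intensity, select_downsample_scale
from .straighten import straighten_volume, transform_for_volume, unstraighten_volume

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "run_brain_pipeline",
    "run_cord_pipeline",
    "brain_pipeline_volumes",
    "cord_pipeline_volumes",
    "write_report",
]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the run log."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


@dataclass
class PipelineConfig:
    """File-level configuration for one pipeline run (YAML-loadable)."""

    branch: str = "brain"  # brain | cord
    high_path: str = ""
    low_path: str = ""
    out_dir: str = "out"
    high_spacing_um: tuple | None = None  # required for TIFF inputs
    low_spacing_um: tuple | None = None
    band: str | tuple = "auto"
    dilate_radius: int = 2
    landmarks_high_path: str = ""
    landmarks_low_path: str = ""
    centerline_method: str = "com"  # com | grow
    straighten_radius_um: float | None = None
    downsample_candidates: tuple = (1, 2, 4)
    levels: int = 3
    iters_per_level: int = 120
    diffeo: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        if cfg.branch not in ("brain", "cord"):
            raise ValueError(f"branch must be 'brain' or 'cord', got {cfg.branch!r}")
        for name in ("high_path", "low_path"):
            p = getattr(cfg, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{name} = {p!r} does not exist")
        if cfg.branch == "cord":
            for name in ("landmarks_high_path", "landmarks_low_path"):
                p = getattr(cfg, name)
                if not p or not Path(p).exists():
                    raise FileNotFoundError(
                        f"cord branch requires {name}; {p!r} does not exist"
                    )
        return cfg


class _StageLog:
    def __init__(self) -> None:
        self.stages: list[dict] = []

    def run(self, name: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            self.stages.append({"stage": name, "status": "failed", "error": str(exc)})
            raise PipelineStageError(name, exc) from exc
        self.stages.append(
            {"stage": name, "status": "ok", "seconds": round(time.perf_counter() - t0, 3)}
        )
        return out


def _foreground_mask(volume: Volume) -> BinaryMask:
    """Otsu foreground, per-slice hole-filled, largest component."""
    t = threshold_otsu(volume)
    mask = BinaryMask.like(volume, volume.data > t, provenance=f"otsu>{t:.4g}")
    return keep_largest_component(fill_holes_2d(mask))


# ---------------------------------------------------------------------------
# brain branch
# ---------------------------------------------------------------------------

def brain_pipeline_volumes(
    high: Volume,
    low: Volume,
    landmarks_high: np.ndarray | None = None,
    landmarks_low: np.ndarray | None = None,
    band="auto",
    dilate_radius: int = 2,
    levels: int = 3,
    iters_per_level: int = 120,
    diffeo: bool = False,
    seed: int = 0,
    restore_native: bool = False,
) -> tuple[dict, dict]:
    """Run the brain branch on in-memory volumes.

    Returns ``(report, artifacts)``; artifacts holds the intermediate volumes,
    masks and transforms keyed by name.  With ``restore_native`` the
    registered low-resolution map is additionally resampled onto the
    *native* high-resolution grid (artifact ``moved_native``), restoring the
    tomogram's full resolution for downstream analysis.
    """
    log = _StageLog()
    fixed = log.run("antialias_downsample", antialias_downsample, high, low.spacing)
    mask_fixed = log.run("mask_high", brain_mask_pipeline, fixed, band, dilate_radius)
    mask_moving = log.run("mask_low", brain_mask_pipeline, low, "auto", dilate_radius)

    if landmarks_high is not None and landmarks_low is not None:
        init = log.run("landmark_init", landmark_init, landmarks_high, landmarks_low)
    else:
        init = AffineTransform.identity()

    moved_mask_pre = apply_transform(
        mask_moving.to_volume(), init, target_grid=fixed, interpolation="nearest"
    )
    dice_pre = dice(mask_fixed.data, moved_mask_pre.data > 0.5)

    res = log.run(
        "register_affine", register_affine, fixed, low,
        init=init, levels=levels, iters_per_level=iters_per_level, seed=seed,
    )
    transform = res.transform
    artifacts: dict = {
        "fixed": fixed, "mask_fixed": mask_fixed, "mask_moving": mask_moving,
        "affine": transform, "affine_result": res,
    }
    chain = [transform]
    if diffeo:
        dres = log.run(
            "register_diffeomorphic", register_diffeomorphic, fixed, low,
            init=transform, foreground=mask_fixed.data,
        )
        artifacts["diffeo_result"] = dres
        chain = [dres.transform, transform]

    moved = apply_transform(low, chain, target_grid=fixed)
    moved_mask = apply_transform(
        mask_moving.to_volume(), chain, target_grid=fixed, interpolation="nearest"
    )
    dice_post = dice(mask_fixed.data, moved_mask.data > 0.5)
    artifacts["moved"] = moved
    if restore_native:
        # the transform chain is world-based, so the same chain carries the
        # low-res map onto the native high-res grid
        artifacts["moved_native"] = apply_transform(low, chain, target_grid=high)

    report = {
        "branch": "brain",
        "seed": seed,
        "stages": log.stages,
        "dice_pre": round(dice_pre, 6),
        "dice_post": round(dice_post, 6),
        "affine_metric": res.metric_value,
        "affine_converged": res.converged,
        "affine_matrix": transform.matrix.tolist(),
        "metric_trace_length": len(res.trace),
    }
    if diffeo:
        report["diffeo_converged"] = artifacts["diffeo_result"].converged
        report["diffeo_message"] = artifacts["diffeo_result"].message
    return report, artifacts


# ---------------------------------------------------------------------------
# cord branch
# ---------------------------------------------------------------------------

def _extract_cord_centerline(
    volume: Volume, method: str, log: _StageLog
) -> tuple[Centerline, BinaryMask | None]:
    sigma = 1.5 * float(min(volume.spacing))
    edges = log.run("detect_edges_3d", detect_edges_3d, volume, sigma)
    cl_com = log.run("centerline_com", centerline_from_slices, edges)
    if method == "com":
        return cl_com, None
    if method != "grow":
        raise ValueError(f"centerline method must be 'com' or 'grow', got {method!r}")

    def grow():
        mid = cl_com.point_at(cl_com.total_length * 0.5)
        seeds = find_interior_seeds(edges, mid)
        union = np.zeros(edges.shape, bool)
        for s in seeds:
            union |= region_grow_mask(edges, s).data
        return fill_holes_2d(BinaryMask.like(edges, union, provenance="region_grow_union"))

    mask = log.run("region_grow_mask", grow)
    cl = log.run("centerline_grow", centerline_from_slices, mask)
    return cl, mask


def _landmark_arclengths(cl: Centerline, landmarks: np.ndarray) -> np.ndarray:
    return np.asarray(
        [float(cl.nearest_arclength(p.reshape(1, 3))[0]) for p in np.asarray(landmarks)]
    )


def _straight_axis_init(
    s_fixed: np.ndarray, s_moving: np.ndarray, allow_scale: bool = True
) -> AffineTransform:
    """Axial shift (+ optional axial scale) aligning landmark arc lengths."""
    a = (s_moving[1] - s_moving[0]) / (s_fixed[1] - s_fixed[0]) if allow_scale else 1.0
    m = np.eye(4)
    m[2, 2] = a
    m[2, 3] = s_moving[0] - a * s_fixed[0]
    return AffineTransform(m)


def cord_pipeline_volumes(
    high: Volume,
    low: Volume,
    landmarks_high: np.ndarray,
    landmarks_low: np.ndarray,
    method: str = "com",
    straighten_radius: float | None = None,
    downsample_candidates=(1, 2, 4),
    levels: int = 3,
    iters_per_level: int = 120,
    diffeo: bool = False,
    seed: int = 0,
    truth_centerline: Centerline | None = None,
) -> tuple[dict, dict]:
    """Run the cord branch on in-memory volumes.

    The high-resolution volume is saturated (0.3 % tails), NN-down-sampled at
    the gradient-maximizing factor, its centerline extracted (``com`` or
    ``grow`` route); both volumes are straightened and registered in the
    straightened frame, fixed = straightened high-resolution volume.
    """
    log = _StageLog()
    high_sat = log.run("saturate_intensity", saturate_intensity, high, 0.003, 0.003)

    def pick_factor():
        if len(downsample_candidates) < 2:
            return int(downsample_candidates[0])
        fg = _foreground_mask(high_sat)
        from scipy import ndimage as ndi

        boundary = fg.data ^ ndi.binary_erosion(fg.data)
        band = BinaryMask.like(high_sat, ndi.binary_dilation(boundary))
        zs = np.linspace(0, high_sat.shape[2] - 1, 7)[1:-1].astype(int)
        return select_downsample_scale(high_sat, list(downsample_candidates), band, list(zs))

    factor = log.run("select_downsample_scale", pick_factor)
    high_ds = log.run("nn_downsample", nn_downsample, high_sat, factor)

    cl_high, grow_mask = _extract_cord_centerline(high_ds, method, log)
    cl_high = resample_centerline(cl_high, step=5.0 * float(min(high_ds.spacing)))

    # low-resolution centerline from the Otsu foreground (dMRI maps have no
    # usable edge shell at this resolution)
    fg_low = log.run("mask_low", _foreground_mask, low)
    cl_low = log.run("centerline_low", centerline_from_slices, fg_low)
    cl_low = resample_centerline(cl_low, step=2.5 * float(min(low.spacing)))

    if straighten_radius is None:
        area = float(fg_low.data.sum(axis=(0, 1)).max()) * float(np.prod(low.spacing[:2]))
        straighten_radius = 1.2 * float(np.sqrt(area / np.pi))
    kmax = max(float(cl_high.curvature().max()), float(cl_low.curvature().max()))
    straighten_radius = min(straighten_radius, 0.9 / max(kmax, 1e-12))

    tf_high = transform_for_volume(cl_high, high, radius=straighten_radius)
    tf_low = transform_for_volume(cl_low, low, radius=straighten_radius)
    straight_high = log.run("straighten_high", straighten_volume, high, tf_high)
    straight_low = log.run("straighten_low", straighten_volume, low, tf_low)

    s_high = _landmark_arclengths(cl_high, landmarks_high)
    s_low = _landmark_arclengths(cl_low, landmarks_low)
    init = _straight_axis_init(s_high, s_low)

    # register at the low modality's scale
    fixed_reg = antialias_downsample(straight_high, np.maximum(straight_low.spacing, straight_high.spacing))
    res = log.run(
        "register_affine", register_affine, fixed_reg, straight_low,
        init=init, levels=levels, iters_per_level=iters_per_level, seed=seed,
    )
    transform = res.transform
    chain = [transform]
    artifacts: dict = {
        "factor": factor, "cl_high": cl_high, "cl_low": cl_low,
        "tf_high": tf_high, "tf_low": tf_low,
        "straight_high": straight_high, "straight_low": straight_low,
        "affine": transform, "affine_result": res, "grow_mask": grow_mask,
    }
    if diffeo:
        dres = log.run(
            "register_diffeomorphic", register_diffeomorphic, fixed_reg, straight_low,
            init=transform,
        )
        artifacts["diffeo_result"] = dres
        chain = [dres.transform, transform]

    # cord masks in the straightened frame, moving one carried through the fit
    mask_s_high = _foreground_mask(straight_high)
    mask_s_low = _foreground_mask(straight_low)
    moved_mask_pre = apply_transform(
        mask_s_low.to_volume(), init, target_grid=straight_high, interpolation="nearest"
    )
    moved_mask = apply_transform(
        mask_s_low.to_volume(), chain, target_grid=straight_high, interpolation="nearest"
    )
    dice_pre = dice(mask_s_high.data, moved_mask_pre.data > 0.5)
    dice_post = dice(mask_s_high.data, moved_mask.data > 0.5)
    moved = apply_transform(straight_low, chain, target_grid=straight_high)
    artifacts["moved_straight_low"] = moved
    artifacts["mask_straight_high"] = mask_s_high

    # straightness check: centerline of the straightened high volume should
    # hug the (u, v) = (0, 0) axis
    fg_sh = _foreground_mask(straight_high)
    cl_check = centerline_from_slices(fg_sh)
    straightness = float(np.hypot(cl_check.points[:, 0], cl_check.points[:, 1]).max())

    report = {
        "branch": "cord",
        "seed": seed,
        "stages": log.stages,
        "centerline_method": method,
        "downsample_factor": int(factor),
        "straighten_radius_um": float(straighten_radius),
        "dice_pre": round(dice_pre, 6),
        "dice_post": round(dice_post, 6),
        "straightness_max_lateral_um": round(straightness, 3),
        "affine_metric": res.metric_value,
        "affine_converged": res.converged,
        "affine_matrix": transform.matrix.tolist(),
    }
    if truth_centerline is not None:
        d = np.array(
            [
                np.linalg.norm(
                    truth_centerline.point_at(truth_centerline.nearest_arclength(p[None, :]))[0] - p
                )
                for p in cl_high.points
            ]
        )
        report["centerline_rms_um"] = round(float(np.sqrt((d**2).mean())), 3)
    if diffeo:
        report["diffeo_converged"] = artifacts["diffeo_result"].converged
    return report, artifacts


# ---------------------------------------------------------------------------
# file-level wrappers + report
# ---------------------------------------------------------------------------

def run_brain_pipeline(config: PipelineConfig) -> dict:
    high = cio.read_volume(config.high_path, config.high_spacing_um)
    low = cio.read_volume(config.low_path, config.low_spacing_um)
    lmh = lml = None
    if config.landmarks_high_path:
        lmh = cio.read_landmarks_csv(config.landmarks_high_path)
        lml = cio.read_landmarks_csv(config.landmarks_low_path)
    report, artifacts = brain_pipeline_volumes(
        high, low, landmarks_high=lmh, landmarks_low=lml,
        band=config.band, dilate_radius=config.dilate_radius,
        levels=config.levels, iters_per_level=config.iters_per_level,
        diffeo=config.diffeo, seed=config.seed,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cio.write_volume(artifacts["fixed"], out / "fixed.nii.gz")
    cio.write_volume(artifacts["moved"], out / "moved.nii.gz")
    cio.write_mask(artifacts["mask_fixed"], out / "mask_fixed.nii.gz")
    cio.write_mask(artifacts["mask_moving"], out / "mask_moving.nii.gz")
    cio.write_affine_txt(artifacts["affine"].matrix, out / "affine.txt")
    write_report(report, out, config)
    return report


def run_cord_pipeline(config: PipelineConfig) -> dict:
    high = cio.read_volume(config.high_path, config.high_spacing_um)
    low = cio.read_volume(config.low_path, config.low_spacing_um)
    lmh = cio.read_landmarks_csv(config.landmarks_high_path)
    lml = cio.read_landmarks_csv(config.landmarks_low_path)
    report, artifacts = cord_pipeline_volumes(
        high, low, lmh, lml,
        method=config.centerline_method,
        straighten_radius=config.straighten_radius_um,
        downsample_candidates=config.downsample_candidates,
        levels=config.levels, iters_per_level=config.iters_per_level,
        diffeo=config.diffeo, seed=config.seed,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cio.write_centerline_csv(artifacts["cl_high"], out / "centerline_high.csv")
    cio.write_centerline_csv(artifacts["cl_low"], out / "centerline_low.csv")
    cio.write_volume(artifacts["straight_high"], out / "straight_high.nii.gz")
    cio.write_volume(artifacts["straight_low"], out / "straight_low.nii.gz")
    cio.write_volume(artifacts["moved_straight_low"], out / "moved_straight_low.nii.gz")
    cio.write_affine_txt(artifacts["affine"].matrix, out / "affine_straight.txt")
    cio.write_straightening_transform(artifacts["tf_high"], out / "straighten_high.json")
    cio.write_straightening_transform(artifacts["tf_low"], out / "straighten_low.json")
    write_report(report, out, config)
    return report


def write_report(report: dict, out_dir, config: PipelineConfig | None = None) -> Path:
    """Write the JSON run report plus provenance (config, package version).

    Field order is deterministic (sorted keys); the timestamp is the only
    field expected to differ between two identical runs.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = dict(report)
    payload["software_version"] = __version__
    payload["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    if config is not None:
        payload["config"] = asdict(config)
    path = out / "report.json"
    path.write_text(json.dumps(payload, sort_keys=True, indent=2, default=_json_default))
    log_path = out / "run.log"
    lines = [f"{s['stage']}: {s['status']}" for s in report.get("stages", [])]
    log_path.write_text("\n".join(lines) + "\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
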
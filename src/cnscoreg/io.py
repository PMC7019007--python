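"""File I/O: NIfTI-1 and multi-page TIFF volumes, centerline/landmark CSVs,
affine matrices and straightening-transform sidecars.

World coordinates are µm throughout the package; NIfTI stores mm, so spacing
and origin are converted at this boundary (a 6 µm voxel is written as
pixdim 0.006).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import BinaryMask, Centerline, Volume
from .straighten import StraighteningTransform

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_centerline_csv",
    "write_centerline_csv",
    "read_affine_txt",
    "write_affine_txt",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "write_straightening_transform",
    "read_straightening_transform",
]

MM_PER_UM = 1e-3


def read_volume(path, spacing_override=None) -> Volume:
    """Read a 3D volume from NIfTI-1 (.nii/.nii.gz) or multi-page TIFF.

    Spacing comes from the NIfTI header (pixdim, mm → µm) unless
    ``spacing_override`` (µm) is given; TIFF carries no reliable spacing, so
    the override is mandatory there.  Data are cast to float64 and axes are
    (x, y, z).
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = np.asarray(tifffile.imread(path))
        if data.ndim != 3:
            raise ValueError(f"expected a 3D TIFF stack, got ndim={data.ndim}")
        # TIFF pages are z-slices: (z, y, x) → (x, y, z)
        data = np.transpose(data, (2, 1, 0))
        if spacing_override is None:
            raise ValueError("TIFF input requires an explicit voxel spacing (µm)")
        return Volume(data.astype(np.float64), spacing=np.asarray(spacing_override, float))

    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got ndim={data.ndim}")
    if spacing_override is not None:
        spacing = np.asarray(spacing_override, dtype=float)
    else:
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=float) / MM_PER_UM
    origin = np.asarray(img.affine[:3, 3], dtype=float) / MM_PER_UM
    return Volume(data, spacing=spacing, origin=origin)


def write_volume(volume: Volume, path) -> None:
    """Write a volume as NIfTI-1 with spacing in pixdim (mm) and origin in the sform."""
    import nibabel as nib

    affine = np.diag(np.append(volume.spacing * MM_PER_UM, 1.0))
    affine[:3, 3] = volume.origin * MM_PER_UM
    img = nib.Nifti1Image(volume.data, affine)
    img.header.set_zooms(tuple(volume.spacing * MM_PER_UM))
    nib.save(img, str(path))


def read_mask(path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.data > 0.5, vol.spacing, vol.origin, provenance=str(path))


def write_mask(mask: BinaryMask, path) -> None:
    write_volume(mask.to_volume(), path)


def write_centerline_csv(centerline: Centerline, path) -> None:
    """Columns: x_um, y_um, z_um, arclen_um."""
    arr = np.column_stack([centerline.points, centerline.arclength])
    np.savetxt(
        path, arr, delimiter=",", header="x_um,y_um,z_um,arclen_um", comments="", fmt="%.6f"
    )


def read_centerline_csv(path) -> Centerline:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return Centerline(arr[:, :3], arr[:, 3] if arr.shape[1] > 3 else None)


def write_affine_txt(matrix: np.ndarray, path) -> None:
    """4×4 row-major text matrix."""
    np.savetxt(path, np.asarray(matrix, dtype=float).reshape(4, 4), fmt="%.12g")


def read_affine_txt(path) -> np.ndarray:
    m = np.loadtxt(path)
    if m.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix in {path}, got shape {m.shape}")
    return m


def write_landmarks_csv(points: np.ndarray, path) -> None:
    np.savetxt(
        path, np.asarray(points, float).reshape(-1, 3), delimiter=",",
        header="x_um,y_um,z_um", comments="", fmt="%.6f",
    )


def read_landmarks_csv(path) -> np.ndarray:
    pts = np.loadtxt(path, delimiter=",", skiprows=1)
    return pts.reshape(-1, 3)


def write_straightening_transform(transform: StraighteningTransform, path) -> None:
    """Serialize as JSON: centerline samples, per-sample 3×3 frames (row-major),
    radius and grid steps."""
    payload = {
        "points_um": transform.centerline.points.tolist(),
        "arclength_um": transform.centerline.arclength.tolist(),
        "frames_row_major": transform.frames.reshape(-1, 9).tolist(),
        "radius_um": transform.radius,
        "in_plane_spacing_um": list(transform.in_plane_spacing),
        "axial_step_um": transform.axial_step,
    }
    Path(path).write_text(json.dumps(payload))


def read_straightening_transform(path) -> StraighteningTransform:
    payload = json.loads(Path(path).read_text())
    cl = Centerline(
        np.asarray(payload["points_um"]), np.asarray(payload["arclength_um"])
    )
    frames = np.asarray(payload["frames_row_major"]).reshape(-1, 3, 3)
    return StraighteningTransform(
        cl,
        frames=frames,
        radius=payload["radius_um"],
        in_plane_spacing=tuple(payload["in_plane_spacing_um"]),
        axial_step=payload["axial_step_um"],
    )
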
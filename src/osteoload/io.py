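"""File formats: TIFF/NIfTI volumes, 8-bit TIFF masks, CSV tables, YAML transforms.

Volumes travel as multi-page 32-bit float TIFF stacks (one page per
z-slice) or NIfTI-1; voxel size is carried in the TIFF ImageDescription /
the NIfTI zooms. Ground-truth and analysis masks are 8-bit TIFF (0/255).
Loading traces and Ct tables are header-row CSV. Rigid transforms are YAML
with rotation in degrees (Z-Y-X) and translation in mm, (z, y, x) ordered.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import RigidTransform, VolumeScan
from .loading_mechanics import LoadingProtocol, LoadingTrace

__all__ = [
    "write_volume",
    "read_volume",
    "write_mask",
    "read_mask",
    "write_trace",
    "read_trace",
    "write_transform",
    "read_transform",
    "write_ct_table",
    "read_ct_table",
]


def write_volume(path: str | Path, scan: VolumeScan) -> None:
    """Write a scan as float32 TIFF stack (.tif/.tiff) or NIfTI-1 (.nii[.gz])."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        meta = {
            "voxel_size_um": scan.voxel_size_um,
            "calibration": list(scan.calibration),
        }
        tifffile.imwrite(
            path, scan.voxels.astype(np.float32), description=json.dumps(meta)
        )
    elif path.name.lower().endswith((".nii", ".nii.gz")):
        vs = scan.voxel_size_mm
        affine = np.diag([vs, vs, vs, 1.0])
        img = nib.Nifti1Image(scan.voxels.astype(np.float32), affine)
        img.header.set_zooms((vs, vs, vs))
        nib.save(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")


def read_volume(
    path: str | Path, voxel_size_um: float | None = None
) -> VolumeScan:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            voxels = tf.asarray()
            vs, cal = voxel_size_um or 18.0, (1.0, 0.0)
            desc = tf.pages[0].description
            if desc:
                try:
                    meta = json.loads(desc)
                    vs = voxel_size_um or float(meta.get("voxel_size_um", vs))
                    cal = tuple(meta.get("calibration", cal))
                except (json.JSONDecodeError, TypeError):
                    pass
        return VolumeScan(voxels, vs, cal)
    if path.name.lower().endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        vs = voxel_size_um or float(img.header.get_zooms()[0]) * 1000.0
        return VolumeScan(np.asarray(img.dataobj, dtype=np.float32), vs)
    raise ValueError(f"unsupported volume format: {path.suffix}")


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Boolean voxel/pixel mask as 8-bit TIFF (255 = true)."""
    tifffile.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


def write_trace(path: str | Path, trace: LoadingTrace) -> None:
    pd.DataFrame(
        {
            "time_s": trace.time,
            "displacement_um": trace.displacement,
            "force_N": trace.force,
        }
    ).to_csv(path, index=False)


def read_trace(path: str | Path, protocol: LoadingProtocol) -> LoadingTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "displacement_um", "force_N"):
        if col not in df.columns:
            raise ValueError(f"trace CSV missing column {col!r}")
    return LoadingTrace(
        df["time_s"].to_numpy(),
        df["displacement_um"].to_numpy(),
        df["force_N"].to_numpy(),
        protocol,
    )


def write_transform(path: str | Path, transform: RigidTransform) -> None:
    payload = {
        "rotation_deg": list(transform.rotation_deg),
        "translation_mm": list(transform.translation_mm),
        "center": "grid_center",
        "euler_order": "ZYX",
        "axis_order": "zyx",
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_transform(path: str | Path) -> RigidTransform:
    payload = yaml.safe_load(Path(path).read_text())
    return RigidTransform(
        tuple(payload["rotation_deg"]), tuple(payload["translation_mm"])
    )


def write_ct_table(path: str | Path, ct_table: pd.DataFrame) -> None:
    ct_table.to_csv(path, index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "condition", "gene", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"Ct CSV must have columns {sorted(required)}")
    return df
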
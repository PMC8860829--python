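"""BaSO4-stained microdamage quantification (SV/BV) from serial scans.

BaSO4 precipitates inside microcracks and raises their X-ray density, so
damage shows up as voxels whose density *increased* between the unloaded
scan and the stained post-loading scan. The chain, run after rigid
registration of the three serial scans to the unloaded frame:

1. overlap mask of all three scans (voxels with valid data everywhere);
2. bone mask on the unloaded scan — density strictly above 560 mg HA/cm3;
3. analysis region: the bone mask closed (radius 2, to bridge lacunae and
   recover the solid explant footprint), intersected with the overlap mask,
   then eroded by 5 face-connected surface layers — the deletion that
   discards BaSO4 precipitated on the free surface, which does not
   represent microcracks;
4. voxel-wise BMD difference (stained - unloaded) inside the region;
5. stained volume SV: difference strictly above 300 native units, counted
   among unloaded-scan bone voxels (the unloaded scan predates loading, so
   every microcrack voxel is bone there; lacunar pores, which are not, can
   otherwise fake a density increase through interpolation smoothing);
6. bone volume BV: unloaded bone voxels in the same eroded region, so the
   SV/BV ratio's numerator and denominator share support.

Both thresholds use strict "above" comparisons; boundary values (exactly
560, exactly 300) do not qualify.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import RigidTransform, VolumeScan, ball_structuring_element as _ball, resample
from .registration import overlap_mask, register_rigid

__all__ = [
    "DamageConfig",
    "DamageResult",
    "calibrate_to_bmd",
    "decalibrate_from_bmd",
    "bone_mask",
    "erode_surface",
    "bmd_difference",
    "stained_volume",
    "quantify_damage",
]

BONE_THRESHOLD_MG_HA = 560.0
STAIN_THRESHOLD_NATIVE = 300.0
EROSION_LAYERS = 5


@dataclass(frozen=True)
class DamageConfig:
    """Tunable parameters of the damage chain (defaults as characterised)."""

    bone_threshold_mg_ha: float = BONE_THRESHOLD_MG_HA
    stain_threshold_native: float = STAIN_THRESHOLD_NATIVE
    erosion_layers: int = EROSION_LAYERS
    closing_radius: int = 2
    #: count SV within the unloaded bone mask (the default): the unloaded
    #: scan predates loading, so every future crack voxel is bone there,
    #: while lacunar pores — whose sharp unloaded profile against the
    #: interpolation-smoothed stained scan can fake a density increase —
    #: never are. Set True to count within the whole closed-bone region.
    sv_within_closed_bone: bool = False
    registration_levels: int = 3

    def __post_init__(self) -> None:
        if self.erosion_layers < 0:
            raise ValueError("erosion_layers must be >= 0")
        if self.closing_radius < 0:
            raise ValueError("closing_radius must be >= 0")


@dataclass
class DamageResult:
    """BV, SV and SV/BV with every mask that produced them."""

    bv_voxels: int
    sv_voxels: int
    bv_mm3: float
    sv_mm3: float
    sv_bv: float
    analysis_mask_voxels: int
    bone_threshold_mg_ha: float
    stain_threshold_native: float
    erosion_layers: int
    masks: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    transforms: dict[str, RigidTransform] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.sv_bv <= 1:
            raise ValueError("sv_bv must lie in [0, 1]")
        if self.sv_voxels > self.bv_voxels:
            raise ValueError("SV cannot exceed BV")

    def summary(self) -> dict[str, float]:
        return {
            "bv_mm3": self.bv_mm3,
            "sv_mm3": self.sv_mm3,
            "sv_bv": self.sv_bv,
            "bv_voxels": self.bv_voxels,
            "sv_voxels": self.sv_voxels,
            "analysis_mask_voxels": self.analysis_mask_voxels,
        }


def calibrate_to_bmd(scan: VolumeScan) -> VolumeScan:
    """Map native units to mg HA/cm3 through the scan's linear calibration."""
    slope, intercept = scan.calibration
    if slope == 0:
        raise ValueError("calibration slope must be nonzero")
    out = scan.copy()
    out.voxels = (scan.voxels * np.float32(slope)) + np.float32(intercept)
    out.calibration = (1.0, 0.0)
    return out


def decalibrate_from_bmd(
    scan: VolumeScan, calibration: tuple[float, float]
) -> VolumeScan:
    """Inverse of :func:`calibrate_to_bmd` for a given (slope, intercept)."""
    slope, intercept = calibration
    if slope == 0:
        raise ValueError("calibration slope must be nonzero")
    out = scan.copy()
    out.voxels = (scan.voxels - np.float32(intercept)) / np.float32(slope)
    out.calibration = calibration
    return out


def bone_mask(
    bmd: VolumeScan, threshold: float = BONE_THRESHOLD_MG_HA
) -> tuple[np.ndarray, int]:
    """Bone = voxels with density strictly above the threshold (560 default).

    Returns the mask and the bone voxel count (BV in voxels); only valid
    voxels can be bone.
    """
    mask = (bmd.voxels > threshold) & bmd.validity
    return mask, int(mask.sum())


def erode_surface(mask: np.ndarray, layers: int = EROSION_LAYERS) -> np.ndarray:
    """Delete ``layers`` one-voxel surface layers (6-connected erosion).

    Each iteration removes one voxel of depth from every face; the result
    is always a subset of the input. ``layers = 0`` is the identity.
    """
    if layers < 0:
        raise ValueError("layers must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if layers == 0:
        return mask.copy()
    struct = ndimage.generate_binary_structure(3, 1)
    return ndimage.binary_erosion(mask, struct, iterations=layers)


def bmd_difference(
    stained_scan: VolumeScan, unloaded_scan: VolumeScan, mask: np.ndarray
) -> np.ndarray:
    """Voxel-wise (stained - unloaded) in native units, zero outside mask."""
    if stained_scan.shape != unloaded_scan.shape:
        raise ValueError("scans must be registered to the same grid")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stained_scan.shape:
        raise ValueError("mask grid does not match the scans")
    if not mask.any():
        raise ValueError("mask is empty")
    diff = np.zeros(stained_scan.shape, dtype=np.float32)
    diff[mask] = stained_scan.voxels[mask] - unloaded_scan.voxels[mask]
    return diff


def stained_volume(
    diff: np.ndarray,
    bone: np.ndarray,
    threshold: float = STAIN_THRESHOLD_NATIVE,
) -> tuple[np.ndarray, int]:
    """SV = voxels of ``bone`` whose difference is strictly above threshold."""
    bone = np.asarray(bone, dtype=bool)
    mask = (np.asarray(diff) > threshold) & bone
    return mask, int(mask.sum())


def quantify_damage(
    unloaded: VolumeScan,
    loaded: VolumeScan,
    stained: VolumeScan,
    transforms: dict[str, RigidTransform] | None = None,
    config: DamageConfig = DamageConfig(),
    seed: int = 0,
) -> DamageResult:
    """Full SV/BV chain on one explant's serial-scan triplet.

    ``transforms`` maps scan roles (``"loaded"``, ``"stained"``) to
    transforms onto the unloaded frame; missing transforms are computed by
    :func:`~osteoload.registration.register_rigid`. Every intermediate mask
    is retained in the result for audit.
    """
    if not (unloaded.shape == loaded.shape == stained.shape):
        raise ValueError("the three scans must share one grid")
    transforms = dict(transforms or {})
    for role, scan in (("loaded", loaded), ("stained", stained)):
        if role not in transforms:
            transforms[role] = register_rigid(
                unloaded,
                scan,
                levels=config.registration_levels,
                seed=seed,
                # the loaded/stained scans genuinely differ from the
                # unloaded reference (cracks, stain); keep those structural
                # outliers from steering the alignment
                trim_fraction=0.05,
            ).transform
    transforms["unloaded"] = transforms.get("unloaded", RigidTransform())

    loaded_r = resample(loaded, transforms["loaded"])
    stained_r = resample(stained, transforms["stained"])
    unloaded_r = resample(unloaded, transforms["unloaded"])

    overlap = overlap_mask(
        [unloaded, loaded, stained],
        [transforms["unloaded"], transforms["loaded"], transforms["stained"]],
    )

    bmd_u = calibrate_to_bmd(unloaded_r)
    bone, _ = bone_mask(bmd_u, config.bone_threshold_mg_ha)
    if not bone.any():
        raise ValueError("stage bone_mask: no bone voxels above threshold")

    # explant footprint: close surface dents, then fill enclosed cavities
    # (lacunar pore clusters) of any size so the surface erosion removes
    # true surface layers instead of eating around interior holes
    closed = ndimage.binary_closing(
        bone, structure=_ball(config.closing_radius)
    ) if config.closing_radius > 0 else bone
    closed = ndimage.binary_fill_holes(closed)
    analysis = erode_surface(closed & overlap, config.erosion_layers)
    if not analysis.any():
        raise ValueError(
            "stage erode_surface: eroded analysis region is empty"
        )

    diff = bmd_difference(stained_r, unloaded_r, analysis)
    sv_region = analysis if config.sv_within_closed_bone else (analysis & bone)
    # (bone is computed on the unloaded scan, which predates loading: crack
    # voxels are bone there, so restricting SV to bone does not miss cracks)
    sv_mask, sv_vox = stained_volume(diff, sv_region, config.stain_threshold_native)
    bv_mask = bone & analysis
    bv_vox = int(bv_mask.sum())
    if bv_vox == 0:
        raise ValueError("stage bone_volume: no bone voxels in analysis region")

    vv = unloaded.voxel_volume_mm3
    return DamageResult(
        bv_voxels=bv_vox,
        sv_voxels=sv_vox,
        bv_mm3=bv_vox * vv,
        sv_mm3=sv_vox * vv,
        sv_bv=sv_vox / bv_vox,
        analysis_mask_voxels=int(analysis.sum()),
        bone_threshold_mg_ha=config.bone_threshold_mg_ha,
        stain_threshold_native=config.stain_threshold_native,
        erosion_layers=config.erosion_layers,
        masks={
            "overlap": overlap,
            "bone": bone,
            "analysis": analysis,
            "stained": sv_mask,
            "bone_in_analysis": bv_mask,
        },
        transforms=transforms,
    )
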
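"""Shared voxel-grid containers and rigid-body geometry.

Conventions used throughout the package:

* Volumes are indexed ``(z, y, x)`` with 0-based, half-open voxel indexing.
* World coordinates are ``voxel index x voxel size`` with the origin at the
  grid corner; all voxels are isotropic.
* Rigid transforms rotate about the geometric center of the grid (Euler
  Z-Y-X, degrees) and then translate (mm, ordered ``(z, y, x)``).
* "Native units" are the scanner's raw density values; the default
  calibration (slope 1, intercept 0) defines them as numerically equal to
  mg HA/cm3, so the 560 mg HA/cm3 bone threshold and the 300 native-unit
  stain threshold live on the same scale unless a real calibration is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

__all__ = [
    "VolumeScan",
    "RigidTransform",
    "ExplantGeometry",
    "resample",
    "transform_error",
    "ball_structuring_element",
]


def ball_structuring_element(radius: int) -> np.ndarray:
    """Digital ball of the given voxel radius (the radius-0 ball is a point)."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return np.ones((1, 1, 1), dtype=bool)
    zz, yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1, -radius : radius + 1]
    return zz**2 + yy**2 + xx**2 <= radius**2

# permutation between (z, y, x) storage order and the (x, y, z) order
# scipy.spatial.transform works in
_P = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rigid-body map: rotate about the grid center, then translate.

    Parameters
    ----------
    rotation_deg
        Euler angles ``(rz, ry, rx)`` in degrees, applied intrinsically in
        Z-Y-X order about the grid center.
    translation_mm
        Translation ``(tz, ty, tx)`` in mm.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation_deg, dtype=float)
        t = np.asarray(self.translation_mm, dtype=float)
        if r.shape != (3,) or t.shape != (3,):
            raise ValueError("rotation and translation must be 3-vectors")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(t))):
            raise ValueError("transform parameters must be finite")
        object.__setattr__(self, "rotation_deg", tuple(float(v) for v in r))
        object.__setattr__(self, "translation_mm", tuple(float(v) for v in t))

    @property
    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix acting on (z, y, x) vectors."""
        rz, ry, rx = self.rotation_deg
        r_xyz = Rotation.from_euler("ZYX", [rz, ry, rx], degrees=True).as_matrix()
        return _P @ r_xyz @ _P  # _P is its own inverse

    @property
    def translation(self) -> np.ndarray:
        return np.asarray(self.translation_mm, dtype=float)

    def apply(self, points_mm: np.ndarray, center_mm: np.ndarray) -> np.ndarray:
        """Map world points (..., 3) forward: R(p - c) + c + t."""
        p = np.asarray(points_mm, dtype=float)
        c = np.asarray(center_mm, dtype=float)
        return (p - c) @ self.matrix.T + c + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        ra, rb = self.matrix, other.matrix
        r = ra @ rb
        t = ra @ other.translation + self.translation
        return RigidTransform(_euler_zyx_from_matrix(r), tuple(t))

    def inverse(self) -> "RigidTransform":
        r_inv = self.matrix.T
        t_inv = -r_inv @ self.translation
        return RigidTransform(_euler_zyx_from_matrix(r_inv), tuple(t_inv))

    @property
    def rotation_angle_deg(self) -> float:
        """Total rotation angle (degrees) of the transform."""
        cos = (np.trace(self.matrix) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))

    def is_identity(self, atol: float = 1e-9) -> bool:
        return (
            np.allclose(self.matrix, np.eye(3), atol=atol)
            and np.allclose(self.translation, 0.0, atol=atol)
        )


def _euler_zyx_from_matrix(m_zyx: np.ndarray) -> tuple[float, float, float]:
    r_xyz = _P @ m_zyx @ _P
    rz, ry, rx = Rotation.from_matrix(r_xyz).as_euler("ZYX", degrees=True)
    return (float(rz), float(ry), float(rx))


def transform_error(
    a: RigidTransform, b: RigidTransform
) -> tuple[float, np.ndarray]:
    """Discrepancy between two transforms.

    Returns ``(rotation_angle_deg, |translation difference| per axis in mm)``
    of the residual ``a ∘ b⁻¹``; both are 0 when the transforms agree.
    """
    delta = a.compose(b.inverse())
    return delta.rotation_angle_deg, np.abs(delta.translation)


@dataclass
class VolumeScan:
    """A 3D micro-CT scan: attenuation in native units on an isotropic grid.

    ``calibration = (slope, intercept)`` maps native units to mg HA/cm3.
    ``validity`` marks voxels carrying real data; resampling flags voxels
    pulled from outside the source grid as invalid and they are excluded
    from similarity metrics and analysis masks.
    """

    voxels: np.ndarray
    voxel_size_um: float = 18.0
    calibration: tuple[float, float] = (1.0, 0.0)
    validity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D (z, y, x) array")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be > 0")
        if self.calibration[0] == 0:
            raise ValueError("calibration slope must be nonzero")
        if self.validity is None:
            self.validity = np.ones(self.voxels.shape, dtype=bool)
        else:
            self.validity = np.asarray(self.validity, dtype=bool)
            if self.validity.shape != self.voxels.shape:
                raise ValueError("validity grid must be congruent with voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**3

    @property
    def center_mm(self) -> np.ndarray:
        """World coordinates of the grid center (center of voxel centers)."""
        return (np.array(self.shape, dtype=float) - 1.0) / 2.0 * self.voxel_size_mm

    def copy(self) -> "VolumeScan":
        return VolumeScan(
            self.voxels.copy(),
            self.voxel_size_um,
            self.calibration,
            self.validity.copy(),
        )

    def with_voxels(self, voxels: np.ndarray) -> "VolumeScan":
        return replace(self, voxels=np.asarray(voxels, dtype=np.float32))


@dataclass(frozen=True)
class ExplantGeometry:
    """Cortical explant dimensions (mm) for three-point bending.

    ``loading_length`` is the span between the two holding points; the
    default explant measures 8.0 x 3.0 x 1.5 mm with a 6.0 mm span.
    """

    length: float = 8.0
    width: float = 3.0
    thickness_end1: float = 1.5
    thickness_end2: float = 1.5
    thickness_center: float = 1.5
    loading_length: float = 6.0

    def __post_init__(self) -> None:
        dims = (
            self.length,
            self.width,
            self.thickness_end1,
            self.thickness_end2,
            self.thickness_center,
            self.loading_length,
        )
        if any(d <= 0 for d in dims):
            raise ValueError("all explant dimensions must be > 0")
        if self.loading_length > self.length:
            raise ValueError("loading_length cannot exceed explant length")

    @property
    def mean_thickness(self) -> float:
        return (self.thickness_end1 + self.thickness_end2 + self.thickness_center) / 3.0


def resample(
    moving: VolumeScan,
    transform: RigidTransform,
    *,
    order: int = 1,
    cval: float = 0.0,
) -> VolumeScan:
    """Resample ``moving`` so the object appears moved forward by ``transform``.

    The output voxel at world position x takes the source value at
    ``transform⁻¹(x)`` (trilinear interpolation by default). Voxels whose
    source position falls outside the grid, or lands on invalid source
    voxels, are flagged invalid.
    """
    if transform.is_identity():
        return moving.copy()
    vs = moving.voxel_size_mm
    c_vox = (np.array(moving.shape, dtype=float) - 1.0) / 2.0
    t_vox = transform.translation / vs
    r_inv = transform.matrix.T
    # output index o samples input at  r_inv @ o + offset
    offset = c_vox - r_inv @ (c_vox + t_vox)
    out = ndimage.affine_transform(
        moving.voxels, r_inv, offset=offset, order=order, mode="constant", cval=cval
    )
    # in-grid support: a voxel is valid only when every trilinear source
    # neighbor is in-grid (ones-volume pulled back stays exactly 1 there)
    support = ndimage.affine_transform(
        np.ones(moving.shape, dtype=np.float32),
        r_inv,
        offset=offset,
        order=1,
        mode="constant",
        cval=0.0,
    )
    valid = support > 1.0 - 1e-5
    if not moving.validity.all():
        src_valid = ndimage.affine_transform(
            moving.validity.astype(np.uint8),
            r_inv,
            offset=offset,
            order=0,
            mode="constant",
            cval=0,
        )
        valid &= src_valid.astype(bool)
    return VolumeScan(out, moving.voxel_size_um, moving.calibration, valid)
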
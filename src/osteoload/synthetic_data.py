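"""Synthetic inputs with known ground truth for every pipeline stage.

No public scan archive exists for this kind of experiment, so validation is
done on phantoms: cortical-explant micro-CT volumes in the three serial
states (unloaded, loaded, loaded+BaSO4-stained) with planted microcracks,
free-surface stain precipitation, scanner noise and a rigid misalignment
between states; sinusoidal three-point-bending displacement/force traces;
2D stained sections with known positive/total lacuna counts; and paired
qPCR Ct tables with a housekeeping gene. Every generator is bit-reproducible
for a fixed seed and returns the ground truth the analysis is later judged
against.

The phantom emulates the *reconstructed* scan directly: bone voxels draw
their density from a normal distribution well above the 560 mg HA/cm3 bone
threshold, lacunar pores and microcracks sit well below it, BaSO4 raises
stained voxels additively, and Gaussian noise models the scanner. X-ray
projection physics (beam hardening, ring artifacts) is not simulated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ExplantGeometry, RigidTransform, VolumeScan, resample
from .loading_mechanics import (
    LoadingProtocol,
    LoadingTrace,
    sinusoidal_waveform,
    strain_to_displacement,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "explant_shape_voxels",
    "generate_explant_volume",
    "registration_validation_spec",
    "damage_validation_spec",
    "insert_microcracks",
    "insert_axis_aligned_crack",
    "apply_baso4_staining",
    "simulate_scan",
    "generate_scan_triplet",
    "generate_loading_trace",
    "generate_section_image",
    "SectionImage",
    "CellCounts",
    "generate_ct_table",
]

#: density (native units) written into pores, lacunae and fresh microcracks;
#: far below the 560 mg HA/cm3 bone threshold.
CAVITY_DENSITY = 150.0


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one explant phantom and its serial-scan triplet.

    Defaults describe a healthy cortical explant: mean matrix density
    900 mg HA/cm3 (sd 40), ~3% lacunar porosity, scanner noise 18 native
    units (2% of the matrix density). ``stain_increment`` is chosen so a
    stained crack sits ~600 native units above the unloaded matrix
    (crack cavity 150 + increment 1350 - matrix 900), i.e. the 300-unit
    stain threshold lies at half the step height.
    """

    geometry: ExplantGeometry = field(default_factory=ExplantGeometry)
    voxel_size_um: float = 18.0
    bone_density_mean: float = 900.0  # mg HA/cm3 == native units
    bone_density_sd: float = 40.0
    pore_fraction: float = 0.03
    crack_count: int = 6
    crack_thickness: int = 3  # voxels
    crack_extent: int = 12  # in-plane half-extent, voxels
    stain_increment: float = 1350.0  # native units
    surface_stain_depth: int = 4  # voxels
    noise_sd: float = 18.0  # native units
    misalignment: RigidTransform = field(default_factory=RigidTransform)
    margin_voxels: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bone_density_mean <= 560:
            raise ValueError("bone_density_mean must exceed the 560 bone threshold")
        if not 0 <= self.pore_fraction < 1:
            raise ValueError("pore_fraction must lie in [0, 1)")
        if self.crack_count < 0 or self.crack_thickness < 1:
            raise ValueError("crack_count >= 0 and crack_thickness >= 1 required")
        if self.stain_increment and self.stain_increment <= 300:
            raise ValueError(
                "stain_increment must exceed the 300-unit stain threshold"
            )
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be > 0")
        if self.noise_sd < 0 or self.surface_stain_depth < 0 or self.margin_voxels < 0:
            raise ValueError("noise_sd, surface_stain_depth, margin_voxels must be >= 0")


@dataclass
class GroundTruth:
    """What was actually planted in a phantom.

    ``true_sv_bv`` is the planted stained-crack fraction evaluated exactly
    the way the damage pipeline reports it: stained crack voxels inside the
    5-layer-eroded explant interior over bone voxels in that interior.
    """

    crack_mask: np.ndarray
    stained_mask: np.ndarray
    bone_mask: np.ndarray
    explant_mask: np.ndarray
    true_sv_bv: float = 0.0
    applied_transforms: dict[str, RigidTransform] = field(default_factory=dict)

    def recompute_sv_bv(self, erosion_layers: int = 5) -> float:
        """Planted interior stained fraction by direct voxel count."""
        struct = ndimage.generate_binary_structure(3, 1)
        interior = ndimage.binary_erosion(
            self.explant_mask, struct, iterations=erosion_layers
        )
        # cracks are carved out of bone, so unloaded-state bone (the BV
        # denominator) is the current bone mask plus the crack voxels
        unloaded_bone = self.bone_mask | self.crack_mask
        denom = int((unloaded_bone & interior).sum())
        if denom == 0:
            raise ValueError("no bone interior survives the erosion")
        num = int((self.crack_mask & interior).sum())
        self.true_sv_bv = num / denom
        return self.true_sv_bv


def explant_shape_voxels(
    geometry: ExplantGeometry, voxel_size_um: float = 18.0
) -> tuple[int, int, int]:
    """Explant footprint in voxels, (z, y, x) = (thickness, width, length).

    Each dimension is the number of voxels needed to cover the physical
    extent (ceiling of mm / voxel size); 8.0 x 3.0 x 1.5 mm at 18 µm gives
    (84, 167, 445).
    """
    vs_mm = voxel_size_um / 1000.0
    t = (geometry.thickness_end1 + geometry.thickness_end2 + geometry.thickness_center) / 3.0
    return (
        math.ceil(t / vs_mm - 1e-9),
        math.ceil(geometry.width / vs_mm - 1e-9),
        math.ceil(geometry.length / vs_mm - 1e-9),
    )


def generate_explant_volume(spec: PhantomSpec) -> tuple[VolumeScan, GroundTruth]:
    """The unloaded-state phantom: solid cortical slab with lacunar pores.

    Bone voxels draw ~Normal(bone_density_mean, bone_density_sd); a
    ``pore_fraction`` of explant voxels is carved to cavity density;
    background (outside the explant) is 0. Deterministic for a fixed seed.
    """
    fp = explant_shape_voxels(spec.geometry, spec.voxel_size_um)
    if min(fp) < 12:
        raise ValueError(
            f"explant footprint {fp} has a dimension below 12 voxels; too small "
            "to delete 5 surface layers and retain an interior"
        )
    rng = np.random.default_rng(spec.seed)
    m = spec.margin_voxels
    shape = tuple(s + 2 * m for s in fp)
    explant = np.zeros(shape, dtype=bool)
    explant[m : m + fp[0], m : m + fp[1], m : m + fp[2]] = True

    voxels = np.zeros(shape, dtype=np.float32)
    n_explant = int(explant.sum())
    density = rng.normal(spec.bone_density_mean, spec.bone_density_sd, n_explant)
    voxels[explant] = density.astype(np.float32)

    bone = explant.copy()
    if spec.pore_fraction > 0:
        # lacunae are embedded in matrix: keep pores >= 2 voxels below the
        # cut surface rather than modeling open surface pits
        struct = ndimage.generate_binary_structure(3, 1)
        embedded = ndimage.binary_erosion(explant, struct, iterations=2)
        pores = embedded & (rng.random(shape) < spec.pore_fraction)
        voxels[pores] = CAVITY_DENSITY
        bone[pores] = False

    scan = VolumeScan(voxels, spec.voxel_size_um)
    truth = GroundTruth(
        crack_mask=np.zeros(shape, dtype=bool),
        stained_mask=np.zeros(shape, dtype=bool),
        bone_mask=bone,
        explant_mask=explant,
    )
    return scan, truth


def insert_axis_aligned_crack(
    volume: VolumeScan,
    truth: GroundTruth,
    corner: tuple[int, int, int],
    size: tuple[int, int, int],
    value: float = CAVITY_DENSITY,
) -> tuple[VolumeScan, GroundTruth]:
    """Plant one axis-aligned slab crack with exactly known voxel extent.

    The slab is clipped to the bone mask; a clipped slab logs a warning.
    """
    out = volume.copy()
    sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
    slab = np.zeros(volume.shape, dtype=bool)
    slab[sl] = True
    requested = int(slab.sum())
    slab &= truth.bone_mask
    if int(slab.sum()) < requested:
        logger.warning(
            "crack clipped to bone: %d of %d voxels kept", int(slab.sum()), requested
        )
    out.voxels[slab] = value
    truth.crack_mask |= slab
    b = truth.bone_mask.copy()
    b[slab] = False
    truth.bone_mask = b
    return out, truth


def _random_slab(
    shape: tuple[int, int, int],
    center: np.ndarray,
    normal: np.ndarray,
    half_thickness: float,
    half_extent: float,
) -> np.ndarray:
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    rel = np.stack([zz - center[0], yy - center[1], xx - center[2]], axis=-1).astype(
        np.float32
    )
    dist_n = np.abs(rel @ normal)
    in_plane = np.linalg.norm(rel - dist_n[..., None] * normal, axis=-1)
    return (dist_n <= half_thickness) & (in_plane <= half_extent)


def insert_microcracks(
    volume: VolumeScan, truth: GroundTruth, spec: PhantomSpec
) -> tuple[VolumeScan, GroundTruth]:
    """Plant ``crack_count`` randomly oriented planar slab cracks in bone.

    Crack voxels are set to cavity density (below the bone threshold);
    cracks never extend outside the bone mask (clipping logs a warning).
    Deterministic for the spec seed.
    """
    if spec.crack_count == 0:
        return volume, truth
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    out = volume.copy()
    struct = ndimage.generate_binary_structure(3, 1)
    # keep crack centers clear of the surface so most planted volume
    # survives the 5-layer interior erosion
    deep = ndimage.binary_erosion(truth.explant_mask, struct, iterations=7)
    candidates = np.argwhere(deep & truth.bone_mask)
    if candidates.size == 0:
        raise ValueError("explant too small to host interior cracks")
    for _ in range(spec.crack_count):
        center = candidates[rng.integers(len(candidates))]
        v = rng.normal(size=3)
        normal = (v / np.linalg.norm(v)).astype(np.float32)
        slab = _random_slab(
            volume.shape,
            center.astype(np.float32),
            normal,
            spec.crack_thickness / 2.0,
            float(spec.crack_extent),
        )
        requested = int(slab.sum())
        slab &= truth.bone_mask
        if int(slab.sum()) < requested:
            logger.warning(
                "crack clipped to bone: %d of %d voxels kept",
                int(slab.sum()),
                requested,
            )
        out.voxels[slab] = CAVITY_DENSITY
        truth.crack_mask |= slab
        b = truth.bone_mask.copy()
        b[slab] = False
        truth.bone_mask = b
    return out, truth


def apply_baso4_staining(
    volume: VolumeScan, truth: GroundTruth, spec: PhantomSpec
) -> tuple[VolumeScan, GroundTruth]:
    """Additive BaSO4 model: cracks and the free-surface shell gain density.

    ``stain_increment`` native units are added to every crack voxel (BaSO4
    precipitated in microcracks) and to all explant voxels within
    ``surface_stain_depth`` layers of the free surface (precipitate the
    5-layer deletion is designed to discard).
    """
    out = volume.copy()
    shell = np.zeros(volume.shape, dtype=bool)
    if spec.surface_stain_depth > 0:
        struct = ndimage.generate_binary_structure(3, 1)
        interior = ndimage.binary_erosion(
            truth.explant_mask, struct, iterations=spec.surface_stain_depth
        )
        shell = truth.explant_mask & ~interior
    stained = truth.crack_mask | shell
    out.voxels[stained] += np.float32(spec.stain_increment)
    truth.stained_mask = stained
    return out, truth


def simulate_scan(
    volume: VolumeScan,
    transform: RigidTransform,
    noise_sd: float,
    seed: int,
) -> VolumeScan:
    """One scanner acquisition: rigid repositioning plus Gaussian noise.

    The object is moved forward by ``transform`` (trilinear resampling;
    voxels mapped from outside the source grid are flagged invalid) and
    independent Gaussian noise of sd ``noise_sd`` native units is added.
    Deterministic for a fixed seed.
    """
    out = resample(volume, transform)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out.voxels = out.voxels + rng.normal(0.0, noise_sd, out.shape).astype(
            np.float32
        )
    return out


def generate_scan_triplet(
    spec: PhantomSpec,
) -> tuple[VolumeScan, VolumeScan, VolumeScan, GroundTruth]:
    """The full serial-scan experiment on one phantom.

    Returns (unloaded, loaded, stained) scans plus ground truth. The
    unloaded scan defines the reference frame (identity transform); the
    loaded scan is misaligned by half the spec misalignment and the stained
    scan by the full misalignment, emulating three separate mountings.
    ``truth.true_sv_bv`` is the planted interior stained fraction.
    """
    base, truth = generate_explant_volume(spec)
    loaded_vol, truth = insert_microcracks(base, truth, spec)
    stained_vol, truth = apply_baso4_staining(loaded_vol, truth, spec)

    half = RigidTransform(
        tuple(r / 2.0 for r in spec.misalignment.rotation_deg),
        tuple(t / 2.0 for t in spec.misalignment.translation_mm),
    )
    seeds = np.random.SeedSequence([spec.seed, 2]).generate_state(3)
    unloaded = simulate_scan(base, RigidTransform(), spec.noise_sd, int(seeds[0]))
    loaded = simulate_scan(loaded_vol, half, spec.noise_sd, int(seeds[1]))
    stained = simulate_scan(stained_vol, spec.misalignment, spec.noise_sd, int(seeds[2]))
    truth.applied_transforms = {
        "unloaded": RigidTransform(),
        "loaded": half,
        "stained": spec.misalignment,
    }
    truth.recompute_sv_bv()
    return unloaded, loaded, stained, truth


def registration_validation_spec(seed: int = 0, noise_sd: float = 18.0) -> PhantomSpec:
    """Standard phantom for transform-recovery validation: ~64³ grid.

    A 44 x 40 x 36 voxel explant (18 µm voxels) with 5% lacunar porosity as
    registration texture, no cracks, 11-voxel air margin so misalignments up
    to ~10 voxels translation / 5 degrees keep the explant in-grid. Noise
    default 18 native units = 2% of the matrix density.
    """
    vs = 18e-3
    geom = ExplantGeometry(
        length=44 * vs,
        width=40 * vs,
        thickness_end1=36 * vs,
        thickness_end2=36 * vs,
        thickness_center=36 * vs,
        loading_length=30 * vs,
    )
    return PhantomSpec(
        geometry=geom,
        pore_fraction=0.05,
        crack_count=0,
        noise_sd=noise_sd,
        margin_voxels=11,
        seed=seed,
    )


def damage_validation_spec(
    seed: int = 0,
    noise_sd: float = 18.0,
    misalignment: RigidTransform | None = None,
) -> PhantomSpec:
    """Standard phantom for SV/BV ground-truth recovery: ~2% planted damage.

    A 1.2 x 0.9 x 0.7 mm explant (67 x 50 x 39 voxels at 18 µm) with three
    slab cracks sized so the interior stained fraction lands near 0.02, a
    4-layer free-surface stain shell, and by default a misalignment of
    2 degrees about z plus (1, 2, -2) voxels translation between the
    unloaded and stained mountings.
    """
    vs = 18e-3
    if misalignment is None:
        misalignment = RigidTransform((2.0, 0.0, 0.0), (1 * vs, 2 * vs, -2 * vs))
    geom = ExplantGeometry(
        length=1.2,
        width=0.9,
        thickness_end1=0.7,
        thickness_end2=0.7,
        thickness_center=0.7,
        loading_length=0.9,
    )
    return PhantomSpec(
        geometry=geom,
        pore_fraction=0.03,
        crack_count=3,
        crack_thickness=3,
        crack_extent=8,
        stain_increment=1350.0,
        surface_stain_depth=4,
        noise_sd=noise_sd,
        misalignment=misalignment,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# loading traces
# ---------------------------------------------------------------------------


def generate_loading_trace(
    protocol: LoadingProtocol,
    stiffness: float,
    contact_decay: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> LoadingTrace:
    """Simulated loading session on a linear-elastic explant.

    The displacement channel is the commanded sinusoid scaled by a linear
    amplitude-decay envelope reaching ``1 - contact_decay`` at session end;
    the force channel is ``preload + stiffness x displacement`` (N, with
    stiffness in N/µm) plus Gaussian sensor noise.
    """
    if stiffness <= 0:
        raise ValueError("stiffness must be > 0")
    if not 0 <= contact_decay < 1:
        raise ValueError("contact_decay must lie in [0, 1)")
    amplitude = strain_to_displacement(protocol.geometry, protocol.target_strain)
    trace = sinusoidal_waveform(protocol, amplitude)
    envelope = 1.0 - contact_decay * trace.time / protocol.duration
    disp = trace.displacement * envelope
    force = protocol.preload + stiffness * disp
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        force = force + rng.normal(0.0, noise_sd, force.shape)
    return LoadingTrace(trace.time, disp, force, protocol)


# ---------------------------------------------------------------------------
# stained sections
# ---------------------------------------------------------------------------

#: grayscale rendering intensities for synthetic sections
SECTION_BACKGROUND = 20.0
SECTION_EMPTY = 100.0
SECTION_POSITIVE = 220.0


@dataclass
class SectionImage:
    """A 2D stained bone section (single- or multi-channel)."""

    pixels: np.ndarray
    pixel_size_um: float = 1.0
    stain_channel: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be 2D or 2D multi-channel")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def stain_plane(self) -> np.ndarray:
        if self.pixels.ndim == 2:
            return self.pixels
        return self.pixels[..., self.stain_channel]


@dataclass(frozen=True)
class CellCounts:
    """Positive / total lacuna counts with the derived percentage."""

    positive: int
    total: int

    def __post_init__(self) -> None:
        if not 0 <= self.positive <= self.total:
            raise ValueError("need 0 <= positive <= total")

    @property
    def fraction_percent(self) -> float:
        if self.total == 0:
            raise ValueError("fraction undefined for zero total count")
        return 100.0 * self.positive / self.total


def generate_section_image(
    width: int,
    height: int,
    n_total: int,
    n_positive: int,
    seed: int = 0,
    *,
    radius_px: int = 4,
    pixel_size_um: float = 1.0,
) -> tuple[SectionImage, CellCounts]:
    """Render ``n_total`` non-overlapping disk lacunae, ``n_positive`` stained.

    Positive lacunae carry the positive-stain intensity, the rest the
    empty-lacuna intensity, on a uniform background. Raises if the requested
    count cannot be placed without overlap.
    """
    if not 0 <= n_positive <= n_total:
        raise ValueError("need 0 <= n_positive <= n_total")
    rng = np.random.default_rng(seed)
    img = np.full((height, width), SECTION_BACKGROUND, dtype=np.float32)
    yy, xx = np.mgrid[0:height, 0:width]
    centers: list[tuple[float, float]] = []
    min_sep = 2 * radius_px + 2
    attempts = 0
    while len(centers) < n_total:
        attempts += 1
        if attempts > 200 * max(n_total, 1):
            raise ValueError(
                f"could not place {n_total} non-overlapping lacunae on a "
                f"{width}x{height} section"
            )
        cy = rng.uniform(radius_px + 1, height - radius_px - 1)
        cx = rng.uniform(radius_px + 1, width - radius_px - 1)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep**2 for y, x in centers):
            centers.append((cy, cx))
    for i, (cy, cx) in enumerate(centers):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2
        img[disk] = SECTION_POSITIVE if i < n_positive else SECTION_EMPTY
    return (
        SectionImage(img, pixel_size_um),
        CellCounts(positive=n_positive, total=n_total),
    )


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def generate_ct_table(
    genes: list[str],
    n_pairs: int,
    effect_log2: dict[str, float] | float = 0.0,
    ct_sd: float = 0.25,
    seed: int = 0,
    *,
    housekeeping_gene: str = "TBP",
    base_ct: float = 25.0,
    between_sample_sd: float = 1.0,
) -> pd.DataFrame:
    """Paired control/treated Ct table with a housekeeping gene.

    For each sample and gene the treated Ct is ``control Ct - effect_log2 +
    noise`` (a positive effect means higher expression, i.e. fewer cycles);
    the housekeeping gene is generated with effect 0. Columns:
    sample_id, condition, gene, ct.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    if ct_sd < 0:
        raise ValueError("ct_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if not isinstance(effect_log2, dict):
        effect_log2 = {g: float(effect_log2) for g in genes}
    all_genes = list(genes)
    if housekeeping_gene not in all_genes:
        all_genes.append(housekeeping_gene)
    rows = []
    for s in range(n_pairs):
        sample = f"S{s + 1}"
        for gene in all_genes:
            effect = 0.0 if gene == housekeeping_gene else effect_log2.get(gene, 0.0)
            ct_control = base_ct + rng.normal(0.0, between_sample_sd)
            ct_treated = ct_control - effect + rng.normal(0.0, ct_sd) if ct_sd > 0 else ct_control - effect
            rows.append((sample, "control", gene, ct_control))
            rows.append((sample, "treated", gene, ct_treated))
    df = pd.DataFrame(rows, columns=["sample_id", "condition", "gene", "ct"])
    df.attrs["housekeeping_gene"] = housekeeping_gene
    return df
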
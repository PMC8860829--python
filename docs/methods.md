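# Methods

This note records the models, conventions and numerical choices behind
`osteoload`, and what the phantom-based validation does and does not show.

## Coordinate and unit conventions

Volumes are `(z, y, x)` arrays with 0-based half-open indexing; world
coordinates are voxel index × voxel size with the origin at the grid
corner; voxels are isotropic (18 µm default). Rigid transforms are Euler
Z-Y-X rotations (degrees) about the geometric grid center followed by a
translation in mm, ordered `(z, y, x)`. `simulate_scan(volume, T)` moves
the object forward by `T`; `register_rigid` returns the transform that
resamples the moving scan onto the fixed grid, i.e. the inverse of the
planted misalignment — oracle comparisons therefore use
`planted.inverse()`.

Scanner "native units" are defined as numerically equal to mg HA/cm³
(calibration slope 1, intercept 0) unless a calibration is supplied on the
`VolumeScan`. This puts the 560 mg HA/cm³ bone threshold and the 300
native-unit stain threshold on one scale while keeping a real calibration
expressible.

## Three-point bending

Peak surface strain and central deflection of a beam of thickness *t* on a
span *L* are related by ε = 12·c·δ/L² with c = t/2, i.e. δ = ε·L²/(6t);
thickness is the mean of the two end measurements and the center
measurement. The span between the holding points is not a property of the
explant and defaults to 6.0 mm (8 mm explant minus seating), configurable
on `ExplantGeometry`; all worked examples state their span. The commanded
waveform is d(t) = (A/2)(1 − cos 2πft): displacement starts at zero (the
indenter resting at pre-load contact) and rises first, so the pre-load
force is the trough of every cycle.

Two QC percentages summarise a session. *Contact preservation* is the
trough force of the final cycle over the pre-load: contact loss manifests
as the indenter returning past the contact point, dropping the trough
below the pre-load. *Displacement preservation* is the peak amplitude
(max − min per cycle window) of the cycle containing the session midpoint
over the first cycle's amplitude — an amplitude measure rather than an
instantaneous value, so it is phase-independent and comparable across
frequencies. Both are undefined (and raise) for zero pre-load or fewer
than two cycles.

## Rigid registration

Serial scans of one explant on one scanner share a modality, so the
similarity metric is the mean squared intensity difference. The search is
multi-resolution (block-mean pyramid, factors 4/2/1) Powell minimisation
over the six parameters, translations parametrised in fine-grid voxels so
all parameters move on comparable scales; one deterministic seeded
multi-start perturbation per coarse level guards against shallow minima.

Three robustness measures shape the *internal* objective only (the public
`similarity_msd` and the reported `final_similarity` are plain MSD over
the valid overlap):

- the metric is evaluated on fixed-scan foreground voxels, eroded a few
  layers below the object surface (after closing over lacunae). This
  prevents two failure modes observed during development: whole-volume MSD
  preferring to slide the object out of view (background matches
  background), and free-surface stain dragging the alignment;
- the largest 5% of squared differences can be trimmed
  (`trim_fraction`); the damage chain uses this when registering the
  loaded/stained scans, whose planted cracks and stain are true structural
  outliers that should not steer the alignment;
- the search is soft-bounded (|rotation| ≤ 20°, |translation| ≤ half the
  grid), since serial-mounting misalignments are small; this keeps
  Powell's unbounded line searches out of the 180° symmetry basin of a
  near-cuboidal explant.

Both volumes are pre-smoothed (Gaussian, σ = 0.8 voxel) for the objective
only: this suppresses the noise/interpolation artifact that otherwise
biases rotations by a few tenths of a degree, without moving the geometric
optimum. A result whose full-volume MSD is worse than the initial
alignment is rejected in favour of the identity (flagged not-converged),
so registration never worsens an alignment it accepts.

Validity propagates through every resampling: an output voxel is valid
only if all eight trilinear source neighbours are in-grid and valid
(implemented by interpolating with NaN fill). The all-scans overlap mask
is the conjunction of the three resampled validity grids.

## Microdamage (SV/BV)

After registration to the unloaded frame: bone is every voxel strictly
above 560 mg HA/cm³ on the unloaded scan ("above" is implemented strictly;
exactly 560 is not bone, and the same strictness applies at 300). The
analysis region is the bone mask closed with a radius-2 ball and
hole-filled (recovering the solid explant footprint across lacunae),
intersected with the overlap mask, then eroded by five 6-connected
surface layers — one voxel of depth per iteration on flat faces, which is
what makes the 30×20×12 → 20×10×2 box example exact. This deletion is what
discards BaSO₄ precipitated on free surfaces, which does not represent
microcracks.

SV is the count of voxels whose (stained − unloaded) difference strictly
exceeds 300 native units, counted **within the unloaded bone mask**
intersected with the analysis region. The unloaded scan predates loading,
so every future crack voxel is bone there; lacunar pores never are. This
support matters: against a twice-resampled (hence interpolation-smoothed)
stained scan, a sharp one-voxel pore in the unloaded reference produces a
spurious positive difference well above 300, and counting SV on the whole
closed footprint roughly doubled SV on misaligned phantoms. The
closed-footprint variant remains available
(`DamageConfig.sv_within_closed_bone`). BV uses the same eroded region, so
numerator and denominator share support and SV ≤ BV structurally.

## Phantoms

Phantoms are generated directly in reconstructed-volume space (no
projection physics, no beam hardening or ring artifacts): matrix density
~N(900, 40) mg HA/cm³, background 0, additive Gaussian scanner noise
(default 18 native units, 2% of matrix density — the study reports no
noise statistics, so these are plausible rather than fitted). Lacunar
pores are single voxels at 150 native units, placed ≥2 voxels below the
cut surface (lacunae are embedded structures, not open surface pits).
Microcracks are randomly oriented planar slabs carved out of bone;
staining adds a fixed increment to crack voxels and to a uniform
free-surface shell — exactly the artifact the 5-layer deletion removes.
The default increment (1350) puts a stained crack 600 units above the
unloaded matrix, so the 300-unit threshold sits at half the step height
and threshold-crossing approximately conserves crack volume under
interpolation.

Two standard validation conditions are packaged: a ~64³ registration
phantom (5% porosity as texture, 11-voxel margin so |t| ≤ 10 voxels and
|r| ≤ 5° stay in-grid) and a 1.2 × 0.9 × 0.7 mm damage phantom whose three
slab cracks plant an interior stained fraction near 0.02, scanned with a
2° / (1, 2, −2)-voxel misalignment. These sizes keep full runs in minutes
on one CPU; the generators accept the full 8.0 × 3.0 × 1.5 mm geometry
unchanged. Every generator draws all randomness from one explicit seed and
is bit-reproducible.

What passing phantom tests shows — and does not. They show the chain is
self-consistent and recovers planted truth under noise, misalignment and
surface artifacts of the modelled kind. They do not show robustness to
beam hardening, patchy/partial staining chemistry, real lacunar
morphology, or human-vs-automated counting differences on real histology;
donor-level biological percentages are not reproducible from synthetic
data and are not claimed.

## Sections and counting

Synthetic sections render non-overlapping disks at three grayscale levels
(background 20, empty lacuna 100, positive 220). Counting thresholds at
intensity 60, classifies components by mean intensity against 160, and
rejects objects under 5 px². Fractions are invariant under joint intensity
scaling of image and thresholds. The three areas of interest are equal
squares realising the target area (2.94 or 2.16 mm²) within pixel
rounding: one flush with each section end, one centered, vertically
centered; pooling across areas sums counts rather than averaging
fractions.

## Expression and statistics

Relative expression is 2^ΔCt with ΔCt = Ct_housekeeping − Ct_gene (TBP
reference), so higher expression gives larger values and one cycle of
earlier amplification doubles the value. The unpaired t-test defaults to
Welch (no equal-variance assumption), with the pooled variant available;
for two groups the ANOVA F equals the pooled t². Degenerate inputs
(zero-variance differences or identical constant groups) are flagged
rather than returning NaN: t = 0 / p = 1 for no effect, ±∞ / p → 0 for a
constant nonzero shift. p-values are clamped into (0, 1]. No
multiple-testing correction is applied — comparisons are reported per gene
and per contrast, which mirrors how such panels are usually read but
inflates family-wise error when many genes are scanned.

## Numerical choices

Trilinear interpolation everywhere (order-1 splines need no prefilter and
preserve integer-shift exactness); nearest-neighbour for validity.
Closing radius 2 for footprint recovery; fill-holes handles pore clusters
larger than the closing element. Powell tolerances: xtol 0.03 × level
factor (voxels/degrees), 15 iterations at coarse levels, 6 at the finest.
The footprint voxelisation rounds up (ceil of mm / voxel size), giving the
documented 84 × 167 × 445 grid for the default explant. Dose–response
fitting on a constant response returns slope 0, R² 0, p 1 explicitly
rather than propagating the undefined correlation.

## Known limitations

Registration assumes small rigid misalignment of a mostly-rigid object;
it has no deformable component and is untested on strongly truncated
fields of view. The SV threshold inherits the study design's empirical
300-unit noise ceiling; on a scanner with a different native-unit scale
both thresholds must be recalibrated together. The lacuna counter is a
threshold/connected-components device validated on synthetic sections
only. The expression module implements plain 2^ΔCt — no primer-efficiency
correction and no ΔΔCt calibrator design.
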
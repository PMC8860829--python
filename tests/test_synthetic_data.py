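"""Phantom, trace, section and Ct-table generators and their ground truth."""

import numpy as np
import pytest
from scipy import ndimage

from osteoload.core import ExplantGeometry, RigidTransform
from osteoload.loading_mechanics import LoadingProtocol, displacement_to_strain
from osteoload.synthetic_data import (
    CAVITY_DENSITY,
    PhantomSpec,
    apply_baso4_staining,
    damage_validation_spec,
    explant_shape_voxels,
    generate_ct_table,
    generate_explant_volume,
    generate_loading_trace,
    generate_scan_triplet,
    generate_section_image,
    insert_axis_aligned_crack,
    insert_microcracks,
    simulate_scan,
)
from osteoload.expression_stats import expression_table


def _small_spec(**kw):
    vs = 18e-3
    geom = ExplantGeometry(
        length=30 * vs, width=24 * vs, thickness_end1=16 * vs,
        thickness_end2=16 * vs, thickness_center=16 * vs, loading_length=20 * vs,
    )
    defaults = dict(geometry=geom, pore_fraction=0.0, bone_density_sd=0.0,
                    noise_sd=0.0, crack_count=0, seed=3, margin_voxels=6)
    defaults.update(kw)
    return PhantomSpec(**defaults)


def test_default_explant_footprint_matches_18um_grid():
    assert explant_shape_voxels(ExplantGeometry(), 18.0) == (84, 167, 445)


def test_noise_free_phantom_is_uniform_bone():
    vol, truth = generate_explant_volume(_small_spec())
    assert np.all(vol.voxels[truth.explant_mask] == 900.0)
    assert np.all(vol.voxels[~truth.explant_mask] == 0.0)
    np.testing.assert_array_equal(truth.bone_mask, truth.explant_mask)


def test_phantom_generation_is_deterministic():
    spec = damage_validation_spec(seed=5)
    a = generate_scan_triplet(spec)
    b = generate_scan_triplet(spec)
    for x, y in zip(a[:3], b[:3]):
        np.testing.assert_array_equal(x.voxels, y.voxels)
    assert a[3].true_sv_bv == b[3].true_sv_bv


def test_too_small_explant_is_rejected():
    vs = 18e-3
    geom = ExplantGeometry(length=30 * vs, width=24 * vs, thickness_end1=10 * vs,
                           thickness_end2=10 * vs, thickness_center=10 * vs,
                           loading_length=20 * vs)
    with pytest.raises(ValueError, match="below 12 voxels"):
        generate_explant_volume(PhantomSpec(geometry=geom))


def test_zero_cracks_leaves_volume_unchanged():
    spec = _small_spec()
    vol, truth = generate_explant_volume(spec)
    out, truth = insert_microcracks(vol, truth, spec)
    np.testing.assert_array_equal(out.voxels, vol.voxels)
    assert truth.crack_mask.sum() == 0


def test_axis_aligned_slab_has_exact_voxel_count():
    vol, truth = generate_explant_volume(_small_spec())
    out, truth = insert_axis_aligned_crack(vol, truth, corner=(8, 8, 8), size=(1, 10, 20))
    assert truth.crack_mask.sum() == 200
    assert np.all(out.voxels[truth.crack_mask] < 560.0)


def test_random_cracks_stay_inside_bone_and_below_threshold():
    spec = damage_validation_spec(seed=9, noise_sd=0.0, misalignment=RigidTransform())
    vol, truth = generate_explant_volume(spec)
    explant_bone = truth.bone_mask.copy()
    out, truth = insert_microcracks(vol, truth, spec)
    assert truth.crack_mask.sum() > 0
    assert not (truth.crack_mask & ~explant_bone).any()
    assert np.all(out.voxels[truth.crack_mask] < 560.0)


def test_zero_stain_increment_is_identity():
    spec = _small_spec(stain_increment=0.0)
    vol, truth = generate_explant_volume(spec)
    out, truth = apply_baso4_staining(vol, truth, spec)
    np.testing.assert_array_equal(out.voxels, vol.voxels)


def test_stain_is_additive_on_crack_voxels():
    spec = _small_spec(stain_increment=400.0)
    vol, truth = generate_explant_volume(spec)
    vol, truth = insert_axis_aligned_crack(vol, truth, (8, 8, 8), (1, 4, 4), value=100.0)
    out, truth = apply_baso4_staining(vol, truth, spec)
    assert np.all(out.voxels[truth.crack_mask] == 500.0)


def test_surface_shell_count_matches_erosion_oracle():
    depth = 5
    spec = _small_spec(stain_increment=400.0, surface_stain_depth=depth)
    vol, truth = generate_explant_volume(spec)
    out, truth = apply_baso4_staining(vol, truth, spec)
    nz, ny, nx = explant_shape_voxels(spec.geometry, spec.voxel_size_um)
    expected_shell = nz * ny * nx - (nz - 2 * depth) * (ny - 2 * depth) * (nx - 2 * depth)
    assert truth.stained_mask.sum() == expected_shell


def test_simulate_scan_identity_no_noise_is_exact():
    vol, _ = generate_explant_volume(_small_spec())
    out = simulate_scan(vol, RigidTransform(), noise_sd=0.0, seed=0)
    np.testing.assert_array_equal(out.voxels, vol.voxels)


def test_simulate_scan_is_deterministic():
    vol, _ = generate_explant_volume(_small_spec())
    t = RigidTransform((1.0, 0, 0), (0.01, 0.02, 0.0))
    a = simulate_scan(vol, t, noise_sd=10.0, seed=11)
    b = simulate_scan(vol, t, noise_sd=10.0, seed=11)
    np.testing.assert_array_equal(a.voxels, b.voxels)


def test_stained_interior_volume_conserved_under_rigid_motion():
    # planted stained interior volume is invariant (within interpolation
    # tolerance) under any in-grid rigid transform
    spec = damage_validation_spec(seed=4, noise_sd=0.0, misalignment=RigidTransform())
    _, _, stained, truth = generate_scan_triplet(spec)
    from osteoload.core import VolumeScan, resample

    mask_vol = VolumeScan(truth.crack_mask.astype(np.float32), 18.0)
    t = RigidTransform((3.0, -1.0, 2.0), (0.02, -0.03, 0.04))
    moved = resample(mask_vol, t)
    n0 = truth.crack_mask.sum()
    n1 = (moved.voxels > 0.5).sum()
    assert abs(n1 - n0) / n0 < 0.02


def test_loading_trace_peak_force_matches_stiffness_line():
    geom = ExplantGeometry(loading_length=6.0)
    strain = displacement_to_strain(geom, 100.0)  # amplitude exactly 100 um
    protocol = LoadingProtocol(target_strain=strain, frequency=1.0, duration=10.0,
                               preload=1.0, sample_rate=100.0, geometry=geom)
    trace = generate_loading_trace(protocol, stiffness=0.02, contact_decay=0.0,
                                   noise_sd=0.0, seed=0)
    assert np.isclose(trace.force.max(), 3.0)  # 1 + 0.02 * 100
    # peak reached once per cycle
    peaks = [trace.force[(trace.time >= k) & (trace.time < k + 1)].max() for k in range(10)]
    assert np.allclose(peaks, 3.0)


def test_zero_amplitude_trace_holds_preload():
    protocol = LoadingProtocol(target_strain=0.0, duration=5.0)
    trace = generate_loading_trace(protocol, stiffness=0.02)
    assert np.all(trace.force == protocol.preload)


def test_loading_trace_deterministic_for_fixed_seed():
    protocol = LoadingProtocol(duration=5.0)
    a = generate_loading_trace(protocol, 0.02, 0.05, noise_sd=0.1, seed=3)
    b = generate_loading_trace(protocol, 0.02, 0.05, noise_sd=0.1, seed=3)
    np.testing.assert_array_equal(a.force, b.force)


@pytest.mark.parametrize("n_total,n_positive", [(100, 76), (50, 50), (30, 0)])
def test_section_ground_truth_counts(n_total, n_positive):
    image, counts = generate_section_image(600, 400, n_total, n_positive, seed=2)
    assert (counts.positive, counts.total) == (n_positive, n_total)
    if n_positive == 0:
        assert not (image.pixels > 150).any()
    if n_total > 0 and n_positive == n_total:
        assert (image.pixels > 150).any() and not (
            (image.pixels > 60) & (image.pixels < 150)
        ).any()


def test_overcrowded_section_is_rejected():
    with pytest.raises(ValueError, match="non-overlapping"):
        generate_section_image(60, 60, 200, 0, seed=0)


def test_ct_table_zero_effect_zero_noise_gives_equal_expression():
    table = generate_ct_table(["SOST"], 4, effect_log2=0.0, ct_sd=0.0, seed=1)
    expr = expression_table(table)
    wide = expr.pivot(index="sample_id", columns="condition", values="expression")
    np.testing.assert_allclose(wide["treated"], wide["control"])


def test_ct_table_unit_effect_doubles_expression():
    table = generate_ct_table(["SOST"], 4, effect_log2=1.0, ct_sd=0.0, seed=1)
    expr = expression_table(table)
    wide = expr.pivot(index="sample_id", columns="condition", values="expression")
    np.testing.assert_allclose(wide["treated"], 2.0 * wide["control"])


def test_ct_table_deterministic():
    a = generate_ct_table(["SOST", "FGF23"], 5, 0.5, 0.25, seed=8)
    b = generate_ct_table(["SOST", "FGF23"], 5, 0.5, 0.25, seed=8)
    assert a.equals(b)
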
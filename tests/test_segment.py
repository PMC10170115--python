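import numpy as np
import pytest

from enteromap.imaging import render_cross_section, render_wholemount
from enteromap.points import PointPattern, generate_point_pattern
from enteromap.segment import (MeasurementError, colocalize, depth_projection,
                               estimate_neuron_count_by_area,
                               measure_muscle_thickness, nuclear_density,
                               segment_neurons, soma_depths, subtype_fraction)


def test_all_zero_image_gives_empty_flagged_result():
    with pytest.warns(UserWarning):
        seg, pat = segment_neurons(np.zeros((1, 64, 64)), pixel_size=1.0)
    assert seg.n == 0
    assert seg.degenerate
    assert pat.n == 0


def test_three_disks_round_trip(rendered_field):
    pattern, truth, stack, rt = rendered_field
    seg, rec = segment_neurons(stack, channel="HuC/D")
    assert seg.n == pattern.n
    from scipy.spatial import cKDTree

    d, _ = cKDTree(pattern.points).query(rec.points)
    assert np.sqrt((d ** 2).mean()) < 1.0     # centroid RMSE < 1 px


def test_touching_somata_split_by_watershed():
    pat = PointPattern(points=[(90.0, 100.0), (100.0, 100.0)],
                      window=(200.0, 200.0))
    stack, _ = render_wholemount(pat, seed=1)
    seg, _ = segment_neurons(stack, split_touching=True)
    assert seg.n == 2
    seg_nosplit, _ = segment_neurons(stack, split_touching=False)
    assert seg_nosplit.n == 1


def test_area_count_unit_and_errors():
    mask = np.zeros((50, 50), dtype=bool)
    mask[:,:] = False
    mask.ravel()[:138] = True            # exactly 138 px at 1 um/px
    assert estimate_neuron_count_by_area(mask, 138.0, pixel_size=1.0) == 1.0
    assert estimate_neuron_count_by_area(np.zeros((10, 10), bool),
                                         pixel_size=1.0) == 0.0
    with pytest.raises(ValueError):
        estimate_neuron_count_by_area(mask, unit_area=0.0, pixel_size=1.0)


def test_area_count_tracks_true_n(rendered_field):
    _, _, stack, _ = rendered_field
    seg, _ = segment_neurons(stack, channel="HuC/D")
    est = estimate_neuron_count_by_area(seg)
    assert abs(est - 50) <= 5            # within 10% of true n


def test_colocalize_identity_and_empty(rendered_field):
    _, _, stack, _ = rendered_field
    ref = stack.single("HuC/D")
    n = colocalize(ref, ref, reference_channel="HuC/D",
                   subtype_channel="HuC/D")
    assert n == 50                       # A AND A has A's components
    noise = np.random.default_rng(0).normal(20, 2, size=(1, 800, 800))
    assert colocalize(ref, np.maximum(noise, 0), reference_channel="HuC/D",
                      pixel_size=1.0) == 0


def test_colocalize_shape_mismatch():
    a = np.zeros((1, 32, 32))
    b = np.zeros((1, 48, 32))
    with pytest.raises(ValueError):
        colocalize(a, b, pixel_size=1.0)


def test_subtype_fraction_recovers_draws():
    # Measurement error against the *realized* draw fraction (the field's
    # ground truth) is an order of magnitude inside the nominal-fraction
    # tolerance: the dominant error in nominal-recovery checks is the
    # binomial draw itself, not the estimator.
    for seed in (42, 43, 44, 45, 46):
        pat, truth = generate_point_pattern("csr", n=200, seed=seed,
                                            subtype_probs={"CalR": 0.4})
        stack, _ = render_wholemount(pat, seed=seed)
        res = subtype_fraction(stack, stack, reference_channel="HuC/D",
                               subtype_channel="CalR")
        true_frac = truth.subtype_draws["CalR"].mean()
        assert res.fraction == pytest.approx(true_frac, abs=0.02)
        assert not res.undefined


def test_subtype_fraction_undefined_on_empty_reference():
    noise = np.random.default_rng(1).normal(20, 2, size=(1, 128, 128))
    res = subtype_fraction(np.maximum(noise, 0), np.maximum(noise, 0),
                           pixel_size=1.0)
    assert res.undefined
    assert np.isnan(res.fraction)


def test_depth_projection_basics_and_scaling_invariance():
    vol = np.full((5, 64, 64), 10.0)
    vol[0, 10:20, 10:20] = 1000.0
    vol[4, 40:50, 40:50] = 1000.0
    d1 = depth_projection(vol, pixel_size=1.0, z_step=3.0,
                          blur_sigma_um=0.0)
    assert np.nanmax(d1[10:20, 10:20]) == 0.0
    assert np.nanmin(d1[40:50, 40:50]) == 12.0
    assert np.isnan(d1[0, 0])
    d2 = depth_projection(vol * 7.0, pixel_size=1.0, z_step=3.0,
                          blur_sigma_um=0.0)
    assert np.array_equal(np.isnan(d1), np.isnan(d2))
    assert np.nanmax(np.abs(d1 - d2)) == 0.0


def test_single_slice_stack_has_zero_depth(rendered_field):
    _, _, stack, _ = rendered_field
    d = depth_projection(stack, channel="HuC/D")
    assert np.nanmax(d) == 0.0


def test_grid_depth_classes_recovered(grid_stack):
    pattern, truth, stack, rt = grid_stack
    seg, rec = segment_neurons(stack, channel="HuC/D")
    dm = depth_projection(stack, channel="HuC/D")
    depths = soma_depths(seg, dm)
    # bimodal: the two depth planes 12 um apart dominate
    shallow = (depths < 6).sum()
    deep = (depths > 6).sum()
    assert shallow > 0 and deep > 0
    from scipy.spatial import cKDTree

    d, idx = cKDTree(pattern.points).query(rec.points)
    ok = (depths > 6) == truth.is_bridging[idx]
    assert ok.mean() >= 0.95


def test_muscle_thickness_two_transects():
    stack, truth = render_cross_section(layer_thicknesses={"CM": 30.0,
                                                           "LM": 45.0},
                                        pixel_size=0.5, seed=11)
    cm = measure_muscle_thickness(stack, "CM", n_locations=2)
    lm = measure_muscle_thickness(stack, "LM", n_locations=2)
    assert cm == pytest.approx(30.0, abs=0.5)    # within one pixel
    assert lm == pytest.approx(45.0, abs=0.5)
    with pytest.raises(ValueError):
        measure_muscle_thickness(stack, "SMP")


def test_muscle_thickness_missing_layer_names_transect():
    img = np.full((100, 60), 20.0)
    img[30:50, :] = 1000.0               # a single band: no LM
    with pytest.raises(MeasurementError, match="transect"):
        measure_muscle_thickness(img, "LM", pixel_size=1.0)


def test_nuclear_density_against_truth():
    stack, truth = render_cross_section(nucleus_density=5e-4,
                                        pixel_size=0.5, seed=12)
    r0, r1 = truth.layer_rows["MP"]
    roi = (0.0, r0 * 0.5, 800.0, (r1 - r0) * 0.5)
    count, dens = nuclear_density(stack, roi, channel="Sox10")
    assert count == truth.nucleus_count
    assert dens == pytest.approx(count / (roi[2] * roi[3]))
    with pytest.raises(ValueError):
        nuclear_density(stack, (0, 0, 5000.0, 50.0), channel="Sox10")


def test_nuclear_density_empty_roi():
    img = np.random.default_rng(2).normal(20, 2, size=(200, 200))
    count, dens = nuclear_density(np.maximum(img, 0), (10, 10, 100, 100),
                                  pixel_size=1.0)
    assert count == 0 and dens == 0.0
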
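import numpy as np
import pytest

from enteromap.motility import (STM, STMQualityError, classify_pattern,
                                compare_conditions, compute_stm,
                                detect_contractions, ripple_frequency)
from enteromap.video import (OcclusionError, generate_motility_video,
                             render_frames, scenario)


@pytest.fixture(scope="module")
def distal_wave():
    """Two clean distal waves at 1000 um/s, rendered and extracted."""
    frames, truth = generate_motility_video(
        duration_s=150, ripple_rate_per_min=0,
        neurogenic=dict(mode="distal_waves", rate_per_min=0.8,
                        velocity_um_s=1000.0, amplitude_um=800.0),
        seed=101)
    stm = compute_stm(frames, pixel_size=truth.pixel_size)
    return frames, truth, stm


def test_constant_tube_gives_constant_stm():
    D = np.full((40, 120), 2000.0)
    frames = render_frames(D, 2000.0, 25.0, noise_sd=0.0,
                           rng=np.random.default_rng(0))
    stm = compute_stm(frames, pixel_size=25.0)
    assert np.ptp(stm.diameter_um) == 0.0
    assert abs(stm.diameter_um[0, 0] - 2000.0) <= 25.0   # within 1 px
    assert detect_contractions(stm) == []


def test_empty_frames_raise_quality_error():
    with pytest.raises(STMQualityError):
        compute_stm(np.full((10, 50, 50), 200, dtype=np.uint8),
                    pixel_size=25.0)


def test_stm_matches_analytic_field(distal_wave):
    frames, truth, stm = distal_wave
    err = np.abs(stm.diameter_um - truth.diameter_um) / truth.pixel_size
    assert err.max() <= 2.0              # <= 2 px at default noise
    frames2, truth2 = generate_motility_video(
        duration_s=60, ripple_rate_per_min=0,
        neurogenic=dict(mode="distal_waves", rate_per_min=1.0,
                        velocity_um_s=1500.0),
        noise_sd=0.0, seed=102)
    stm2 = compute_stm(frames2, pixel_size=truth2.pixel_size)
    err2 = np.abs(stm2.diameter_um - truth2.diameter_um) / truth2.pixel_size
    assert err2.max() <= 1.0             # exact to 1 px without noise


def test_distal_wave_velocity_and_direction(distal_wave):
    _, truth, stm = distal_wave
    events = detect_contractions(stm)
    assert len(events) == len(truth.events)
    for ev in events:
        assert ev.direction == "distal"
        assert abs(ev.velocity_um_s - 1000.0) / 1000.0 <= 0.10
        assert ev.amplitude_um > 100.0


def test_bidirectional_origin_recovery():
    frames, truth = generate_motility_video(
        duration_s=90, ripple_rate_per_min=0,
        neurogenic=dict(mode="bidirectional_bursts", rate_per_min=1.0,
                        active_s=90.0, quiet_s=0.0,
                        velocity_um_s=1500.0, amplitude_um=800.0),
        seed=103)
    stm = compute_stm(frames, pixel_size=truth.pixel_size)
    events = detect_contractions(stm)
    assert len(events) == 1
    ev = events[0]
    assert ev.direction == "bidirectional"
    assert abs(ev.origin_um - truth.events[0].origin_um) <= 2 * stm.bin_um
    vl, vr = ev.branch_velocities
    assert vl < 0 < vr


def test_time_reversal_swaps_direction(distal_wave):
    _, _, stm = distal_wave
    fwd = detect_contractions(stm)
    rev = detect_contractions(stm.reversed_time())
    assert len(fwd) == len(rev)
    assert all(e.direction == "distal" for e in fwd)
    assert all(e.direction == "proximal" for e in rev)


def test_ripple_frequency_recovery():
    frames, truth = generate_motility_video(duration_s=600,
                                            ripple_rate_per_min=6.0,
                                            seed=104)
    stm = compute_stm(frames, pixel_size=truth.pixel_size)
    f = ripple_frequency(stm)
    assert abs(f - 6.0) <= 0.5
    with pytest.raises(ValueError):
        ripple_frequency(STM(np.full((30, 40), 2000.0)), window_s=60.0)


def test_classification_thresholds_and_flags():
    quiet = STM(np.full((300, 40), 2000.0))
    s = classify_pattern([], quiet)
    assert s.label == "ripples_only"
    assert s.low_activity
    assert s.ripple_frequency_per_min == 0.0


def test_occlusion_guard():
    with pytest.raises(OcclusionError):
        generate_motility_video(duration_s=60, baseline_diameter_um=500.0,
                                ripple_amplitude_um=600.0, seed=0)


def test_compare_conditions_identity_and_calibration():
    stm = STM(np.full((240, 40), 2000.0))
    c = compare_conditions(stm, stm)
    assert c.delta_ripple_frequency == 0.0
    assert c.delta_quiescent_fraction == 0.0
    assert c.label_transition == ("ripples_only", "ripples_only")
    other = STM(np.full((240, 40), 2000.0), bin_um=50.0)
    with pytest.raises(ValueError):
        compare_conditions(stm, other)


@pytest.mark.parametrize("stage,ttx,label", [
    ("14pcw", False, "ripples_only"),
    ("18pcw", False, "intermittent_neurogenic"),
    ("21pcw", False, "distal_propagating"),
])
def test_staged_scenarios_classify_correctly(stage, ttx, label):
    frames, truth = scenario(stage, ttx=ttx, duration_s=300, seed=105)
    stm = compute_stm(frames, pixel_size=truth.pixel_size)
    events = detect_contractions(stm)
    s = classify_pattern(events, stm)
    assert s.label == label


def test_ttx_ablates_quiescence_in_immature_recording():
    base_frames, bt = scenario("18pcw", duration_s=300, seed=106)
    ttx_frames, tt = scenario("18pcw", ttx=True, duration_s=300, seed=106)
    base = compute_stm(base_frames, pixel_size=bt.pixel_size)
    ttx = compute_stm(ttx_frames, pixel_size=tt.pixel_size,
                      condition="ttx")
    c = compare_conditions(base, ttx)
    assert c.baseline.label == "intermittent_neurogenic"
    assert c.treated.label != "intermittent_neurogenic"
    assert c.delta_quiescent_fraction < -0.1
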
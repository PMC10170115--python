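import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enteromap.points import (PackingError, PointPattern, StripeParams,
                              generate_point_pattern, min_pairwise_distance)


def test_empty_pattern_is_vacuous():
    pat, truth = generate_point_pattern("csr", n=0, seed=0)
    assert pat.n == 0
    assert truth.mode == "csr"


def test_csr_hard_core_and_determinism():
    pat1, _ = generate_point_pattern("csr", n=300, window=(800, 800),
                                     d_min=5.0, seed=1)
    pat2, _ = generate_point_pattern("csr", n=300, window=(800, 800),
                                     d_min=5.0, seed=1)
    assert pat1.n == 300
    # exhaustive pairwise check
    d = pat1.points[:, None, :] - pat1.points[None, :, :]
    dist = np.hypot(d[..., 0], d[..., 1])
    np.fill_diagonal(dist, np.inf)
    assert dist.min() >= 5.0
    assert np.array_equal(pat1.points, pat2.points)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(n=st.integers(2, 120), d_min=st.floats(0.0, 10.0),
       mode=st.sampled_from(["csr", "striped", "grid"]),
       seed=st.integers(0, 2 ** 20))
def test_hard_core_and_window_hold_for_all_modes(n, d_min, mode, seed):
    pat, truth = generate_point_pattern(mode, n=n, window=(400.0, 400.0),
                                        d_min=d_min, seed=seed)
    assert pat.n == n
    assert (pat.points >= 0).all()
    assert (pat.points[:, 0] < 400).all() and (pat.points[:, 1] < 400).all()
    if d_min > 0:
        assert min_pairwise_distance(pat.points) >= d_min
    if mode == "grid":
        assert truth.is_bridging is not None
        assert len(np.unique(pat.depth)) <= 2


def test_striped_band_occupancy_matches_p_in():
    sp = StripeParams(period=150.0, width=40.0, p_in=0.9)
    fracs = []
    for seed in range(10):
        pat, truth = generate_point_pattern("striped", n=300,
                                            stripe_params=sp, seed=seed)
        fracs.append(truth.in_stripe.mean())
    assert abs(np.mean(fracs) - 0.9) <= 0.05


def test_grid_mode_assigns_bridging_depth():
    sp = StripeParams(stripe_depth=0.0, bridging_depth=12.0,
                      bridging_fraction=0.25)
    pat, truth = generate_point_pattern("grid", n=200, stripe_params=sp,
                                        seed=3)
    assert truth.is_bridging.sum() == 50
    assert (pat.depth[truth.is_bridging] == 12.0).all()
    assert (pat.depth[~truth.is_bridging] == 0.0).all()
    # bridging neurons sit between the stripe bands
    from enteromap.points import _in_band

    assert not _in_band(pat.points[truth.is_bridging, 0],
                        pat.points[truth.is_bridging, 1], sp).any()


def test_subtype_draws_recorded_in_truth():
    pat, truth = generate_point_pattern("csr", n=150, seed=9,
                                        subtype_probs={"CalR": 0.4,
                                                       "nNOS": 0.3})
    for name in ("CalR", "nNOS"):
        assert np.array_equal(pat.labels[name], truth.subtype_draws[name])
        assert len(pat.labels[name]) == 150


def test_infeasible_packing_raises():
    with pytest.raises(PackingError):
        generate_point_pattern("csr", n=10_000, window=(100, 100),
                               d_min=10.0, seed=0)


def test_unknown_mode_raises():
    with pytest.raises(ValueError, match="unknown mode"):
        generate_point_pattern("hexagonal", n=10, seed=0)


def test_pattern_invariants_validated():
    with pytest.raises(ValueError):
        PointPattern(points=[(900.0, 10.0)], window=(800.0, 800.0))
    with pytest.raises(ValueError):
        PointPattern(points=[(1.0, 1.0)], window=(800.0, 800.0),
                     labels={"x": [True, False]})
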
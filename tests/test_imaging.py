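import numpy as np
import pytest

from enteromap.imaging import (GeometryError, ImageStack, ResolutionError,
                               render_cross_section, render_wholemount)
from enteromap.points import PointPattern, generate_point_pattern


def test_empty_pattern_renders_background_only():
    empty = PointPattern(points=np.empty((0, 2)), window=(200.0, 200.0))
    stack, truth = render_wholemount(empty, seed=0)
    vol = stack.channel("HuC/D")
    assert vol.shape == (1, 200, 200)
    # noise floor only: nothing near the soma amplitude
    assert vol.max() < 100


def test_default_field_and_z_step():
    pat, _ = generate_point_pattern("grid", n=50, seed=1)
    stack, _ = render_wholemount(pat, seed=1)
    nz, ny, nx = stack.shape
    assert (ny, nx) == (800, 800)       # 800 x 800 um at 1 um/px
    assert stack.z_step == 3.0          # 3 um optical sections
    assert nz == 5                      # depths 0 and 12 um


def test_resolution_guard():
    pat, _ = generate_point_pattern("csr", n=5, seed=2)
    with pytest.raises(ResolutionError):
        render_wholemount(pat, pixel_size=8.0, seed=2)


def test_subtype_channels_contain_only_positive_somata():
    pat, truth = generate_point_pattern("csr", n=40, window=(400, 400),
                                        d_min=16, seed=3,
                                        subtype_probs={"CalR": 0.5})
    stack, rt = render_wholemount(pat, seed=3)
    assert set(stack.channels) == {"HuC/D", "CalR"}
    ref = stack.channel("HuC/D").max(axis=0)
    sub = stack.channel("CalR").max(axis=0)
    pos = truth.subtype_draws["CalR"]
    for i, (x, y) in enumerate(pat.points):
        val = sub[int(y), int(x)]
        if pos[i]:
            assert val > 500
        else:
            assert val < 100


def test_image_stack_validation():
    with pytest.raises(ValueError):
        ImageStack({"a": np.zeros((1, 4, 4))}, pixel_size=0.0)
    with pytest.raises(ValueError):
        ImageStack({"a": np.zeros((1, 4, 4)), "b": np.zeros((1, 5, 4))},
                   pixel_size=1.0)


def test_cross_section_band_geometry_exact():
    stack, truth = render_cross_section(layer_thicknesses={"CM": 30.0},
                                        pixel_size=0.5, seed=4)
    r0, r1 = truth.layer_rows["CM"]
    assert r1 - r0 == 60               # 30 um at 0.5 um/px
    muscle = stack.channel("muscle")[0]
    assert (muscle[r0:r1, :] > 500).all()
    # rows just outside the two muscle bands are background
    assert muscle[r0 - 2, :].max() < 100


def test_cross_section_nucleus_count_matches_truth():
    stack, truth = render_cross_section(nucleus_density=5e-4,
                                        pixel_size=0.5, seed=5)
    from skimage.measure import label

    sox = stack.channel("Sox10")[0]
    n_cc = label(sox > 500).max()
    assert n_cc == truth.nucleus_count
    assert len(truth.nucleus_centers_px) == truth.nucleus_count


def test_zero_apoptotic_fraction_gives_empty_channel():
    stack, truth = render_cross_section(apoptotic_fraction=0.0, seed=6)
    assert not truth.apoptotic_mask.any()
    assert stack.channel("Casp3").max() < 100


def test_bad_cross_section_parameters_raise():
    with pytest.raises(GeometryError):
        render_cross_section(layer_thicknesses={"CM": -5.0}, seed=0)
    with pytest.raises(ValueError):
        render_cross_section(apoptotic_fraction=1.5, seed=0)


def test_render_determinism():
    pat, _ = generate_point_pattern("csr", n=30, seed=7)
    a, _ = render_wholemount(pat, seed=7)
    b, _ = render_wholemount(pat, seed=7)
    assert np.array_equal(a.channel("HuC/D"), b.channel("HuC/D"))
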
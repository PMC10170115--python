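import numpy as np
import pytest

from enteromap.imaging import render_wholemount
from enteromap.points import generate_point_pattern


def brute_force_cif_histogram(points, L, bin_size):
    """Independent O(n^2) pairwise-offset histogram (double loop).

    Deliberately naive: iterates every ordered pair in Python and drops
    each offset into its lag bin by arithmetic, as a cross-check for the
    vectorised implementation.
    """
    nb = int(round(2 * L / bin_size))
    width = 2 * L / nb
    H = np.zeros((nb, nb), dtype=np.int64)
    pts = [(float(x), float(y)) for x, y in points]
    n = len(pts)
    for i in range(n):
        xi, yi = pts[i]
        for j in range(n):
            if i == j:
                continue
            dx = pts[j][0] - xi
            dy = pts[j][1] - yi
            if -L <= dx <= L and -L <= dy <= L:
                kx = min(int((dx + L) // width), nb - 1)
                ky = min(int((dy + L) // width), nb - 1)
                H[ky, kx] += 1
    return H


@pytest.fixture(scope="session")
def rendered_field():
    """A default 800x800 um field of 50 well-separated somata."""
    pattern, truth = generate_point_pattern(
        "csr", n=50, window=(800.0, 800.0), d_min=16.0, seed=1234)
    stack, render_truth = render_wholemount(pattern, seed=1234)
    return pattern, truth, stack, render_truth


@pytest.fixture(scope="session")
def grid_stack():
    """A grid-mode pattern rendered with two depth planes 12 um apart."""
    pattern, truth = generate_point_pattern("grid", n=300, seed=77)
    stack, render_truth = render_wholemount(pattern, seed=77)
    return pattern, truth, stack, render_truth
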
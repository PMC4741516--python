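import numpy as np
import pytest

from hovmap import HOVSurface, TestGrid, TruthSurface
from hovmap.synthetic import make_test_grid, simulate_bscan_pair, simulate_exams


@pytest.fixture(scope="session")
def logistic_truth():
    """Preserved central island, half-sensitivity at 12 deg, softness 2 deg."""
    return TruthSurface(family="logistic_edge", s_max=30.0, r0=12.0, w=2.0)


@pytest.fixture(scope="session")
def full_grid():
    return make_test_grid()


@pytest.fixture(scope="session")
def small_grid():
    """A compact grid (fast interpolation) spanning +/-20 degrees."""
    return make_test_grid(n_points=81, span_h=40, span_v=40, rings=5, condensation=1.5)


@pytest.fixture(scope="session")
def logistic_surface(logistic_truth):
    """Analytic logistic-edge surface sampled at the protocol spacing."""
    return HOVSurface.from_function(logistic_truth, span=80.0, spacing=0.36)


@pytest.fixture()
def noiseless_exam_pair(logistic_truth, full_grid):
    return simulate_exams(logistic_truth, full_grid, noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def clean_scan_pair(logistic_truth):
    return simulate_bscan_pair(logistic_truth, ez_halfwidth_mm=1.75, seed=3)


def random_exam(rng, n_points=30, span=40.0):
    """A fuzzed scattered exam: random points in a disc plus fixation."""
    n = n_points - 1
    r = span / 2.0 * np.sqrt(rng.uniform(0.05, 1.0, n))
    a = rng.uniform(0, 2 * np.pi, n)
    pts = np.vstack([[0.0, 0.0], np.column_stack([r * np.cos(a), r * np.sin(a)])])
    pts = np.unique(np.round(pts, 6), axis=0)
    from hovmap import FieldExam

    grid = TestGrid(pts)
    dls = rng.uniform(0.0, 35.0, len(pts))
    return FieldExam(grid=grid, dls=dls, rf=float(rng.uniform(0, 20)))
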
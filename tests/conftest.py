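import numpy as np
import pytest

from cshmpl import CompetingRisksMPL, simulate_dataset, study_preset
from cshmpl.data import CompetingRisksData
from cshmpl.likelihood import LikelihoodWorkspace, ModelParameters
from cshmpl.splines import MSplineBasis


@pytest.fixture(scope="session")
def study1_small():
    """A small study-1 draw (n=60) for fast likelihood/score tests."""
    return simulate_dataset(study_preset(1, "balanced", n=60), seed=3)


@pytest.fixture(scope="session")
def study1_n200():
    return simulate_dataset(study_preset(1, "balanced", n=200), seed=11)


@pytest.fixture(scope="session")
def small_workspace(study1_small):
    model = CompetingRisksMPL(study1_small, n_basis=5)
    return model.workspace


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def random_params(small_workspace, rng):
    ws = small_workspace
    return ModelParameters(
        rng.normal(0, 0.3, (ws.g, ws.p)),
        [rng.uniform(0.3, 1.5, m) for m in ws.m],
    )


def constant_hazard_basis(upper=2.0):
    """Order-1 M-spline basis: a single flat density 1/upper on [0, upper]."""
    return MSplineBasis(order=1, interior_knots=np.array([]), boundary=(0.0, upper))


def single_subject(status, t_left, t_right, risk=1):
    return CompetingRisksData(
        [t_left], [t_right], [status], [risk if status != "right" else 0],
        np.zeros((1, 1)), n_risks=1, validate=False,
    )


@pytest.fixture()
def cubic_basis():
    return MSplineBasis(order=4, interior_knots=np.array([0.3, 0.6]), boundary=(0.0, 1.0))


def finite_difference_gradient(f, x0, rel_step=1e-6):
    x0 = np.asarray(x0, dtype=float)
    g = np.empty_like(x0)
    for j in range(x0.size):
        h = rel_step * (1.0 + abs(x0[j]))
        xp = x0.copy(); xp[j] += h
        xm = x0.copy(); xm[j] -= h
        g[j] = (f(xp) - f(xm)) / (2.0 * h)
    return g
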
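"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from scipy.integrate import quad

from parnibvs import Dataset, ModelIndicator, PriorSpec, make_enumerable_fixture
from parnibvs.model_core import build_design, log_likelihood_eta


@pytest.fixture(scope="session")
def logistic_small():
    """n=60, p=5 logistic fixture with two strong effects."""
    data, truth = make_enumerable_fixture("logistic", seed=1, n=60, p=5, n_effects=2)
    return data, truth


@pytest.fixture(scope="session")
def survival_small():
    data, truth = make_enumerable_fixture("weibull", seed=2, n=60, p=5, n_effects=2)
    return data, truth


@pytest.fixture(scope="session")
def cox_small():
    data, truth = make_enumerable_fixture("cox_pl", seed=3, n=50, p=5, n_effects=2)
    return data, truth


@pytest.fixture(scope="session")
def prior_fixed_h():
    return PriorSpec(g=1.0, sigma_alpha2=1.0, h=0.3)


def tiny_logistic_no_z(n=30, p=2, beta=(1.0, 0.0), seed=7):
    """Logistic data without fixed covariates, for low-dimensional quadrature."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    X -= X.mean(axis=0)
    X /= X.std(axis=0)
    eta = X @ np.asarray(beta)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return Dataset(X=X, Z=np.empty((n, 0)), y=y, family="logistic")


def quad_evidence_1d(data, gamma, prior, lim=30.0):
    """Adaptive 1-D quadrature of the evidence integral for a q=0, p_gamma=1
    model: int p(y|beta) N(beta; 0, g) dbeta."""
    assert data.q == 0 and gamma.p_gamma == 1
    J = build_design(gamma, data)

    def logpost(b):
        ll = log_likelihood_eta(J[:, 0] * b, data)
        lp = -0.5 * np.log(2 * np.pi * prior.g) - 0.5 * b * b / prior.g
        return ll + lp

    # shift by the maximum so the integrand is O(1) for quad's tolerances
    grid = np.linspace(-lim, lim, 2001)
    shift = max(logpost(b) for b in grid)
    val, _ = quad(lambda b: np.exp(logpost(b) - shift), -lim, lim, limit=200)
    return shift + np.log(val)


def batch_means_se(x, n_batches=50):
    """Monte-Carlo standard error of the mean of a dependent series."""
    x = np.asarray(x, dtype=float)
    m = len(x) // n_batches
    means = x[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))
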
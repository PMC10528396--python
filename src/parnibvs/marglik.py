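"""Marginal-likelihood engines for model-space MCMC.

The quantity driving everything is the evidence of a model gamma,

    p(y | gamma) = int p(y | theta, gamma) p(theta | gamma) dtheta,

intractable for all three families.  Five interchangeable estimators are
provided behind a single ``estimate(gamma)`` interface:

* ``LAEngine``          — Laplace approximation at the posterior mode;
* ``ALAEngine``         — approximate Laplace approximation: a single Taylor
  expansion at a fixed initial value (the origin by default), no
  optimisation;
* ``AdaptiveALAEngine`` — ALA initialised from a running average of MAP
  linear predictors followed by exactly one Newton step;
* ``CPMEngine``         — correlated pseudo-marginal: an unbiased importance
  sampling estimate under the Laplace proposal whose standard-normal
  auxiliaries are shared across the models scored within one MH step and
  refreshed by an autoregression between steps;
* ``DAEngine``          — Polya-gamma data augmentation (logistic only):
  conditional on latent omega the coefficient integral is Gaussian and the
  conditional evidence p(y | gamma, omega) is available in closed form.

The module also provides the Schur-complement warm start: Rao-Blackwellised
inclusion probabilities at an anchor model for all p covariates from a single
matrix factorisation plus O(p) rank-one work, under ALA at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.special import logsumexp

from .model_core import (
    Coefficients, CurvaturePair, Dataset, ModelIndicator, PriorSpec,
    build_design, eta_score_curvature, log_coef_prior, log_likelihood_eta,
    log_inclusion_prior_ratio, log_model_prior, prior_precision_diag,
)
from .pg import pg1_draw, pg_draw, pg_mean

__all__ = [
    "MarglikEstimate", "PGState", "CPMState", "WarmStartWorkspace",
    "map_estimate", "log_marglik_la", "log_marglik_ala", "adaptive_ala",
    "log_marglik_cpm", "pg_identity_rhs", "pg_update_omega",
    "pg_conditional_marglik", "pg_draw_theta", "warm_start_pips",
    "LAEngine", "ALAEngine", "AdaptiveALAEngine", "CPMEngine", "DAEngine",
    "make_engine",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class MarglikEstimate:
    log_value: float
    estimator: str
    mode: Optional[Coefficients] = None
    neg_hessian_chol: Optional[np.ndarray] = None
    exact_target: bool = False


@dataclass
class PGState:
    """Polya-gamma latent variables omega (all entries > 0)."""
    omega: np.ndarray


@dataclass
class CPMState:
    """Shared auxiliary block for the correlated pseudo-marginal estimator."""
    u: np.ndarray          # N x dim_max standard normals
    rho: float = 0.99
    N: int = 32

    def refresh(self, rng: np.random.Generator) -> None:
        eps = rng.standard_normal(self.u.shape)
        self.u = self.rho * self.u + np.sqrt(1.0 - self.rho ** 2) * eps


# ---------------------------------------------------------------------------
# log-posterior pieces in theta-space

def _logpost_value(theta: np.ndarray, J: np.ndarray, vinv: np.ndarray,
                   data: Dataset, log_k) -> float:
    """Log-likelihood plus coefficient log-prior at theta (value only)."""
    eta = J @ theta
    ll = log_likelihood_eta(eta, data, log_k)
    d = theta.shape[0]
    if d == 0:
        return ll
    logprior = -0.5 * d * _LOG_2PI - 0.5 * np.log(1.0 / vinv).sum() \
        - 0.5 * np.dot(theta * vinv, theta)
    return ll + logprior


def _neg_logpost_grad_hess(theta: np.ndarray, J: np.ndarray, vinv: np.ndarray,
                           data: Dataset, log_k):
    """Value of the log-posterior and the gradient/negated-Hessian of its
    NEGATIVE at theta (packed).  H = J^T W J + V^{-1} is returned densely."""
    eta = J @ theta
    ll = log_likelihood_eta(eta, data, log_k)
    curv = eta_score_curvature(eta, None, data, log_k)
    grad_post = J.T @ curv.y_tilde - vinv * theta
    if curv.diagonal:
        H = (J * curv.W[:, None]).T @ J
    else:
        H = J.T @ curv.W @ J
    H[np.diag_indices_from(H)] += vinv
    d = theta.shape[0]
    logprior = -0.5 * d * _LOG_2PI - 0.5 * np.log(1.0 / vinv).sum() if d else 0.0
    if d:
        logprior -= 0.5 * np.dot(theta * vinv, theta)
    return ll + logprior, -grad_post, H


def _logpost_extra_logk(prior: PriorSpec, log_k) -> float:
    # N(0, sigma_k^2) prior on log k, conditioned on by the theta integral
    if log_k is None:
        return 0.0
    return float(-0.5 * _LOG_2PI - 0.5 * np.log(prior.sigma_k2)
                 - 0.5 * log_k ** 2 / prior.sigma_k2)


def _chol_with_jitter(H: np.ndarray):
    d = H.shape[0]
    if d == 0:
        return np.empty((0, 0))
    try:
        return cholesky(H, lower=True)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * np.trace(H) / d
        return cholesky(H + jitter * np.eye(d), lower=True)


# ---------------------------------------------------------------------------
# MAP / LA / ALA

def map_estimate(gamma: ModelIndicator, data: Dataset, prior: PriorSpec,
                 init: Optional[Coefficients] = None, log_k=None,
                 tol: float = 1e-8, max_iter: int = 100):
    """Posterior mode and negated Hessian by Newton iteration with
    step-halving, from the origin unless ``init`` is given."""
    J = build_design(gamma, data)
    vinv = prior_precision_diag(gamma, data, prior)
    d = J.shape[1]
    if init is not None:
        theta = init.packed().copy()
        if init.log_k is not None:
            log_k = init.log_k
    else:
        theta = np.zeros(d)
    f, g, H = _neg_logpost_grad_hess(theta, J, vinv, data, log_k)
    for _ in range(max_iter):
        if d == 0 or np.max(np.abs(g)) < tol:
            break
        L = _chol_with_jitter(H)
        step = cho_solve((L, True), -g)          # Newton direction on -g
        new_theta = theta + step
        f_new, g_new, H_new = _neg_logpost_grad_hess(new_theta, J, vinv, data, log_k)
        halvings = 0
        while (not np.isfinite(f_new) or f_new < f - 1e-12) and halvings < 40:
            step *= 0.5
            new_theta = theta + step
            f_new, g_new, H_new = _neg_logpost_grad_hess(new_theta, J, vinv, data, log_k)
            halvings += 1
        theta, f, g, H = new_theta, f_new, g_new, H_new
    else:
        if d and np.max(np.abs(g)) > 1e-4:
            raise RuntimeError(
                f"Newton failed to converge for model {gamma.included.tolist()}")
    mode = Coefficients.from_packed(theta, data.q, log_k)
    return mode, H


def log_marglik_la(gamma: ModelIndicator, data: Dataset, prior: PriorSpec,
                   log_k=None, mode: Optional[Coefficients] = None,
                   H: Optional[np.ndarray] = None) -> MarglikEstimate:
    """Laplace approximation
    log p_LA = log p(y|theta_hat) + log p(theta_hat|gamma) - 1/2 log|H| + (d/2) log 2pi."""
    if mode is None or H is None:
        mode, H = map_estimate(gamma, data, prior, log_k=log_k)
    J = build_design(gamma, data)
    vinv = prior_precision_diag(gamma, data, prior)
    theta = mode.packed()
    f, _, _ = _neg_logpost_grad_hess(theta, J, vinv, data, mode.log_k)
    d = theta.shape[0]
    L = _chol_with_jitter(H)
    logdet = 2.0 * np.log(np.diag(L)).sum() if d else 0.0
    val = f + _logpost_extra_logk(prior, mode.log_k) + 0.5 * d * _LOG_2PI - 0.5 * logdet
    return MarglikEstimate(float(val), "LA", mode=mode, neg_hessian_chol=L)


def log_marglik_ala(gamma: ModelIndicator, data: Dataset, prior: PriorSpec,
                    theta0: Optional[Coefficients] = None, log_k=None) -> MarglikEstimate:
    """Approximate Laplace approximation at an arbitrary initial value:
    log p_ALA = log p(y,theta0|gamma) + (d/2) log 2pi - 1/2 log|H0| + 1/2 g0^T H0^{-1} g0,
    with g0, H0 the gradient and Hessian of the negated log-posterior at theta0."""
    J = build_design(gamma, data)
    vinv = prior_precision_diag(gamma, data, prior)
    if theta0 is None:
        theta0 = Coefficients.origin(data.q, gamma.p_gamma, log_k)
    theta = theta0.packed()
    d = theta.shape[0]
    f, g_neg, H = _neg_logpost_grad_hess(theta, J, vinv, data, theta0.log_k)
    L = _chol_with_jitter(H)
    logdet = 2.0 * np.log(np.diag(L)).sum() if d else 0.0
    quad = 0.0
    if d:
        half = solve_triangular(L, -g_neg, lower=True)   # g0 = -grad logpost
        quad = 0.5 * float(np.dot(half, half))
    val = f + _logpost_extra_logk(prior, theta0.log_k) \
        + 0.5 * d * _LOG_2PI - 0.5 * logdet + quad
    return MarglikEstimate(float(val), "ALA", mode=theta0, neg_hessian_chol=L)


def adaptive_ala(gamma: ModelIndicator, data: Dataset, prior: PriorSpec,
                 eta_hat: np.ndarray, log_k=None) -> MarglikEstimate:
    """Adaptive ALA: project the running linear-predictor guess eta_hat onto
    the column space of J_gamma, take one Newton step, then evaluate ALA."""
    J = build_design(gamma, data)
    vinv = prior_precision_diag(gamma, data, prior)
    d = J.shape[1]
    if d == 0:
        est = log_marglik_ala(gamma, data, prior, log_k=log_k)
        est.estimator = "adaptiveALA"
        return est
    # least-squares projection via the normal equations, ridge-regularised
    # when J is (numerically) rank deficient
    A = J.T @ J
    b = J.T @ eta_hat
    try:
        cf = cho_factor(A, lower=True)
        theta0 = cho_solve(cf, b)
    except np.linalg.LinAlgError:
        theta0 = np.linalg.solve(A + 1e-8 * np.eye(d), b)
    if not np.all(np.isfinite(theta0)):
        theta0 = np.linalg.solve(A + 1e-8 * np.eye(d), b)
    # one Newton step on the negated log-posterior
    _, g_neg, H = _neg_logpost_grad_hess(theta0, J, vinv, data, log_k)
    L = _chol_with_jitter(H)
    theta1 = theta0 - cho_solve((L, True), g_neg)
    est = log_marglik_ala(gamma, data, prior,
                          Coefficients.from_packed(theta1, data.q, log_k))
    est.estimator = "adaptiveALA"
    return est


# ---------------------------------------------------------------------------
# correlated pseudo-marginal

def log_marglik_cpm(gamma: ModelIndicator, data: Dataset, prior: PriorSpec,
                    state: CPMState, log_k=None,
                    mode: Optional[Coefficients] = None,
                    L: Optional[np.ndarray] = None) -> MarglikEstimate:
    """Unbiased importance-sampling evidence under the Laplace proposal:
    theta_i = theta_hat + L^{-T} u_i with H = L L^T, weights computed in
    log-space; the same u block must be shared by the two models of an MH
    ratio (slice the first dim rows/columns)."""
    if state.N < 1:
        raise ValueError("N must be >= 1")
    if mode is None or L is None:
        mode, H = map_estimate(gamma, data, prior, log_k=log_k)
        L = _chol_with_jitter(H)
    J = build_design(gamma, data)
    vinv = prior_precision_diag(gamma, data, prior)
    theta_hat = mode.packed()
    d = theta_hat.shape[0]
    logdet_half = np.log(np.diag(L)).sum() if d else 0.0
    u = state.u[:state.N, :d]
    if d:
        thetas = theta_hat + solve_triangular(L, u.T, lower=True, trans="T").T
    else:
        thetas = np.tile(theta_hat, (state.N, 1))
    if data.family == "logistic" and d:
        # vectorised across importance samples
        Eta = J @ thetas.T
        ll = data.y @ Eta - np.logaddexp(0.0, Eta).sum(axis=0)
        logprior = -0.5 * d * _LOG_2PI - 0.5 * np.log(1.0 / vinv).sum() \
            - 0.5 * np.einsum("ij,j,ij->i", thetas, vinv, thetas)
        f = ll + logprior
    else:
        f = np.array([_logpost_value(thetas[i], J, vinv, data, mode.log_k)
                      for i in range(state.N)])
    # log N(theta; theta_hat, H^{-1}) evaluated through u directly
    log_q = -0.5 * d * _LOG_2PI + logdet_half - 0.5 * np.einsum("ij,ij->i", u, u)
    logw = f - log_q
    val = logsumexp(logw) - np.log(state.N) + _logpost_extra_logk(prior, mode.log_k)
    return MarglikEstimate(float(val), "CPM", mode=mode, neg_hessian_chol=L,
                           exact_target=True)


# ---------------------------------------------------------------------------
# Polya-gamma pieces (logistic only)

def pg_identity_rhs(psi: float, a: float, b: int, n_mc: int,
                    rng: np.random.Generator) -> float:
    """Monte-Carlo estimate of 2^{-b} exp(kappa psi) E[exp(-omega psi^2/2)]
    with omega ~ PG(b, 0) and kappa = a - b/2; the left side of the identity
    is exp(a psi)/(1+exp(psi))^b."""
    kappa = a - b / 2.0
    omega = pg_draw(int(b), 0.0, n_mc, rng)
    vals = np.exp(-omega * psi * psi / 2.0)
    return float(2.0 ** (-b) * np.exp(kappa * psi) * vals.mean())


def _check_logistic(data: Dataset):
    if data.family != "logistic":
        raise ValueError("Polya-gamma augmentation applies to the logistic family only")


def pg_update_omega(gamma: ModelIndicator, theta: Coefficients, data: Dataset,
                    rng: np.random.Generator) -> PGState:
    """omega_i ~ PG(1, eta_i) at the current linear predictor."""
    _check_logistic(data)
    eta = build_design(gamma, data) @ theta.packed()
    return PGState(pg1_draw(eta, rng))


def _pg_lambda(gamma: ModelIndicator, omega: PGState, data: Dataset, prior: PriorSpec):
    J = build_design(gamma, data)
    vinv = prior_precision_diag(gamma, data, prior)
    Lam = (J * omega.omega[:, None]).T @ J
    Lam[np.diag_indices_from(Lam)] += vinv
    xi = J.T @ (data.y - 0.5)
    return J, vinv, Lam, xi


def pg_conditional_marglik(gamma: ModelIndicator, omega: PGState, data: Dataset,
                           prior: PriorSpec) -> float:
    """Closed-form conditional evidence
    log p(y|gamma,omega) = -n log 2 - 1/2 log|V| - 1/2 log|Lambda| + 1/2 xi^T Lambda^{-1} xi,
    with xi = J^T (y - 1/2), Lambda = J^T diag(omega) J + V^{-1}.  The additive
    constant is the exact Gaussian-integral constant, fixed across gamma for
    fixed omega, so the same value serves MH ratios and diagnostics."""
    _check_logistic(data)
    J, vinv, Lam, xi = _pg_lambda(gamma, omega, data, prior)
    d = Lam.shape[0]
    out = -data.n * np.log(2.0)
    if d:
        L = _chol_with_jitter(Lam)
        half = solve_triangular(L, xi, lower=True)
        out += -0.5 * np.log(1.0 / vinv).sum() - np.log(np.diag(L)).sum() \
            + 0.5 * float(np.dot(half, half))
    return float(out)


def pg_draw_theta(gamma: ModelIndicator, omega: PGState, data: Dataset,
                  prior: PriorSpec, rng: np.random.Generator) -> Coefficients:
    """Exact draw theta ~ N(Lambda^{-1} xi, Lambda^{-1}) via triangular solves."""
    _check_logistic(data)
    _, _, Lam, xi = _pg_lambda(gamma, omega, data, prior)
    d = Lam.shape[0]
    if d == 0:
        return Coefficients.origin(data.q, 0)
    L = _chol_with_jitter(Lam)
    mean = cho_solve((L, True), xi)
    z = rng.standard_normal(d)
    theta = mean + solve_triangular(L, z, lower=True, trans="T")
    return Coefficients.from_packed(theta, data.q)


# ---------------------------------------------------------------------------
# Schur-complement warm-start PIPs

@dataclass
class WarmStartWorkspace:
    y_tilde: np.ndarray
    W: np.ndarray
    Lambda_chol: np.ndarray
    base_gamma: ModelIndicator


def warm_start_pips(gamma0: ModelIndicator, data: Dataset, prior: PriorSpec,
                    log_k=None, epsilon: float = 1e-3) -> np.ndarray:
    """Rao-Blackwellised inclusion probabilities at an anchor model gamma0
    for all p covariates, using ALA-at-origin Bayes factors computed through
    the Schur complement of Lambda = J0^T W J0 + V^{-1}.

    For j excluded from gamma0 the one-column-added Bayes factor is
        BF_j = d_up^{-1/2} g^{-1/2} exp{ s_j^2 / (2 d_up) },
        d_up = X_j^T W X_j + 1/g - b_j^T Lambda^{-1} b_j,
        b_j  = J0^T W X_j,     s_j = X_j^T y~ - b_j^T Lambda^{-1} J0^T y~ ;
    for j included,
        BF_j = d_dn^{-1/2} g^{-1/2} exp{ d_dn m_j^2 / 2 },
        d_dn = 1/(Lambda^{-1})_{jj},   m_j = (Lambda^{-1} J0^T y~)_j .
    PIPs are BF_j r_j / (1 + BF_j r_j) with r_j the model-prior inclusion
    ratio, clipped to [epsilon, 1-epsilon].  One factorisation + O(p)
    rank-one work in total.
    """
    p = data.p
    curv = eta_score_curvature(np.zeros(data.n), gamma0, data, log_k)
    yt, W = curv.y_tilde, curv.W
    J0 = build_design(gamma0, data)
    vinv = prior_precision_diag(gamma0, data, prior)
    d0 = J0.shape[1]
    if curv.diagonal:
        WX = data.X * W[:, None]
        WJ0 = J0 * W[:, None]
    else:
        WX = W @ data.X
        WJ0 = W @ J0
    xWx = np.einsum("ij,ij->j", data.X, WX)          # X_j^T W X_j for all j
    xy = data.X.T @ yt                                # X_j^T y~
    if d0:
        Lam = J0.T @ WJ0
        Lam[np.diag_indices_from(Lam)] += vinv
        L = _chol_with_jitter(Lam)
        B = J0.T @ WX                                 # d0 x p, columns b_j
        LB = solve_triangular(L, B, lower=True)
        v = solve_triangular(L, J0.T @ yt, lower=True)
        Lam_inv = cho_solve((L, True), np.eye(d0))
        m_full = cho_solve((L, True), J0.T @ yt)
    log_bf = np.empty(p)
    incl = gamma0.gamma == 1
    log_g = np.log(prior.g)
    for j in range(p):
        if not incl[j]:
            if d0:
                d_up = xWx[j] + 1.0 / prior.g - float(np.dot(LB[:, j], LB[:, j]))
                s = xy[j] - float(np.dot(LB[:, j], v))
            else:
                d_up = xWx[j] + 1.0 / prior.g
                s = xy[j]
            if d_up <= 0:
                log_bf[j] = -np.inf
                continue
            log_bf[j] = -0.5 * np.log(d_up) - 0.5 * log_g + 0.5 * s * s / d_up
        else:
            # ordered position of column j within [Z X_gamma0]
            pos = data.q + int(np.sum(incl[:j]))
            dinv = Lam_inv[pos, pos]
            if dinv <= 0:
                log_bf[j] = np.inf
                continue
            d_dn = 1.0 / dinv
            m = m_full[pos]
            log_bf[j] = -0.5 * np.log(d_dn) - 0.5 * log_g + 0.5 * d_dn * m * m
    log_r = np.array([
        log_inclusion_prior_ratio(p, gamma0.p_gamma - int(incl[j]), prior)
        for j in range(p)
    ])
    x = log_bf + log_r
    pips = np.where(np.isfinite(x), 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700))),
                    np.where(x > 0, 1.0, 0.0))
    return np.clip(pips, epsilon, 1.0 - epsilon)


# ---------------------------------------------------------------------------
# engine classes

class _EngineBase:
    """Common estimate/ratio interface with per-call instrumentation."""

    name = "base"
    exact_target = False
    has_mode = True

    def __init__(self, data: Dataset, prior: PriorSpec, log_k=None):
        self.data = data
        self.prior = prior
        self.log_k = log_k if data.family == "weibull" else None
        self.n_calls = 0

    def set_hyper(self, g=None, log_k=None):
        """Update hyper-parameters, invalidating any per-model caches."""
        if g is not None:
            self.prior.g = g
        if log_k is not None:
            self.log_k = log_k
        self.flush()

    def flush(self):
        pass

    def refresh(self, rng, gamma=None):
        """Per-MH-step randomness refresh (no-op for deterministic engines)."""

    def estimate(self, gamma: ModelIndicator) -> MarglikEstimate:
        raise NotImplementedError

    def log_score(self, gamma: ModelIndicator) -> float:
        """log p-hat(y|gamma) + log p(gamma), the unnormalised log PMP."""
        return self.estimate(gamma).log_value + log_model_prior(gamma, self.prior)

    def mode_eta(self, gamma: ModelIndicator):
        """MAP linear predictor J_gamma theta_hat, or None (DA)."""
        est = self.estimate(gamma)
        if est.mode is None:
            return None
        return build_design(gamma, self.data) @ est.mode.packed()


class LAEngine(_EngineBase):
    """Laplace approximation; deterministic, memoised per model."""

    name = "la"

    def __init__(self, data, prior, log_k=None):
        super().__init__(data, prior, log_k)
        self._cache = {}

    def flush(self):
        self._cache.clear()

    def estimate(self, gamma: ModelIndicator) -> MarglikEstimate:
        self.n_calls += 1
        key = gamma.key()
        est = self._cache.get(key)
        if est is None:
            est = log_marglik_la(gamma, self.data, self.prior, log_k=self.log_k)
            self._cache[key] = est
        return est


class ALAEngine(_EngineBase):
    """ALA initialised at the origin; deterministic, memoised per model."""

    name = "ala"

    def __init__(self, data, prior, log_k=None):
        super().__init__(data, prior, log_k)
        self._cache = {}

    def flush(self):
        self._cache.clear()

    def estimate(self, gamma: ModelIndicator) -> MarglikEstimate:
        self.n_calls += 1
        key = gamma.key()
        est = self._cache.get(key)
        if est is None:
            est = log_marglik_ala(gamma, self.data, self.prior, log_k=self.log_k)
            self._cache[key] = est
        return est


class AdaptiveALAEngine(_EngineBase):
    """ALA at a one-Newton-step refinement of the projection of the running
    mean linear predictor eta_hat; eta_hat is owned by the sampler and
    mutated in place, so no per-model caching is possible."""

    name = "adaptive_ala"

    def __init__(self, data, prior, log_k=None):
        super().__init__(data, prior, log_k)
        self.eta_hat = np.zeros(data.n)

    def estimate(self, gamma: ModelIndicator) -> MarglikEstimate:
        self.n_calls += 1
        return adaptive_ala(gamma, self.data, self.prior, self.eta_hat,
                            log_k=self.log_k)


class CPMEngine(_EngineBase):
    """Correlated pseudo-marginal.  MAP modes/factors are deterministic and
    memoised; the evidence itself depends on the shared auxiliary block and
    is recomputed per call."""

    name = "cpm"
    exact_target = True

    def __init__(self, data, prior, log_k=None, N: int = 32, rho: float = 0.99,
                 dim_max: Optional[int] = None,
                 rng: Optional[np.random.Generator] = None):
        super().__init__(data, prior, log_k)
        if dim_max is None:
            dim_max = min(data.q + data.p, data.q + max(64, 4 * data.q + 16))
        init_rng = rng if rng is not None else np.random.default_rng(0)
        self.state = CPMState(init_rng.standard_normal((N, dim_max)), rho, N)
        self._map_cache = {}

    def flush(self):
        self._map_cache.clear()

    def refresh(self, rng, gamma=None):
        self.state.refresh(rng)

    def _map(self, gamma: ModelIndicator):
        key = gamma.key()
        hit = self._map_cache.get(key)
        if hit is None:
            mode, H = map_estimate(gamma, self.data, self.prior, log_k=self.log_k)
            hit = (mode, _chol_with_jitter(H))
            self._map_cache[key] = hit
        return hit

    def estimate(self, gamma: ModelIndicator) -> MarglikEstimate:
        self.n_calls += 1
        mode, L = self._map(gamma)
        d = mode.packed().shape[0]
        if d > self.state.u.shape[1]:   # grow the shared block if needed
            extra = np.random.default_rng(d).standard_normal(
                (self.state.u.shape[0], d - self.state.u.shape[1]))
            self.state.u = np.hstack([self.state.u, extra])
        return log_marglik_cpm(gamma, self.data, self.prior, self.state,
                               mode=mode, L=L)


class DAEngine(_EngineBase):
    """Polya-gamma data augmentation (logistic only).

    ``refresh`` performs the Gibbs sweep theta | gamma, omega then
    omega | theta; ``estimate`` returns the closed-form conditional evidence
    at the current omega.  The chain built on this engine targets the exact
    posterior p(gamma | y)."""

    name = "da"
    exact_target = True
    has_mode = False

    def __init__(self, data, prior, log_k=None,
                 rng: Optional[np.random.Generator] = None):
        super().__init__(data, prior)
        _check_logistic(data)
        self.pg_state = PGState(np.full(data.n, 0.25))

    def refresh(self, rng, gamma=None):
        if gamma is None:
            gamma = ModelIndicator.empty(self.data.p)
        theta = pg_draw_theta(gamma, self.pg_state, self.data, self.prior, rng)
        self.pg_state = pg_update_omega(gamma, theta, self.data, rng)

    def estimate(self, gamma: ModelIndicator) -> MarglikEstimate:
        self.n_calls += 1
        val = pg_conditional_marglik(gamma, self.pg_state, self.data, self.prior)
        return MarglikEstimate(val, "DA", exact_target=True)

    def mode_eta(self, gamma):
        return None


_ENGINES = {
    "la": LAEngine,
    "ala": ALAEngine,
    "adaptive_ala": AdaptiveALAEngine,
    "cpm": CPMEngine,
    "da": DAEngine,
}


def make_engine(name: str, data: Dataset, prior: PriorSpec, log_k=None,
                rng: Optional[np.random.Generator] = None, **kwargs) -> _EngineBase:
    name = name.lower()
    if name not in _ENGINES:
        raise ValueError(f"unknown engine {name!r}; choose from {sorted(_ENGINES)}")
    cls = _ENGINES[name]
    if name in ("cpm", "da"):
        return cls(data, prior, log_k=log_k, rng=rng, **kwargs)
    return cls(data, prior, log_k=log_k, **kwargs)
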
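"""Likelihood families, priors and design-matrix plumbing.

Every marginal-likelihood engine in this package is family-agnostic: it only
needs the log-likelihood and its first two derivatives with respect to the
linear predictor eta = Z alpha + X_gamma beta_gamma.  This module provides
those for three families:

* ``logistic`` — Bernoulli responses with the logit link;
* ``cox_pl``   — Cox proportional hazards via the partial likelihood
  (Breslow approximation for tied event times); the curvature in eta-space
  is a dense n x n matrix;
* ``weibull``  — Weibull survival regression with hazard
  h_i(t) = lambda_i k (lambda_i t)^{k-1}, lambda_i = exp(eta_i); the shape k
  is an extra parameter carried on the log scale and conditioned on by the
  coefficient integrals (it is updated by its own MCMC move).

Priors: alpha ~ N(0, sigma_alpha^2 I_q), beta_gamma | gamma ~ N(0, g I_{p_gamma}),
log k ~ N(0, sigma_k^2) (Weibull only), and a model prior that is either
independent Bernoulli(h) inclusion or its Beta-binomial integral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import betaln, expit

__all__ = [
    "Dataset", "ModelIndicator", "Coefficients", "PriorSpec", "CurvaturePair",
    "build_design", "log_likelihood", "eta_score_curvature", "log_coef_prior",
    "log_model_prior", "prior_precision_diag", "log_inclusion_prior_ratio",
]

FAMILIES = ("logistic", "cox_pl", "weibull")


@dataclass(frozen=True)
class Dataset:
    """Immutable input object: covariates, fixed covariates and response.

    For ``family == "logistic"`` the response is the binary vector ``y``;
    for the survival families it is the pair ``(t, d)`` of right-censored
    observation times and event indicators (d_i = 1 means the event was
    observed, d_i = 0 means censored).
    """

    X: np.ndarray
    family: str
    Z: np.ndarray = None
    y: Optional[np.ndarray] = None
    t: Optional[np.ndarray] = None
    d: Optional[np.ndarray] = None
    names: Optional[list] = None

    def __post_init__(self):
        X = np.ascontiguousarray(np.asarray(self.X, dtype=float))
        object.__setattr__(self, "X", X)
        n = X.shape[0]
        if self.Z is None:
            object.__setattr__(self, "Z", np.empty((n, 0)))
        else:
            Z = np.ascontiguousarray(np.asarray(self.Z, dtype=float))
            if Z.ndim == 1:
                Z = Z[:, None]
            object.__setattr__(self, "Z", Z)
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(self.Z)):
            raise ValueError("covariates must be finite")
        if self.family == "logistic":
            if self.y is None:
                raise ValueError("logistic family requires y")
            y = np.asarray(self.y, dtype=float)
            if y.shape != (n,) or not np.all((y == 0) | (y == 1)):
                raise ValueError("y must be a binary vector of length n")
            object.__setattr__(self, "y", y)
        else:
            if self.t is None or self.d is None:
                raise ValueError("survival families require (t, d)")
            t = np.asarray(self.t, dtype=float)
            d = np.asarray(self.d, dtype=float)
            if t.shape != (n,) or np.any(t <= 0):
                raise ValueError("t must be positive of length n")
            if d.shape != (n,) or not np.all((d == 0) | (d == 1)):
                raise ValueError("d must be binary of length n")
            object.__setattr__(self, "t", t)
            object.__setattr__(self, "d", d)
            # risk-set bookkeeping for the partial likelihood: sort times
            # ascending once; risk set R(t_i) = {s : t_s >= t_i}.
            order = np.argsort(t, kind="stable")
            object.__setattr__(self, "_t_order", order)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]


@dataclass(frozen=True)
class ModelIndicator:
    """Binary inclusion vector gamma identifying a model on the lattice."""

    gamma: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.gamma)
        if not np.all((g == 0) | (g == 1)):
            raise ValueError("gamma must be binary")
        object.__setattr__(self, "gamma", np.ascontiguousarray(g, dtype=np.int8))

    @property
    def p_gamma(self) -> int:
        return int(self.gamma.sum())

    @property
    def included(self) -> np.ndarray:
        return np.flatnonzero(self.gamma)

    def flip(self, j: int) -> "ModelIndicator":
        g = self.gamma.copy()
        g[j] = 1 - g[j]
        return ModelIndicator(g)

    def key(self) -> bytes:
        return self.gamma.tobytes()

    @staticmethod
    def empty(p: int) -> "ModelIndicator":
        return ModelIndicator(np.zeros(p, dtype=np.int8))

    @staticmethod
    def from_support(p: int, support) -> "ModelIndicator":
        g = np.zeros(p, dtype=np.int8)
        g[list(support)] = 1
        return ModelIndicator(g)


@dataclass
class Coefficients:
    """theta_gamma = (alpha, beta_gamma), plus log k for the Weibull family."""

    alpha: np.ndarray
    beta_gamma: np.ndarray
    log_k: Optional[float] = None

    def packed(self) -> np.ndarray:
        return np.concatenate([np.atleast_1d(self.alpha), np.atleast_1d(self.beta_gamma)])

    @staticmethod
    def origin(q: int, p_gamma: int, log_k: Optional[float] = None) -> "Coefficients":
        return Coefficients(np.zeros(q), np.zeros(p_gamma), log_k)

    @staticmethod
    def from_packed(theta: np.ndarray, q: int, log_k: Optional[float] = None) -> "Coefficients":
        theta = np.asarray(theta, dtype=float)
        return Coefficients(theta[:q], theta[q:], log_k)


@dataclass
class PriorSpec:
    """Coefficient and model prior settings.

    ``g`` is the slab variance of the selectable coefficients; set
    ``learn_g=True`` to treat it as a half-Cauchy C+(0,1) hyper-parameter with
    ``g`` holding the current state.  Exactly one of ``h`` (fixed prior
    inclusion probability) and ``beta_binom=(a, b)`` must be given.
    """

    g: float = 1.0
    sigma_alpha2: float = 1.0
    h: Optional[float] = 0.5
    beta_binom: Optional[tuple] = None
    sigma_k2: float = 1.0
    learn_g: bool = False

    def __post_init__(self):
        if self.g <= 0 or self.sigma_alpha2 <= 0 or self.sigma_k2 <= 0:
            raise ValueError("variance hyper-parameters must be positive")
        if (self.h is None) == (self.beta_binom is None):
            raise ValueError("exactly one of fixed-h and Beta-binomial must be set")
        if self.h is not None and not 0.0 < self.h < 1.0:
            raise ValueError("h must lie in (0, 1)")
        if self.beta_binom is not None:
            a, b = self.beta_binom
            if a <= 0 or b <= 0:
                raise ValueError("Beta-binomial parameters must be positive")


@dataclass
class CurvaturePair:
    """Score y_tilde and (negated) curvature W of the log-likelihood in eta-space.

    ``W`` is a length-n vector for the diagonal families (logistic, weibull)
    and a dense symmetric PSD n x n matrix for the Cox partial likelihood.
    """

    y_tilde: np.ndarray
    W: np.ndarray
    reference_eta: np.ndarray

    @property
    def diagonal(self) -> bool:
        return self.W.ndim == 1


# ---------------------------------------------------------------------------
# design matrices

def build_design(gamma: ModelIndicator, data: Dataset) -> np.ndarray:
    """J_gamma = [Z X_gamma]: fixed columns first, then the selected columns
    of X in ascending index order."""
    if gamma.gamma.shape[0] != data.p:
        raise ValueError("gamma length does not match number of covariates")
    return np.hstack([data.Z, data.X[:, gamma.included]])


# ---------------------------------------------------------------------------
# log-likelihoods in eta-space

def _logistic_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # sum y*eta - log(1+e^eta), stabilised through logaddexp
    return float(np.dot(y, eta) - np.logaddexp(0.0, eta).sum())


def _cox_risk_logsumexp(eta: np.ndarray, data: Dataset):
    """log of the risk-set sums log sum_{s in R(t_i)} e^{eta_s} for every i.

    Times are processed in descending order so the risk-set sums are reverse
    cumulative sums; tied times share the same risk set (Breslow).
    """
    order = data._t_order
    t_sorted = data.t[order]
    eta_sorted = eta[order]
    m = eta_sorted.max()
    # reverse cumulative sums of exp(eta - m), ascending-time ordering
    rev_cum = np.cumsum(np.exp(eta_sorted - m)[::-1])[::-1]
    # with ties, subject i's risk sum is the cumulative sum starting at the
    # FIRST position holding a time equal to t_i
    first_idx = np.searchsorted(t_sorted, t_sorted, side="left")
    log_risk_sorted = m + np.log(rev_cum[first_idx])
    log_risk = np.empty_like(eta)
    log_risk[order] = log_risk_sorted
    return log_risk


def _cox_loglik(eta: np.ndarray, data: Dataset) -> float:
    log_risk = _cox_risk_logsumexp(eta, data)
    ev = data.d == 1
    return float(np.sum(eta[ev] - log_risk[ev]))


def _weibull_loglik(eta: np.ndarray, data: Dataset, k: float) -> float:
    # sum d_i [log k + k eta_i + (k-1) log t_i] - (t_i e^{eta_i})^k
    log_t = np.log(data.t)
    log_scale = np.clip(k * (log_t + eta), -745.0, 700.0)
    return float(np.sum(data.d * (np.log(k) + k * eta + (k - 1.0) * log_t)
                        - np.exp(log_scale)))


def log_likelihood(theta: Coefficients, gamma: ModelIndicator, data: Dataset) -> float:
    """Family log-likelihood at theta (log partial likelihood for cox_pl)."""
    J = build_design(gamma, data)
    eta = J @ theta.packed()
    return log_likelihood_eta(eta, data, theta.log_k)


def log_likelihood_eta(eta: np.ndarray, data: Dataset, log_k: Optional[float] = None) -> float:
    if data.family == "logistic":
        return _logistic_loglik(eta, data.y)
    if data.family == "cox_pl":
        return _cox_loglik(eta, data)
    k = 1.0 if log_k is None else float(np.exp(log_k))
    return _weibull_loglik(eta, data, k)


# ---------------------------------------------------------------------------
# score and curvature in eta-space

def eta_score_curvature(eta: np.ndarray, gamma: ModelIndicator, data: Dataset,
                        log_k: Optional[float] = None) -> CurvaturePair:
    """First derivative y_tilde and negated second derivative W of the
    log-likelihood with respect to the linear predictor."""
    eta = np.asarray(eta, dtype=float)
    if data.family == "logistic":
        mu = expit(eta)
        return CurvaturePair(data.y - mu, mu * (1.0 - mu), eta)
    if data.family == "cox_pl":
        return _cox_score_curvature(eta, data)
    k = 1.0 if log_k is None else float(np.exp(log_k))
    log_scale = np.clip(k * (np.log(data.t) + eta), -745.0, 700.0)
    u = np.exp(log_scale)                      # (t_i lambda_i)^k
    return CurvaturePair(k * (data.d - u), k * k * u, eta)


def _cox_score_curvature(eta: np.ndarray, data: Dataset) -> CurvaturePair:
    """Dense partial-likelihood curvature, O(n^2).

    With P_{il} = 1{l in R(t_i)} e^{eta_l} / S_i over event times i,
    score_l = d_l - sum_i P_{il} and W = diag(colsum P) - P^T P.
    """
    n = data.n
    order = data._t_order
    eta_s = eta[order]
    t_s = data.t[order]
    d_s = data.d[order]
    ev_pos = np.flatnonzero(d_s == 1)
    if ev_pos.size == 0:
        return CurvaturePair(np.zeros(n), np.zeros((n, n)), eta)
    m = eta_s.max()
    w = np.exp(eta_s - m)
    rev_cum = np.cumsum(w[::-1])[::-1]
    first_idx = np.searchsorted(t_s, t_s, side="left")
    # event i (sorted position) has risk set = sorted positions >= first_idx[i]
    n_ev = ev_pos.size
    P = np.zeros((n_ev, n))
    for r, i in enumerate(ev_pos):
        lo = first_idx[i]
        P[r, lo:] = w[lo:] / rev_cum[lo]
    score_s = d_s - P.sum(axis=0)
    W_s = np.diag(P.sum(axis=0)) - P.T @ P
    # undo the sort
    score = np.empty(n)
    score[order] = score_s
    W = np.empty((n, n))
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    W = W_s[np.ix_(inv, inv)]
    return CurvaturePair(score, W, eta)


# ---------------------------------------------------------------------------
# priors

def prior_precision_diag(gamma: ModelIndicator, data: Dataset, prior: PriorSpec) -> np.ndarray:
    """Diagonal of V_gamma^{-1} for the design [Z X_gamma]."""
    return np.concatenate([
        np.full(data.q, 1.0 / prior.sigma_alpha2),
        np.full(gamma.p_gamma, 1.0 / prior.g),
    ])


_LOG_2PI = float(np.log(2.0 * np.pi))


def log_coef_prior(theta: Coefficients, gamma: ModelIndicator, prior: PriorSpec) -> float:
    """Gaussian log-density N(0, sigma_alpha^2 I_q) x N(0, g I_{p_gamma});
    adds the N(0, sigma_k^2) density of log k when present (Weibull)."""
    alpha = np.atleast_1d(np.asarray(theta.alpha, dtype=float))
    beta = np.atleast_1d(np.asarray(theta.beta_gamma, dtype=float))
    if beta.shape[0] != gamma.p_gamma:
        raise ValueError("beta_gamma dimension does not match gamma")
    q = alpha.shape[0]
    pg = beta.shape[0]
    out = -0.5 * (q + pg) * _LOG_2PI
    out -= 0.5 * q * np.log(prior.sigma_alpha2) + 0.5 * np.dot(alpha, alpha) / prior.sigma_alpha2
    out -= 0.5 * pg * np.log(prior.g) + 0.5 * np.dot(beta, beta) / prior.g
    if theta.log_k is not None:
        out += -0.5 * _LOG_2PI - 0.5 * np.log(prior.sigma_k2) \
            - 0.5 * theta.log_k ** 2 / prior.sigma_k2
    return float(out)


def log_model_prior(gamma: ModelIndicator, prior: PriorSpec) -> float:
    p = gamma.gamma.shape[0]
    pg = gamma.p_gamma
    if prior.h is not None:
        return float(pg * np.log(prior.h) + (p - pg) * np.log1p(-prior.h))
    a, b = prior.beta_binom
    return float(betaln(a + pg, b + p - pg) - betaln(a, b))


def log_inclusion_prior_ratio(p: int, p_gamma_excl: int, prior: PriorSpec) -> float:
    """log p(gamma with j added) - log p(gamma without j), where the model
    without j has size p_gamma_excl.  Used by the warm-start PIPs."""
    if prior.h is not None:
        return float(np.log(prior.h) - np.log1p(-prior.h))
    a, b = prior.beta_binom
    pg = p_gamma_excl
    return float(betaln(a + pg + 1, b + p - pg - 1) - betaln(a + pg, b + p - pg))
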
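"""Baseline add-delete-swap sampler and hyper-parameter moves.

The add-delete-swap (ADS) proposal picks one of the feasible move types
uniformly, then a position (or pair) uniformly within the type, and corrects
the MH ratio for the unequal neighbourhood counts on the two sides.

Hyper-parameter moves:

* ``update_g`` — Gibbs update of the slab variance g under the half-Cauchy
  C+(0,1) hyper-prior, using its inverse-gamma scale-mixture representation
  (g | a ~ IG(1/2, 1/a), a ~ IG(1/2, 1)); the coefficient draw feeding the
  update comes from the Polya-gamma conditional when the engine is DA and
  from the Laplace normal approximation otherwise.
* ``update_log_k`` — adaptive random-walk MH on the Weibull log-shape with a
  Robbins-Monro step-size recursion targeting 0.44 acceptance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import solve_triangular

from .model_core import Dataset, ModelIndicator, PriorSpec, build_design, log_model_prior

__all__ = ["HyperState", "ads_step", "run_ads", "update_g", "update_log_k"]


@dataclass
class HyperState:
    g: float = 1.0
    log_k: float = 0.0
    rw_scale: float = 0.5
    aux_inv_gamma: float = 1.0
    n_k_updates: int = 0


# ---------------------------------------------------------------------------
# add-delete-swap

def _feasible_moves(gamma: ModelIndicator, p: int):
    moves = []
    pg = gamma.p_gamma
    if pg < p:
        moves.append("add")
    if pg > 0:
        moves.append("delete")
    if 0 < pg < p:
        moves.append("swap")
    return moves


def _log_move_prob(gamma: ModelIndicator, move: str, p: int) -> float:
    """log q(gamma -> gamma') for the chosen move type and uniform position
    choice within the type."""
    moves = _feasible_moves(gamma, p)
    pg = gamma.p_gamma
    lp = -np.log(len(moves))
    if move == "add":
        lp -= np.log(p - pg)
    elif move == "delete":
        lp -= np.log(pg)
    else:
        lp -= np.log(pg) + np.log(p - pg)
    return float(lp)


def ads_step(gamma: ModelIndicator, acc_engine, tuning_unused, rng: np.random.Generator,
             log_score_cur: Optional[float] = None):
    """One add-delete-swap MH step; returns (gamma_new, accepted, log_score)."""
    p = gamma.gamma.shape[0]
    moves = _feasible_moves(gamma, p)
    move = moves[rng.integers(len(moves))]
    incl = gamma.included
    excl = np.flatnonzero(gamma.gamma == 0)
    if move == "add":
        j = excl[rng.integers(excl.shape[0])]
        gamma_new = gamma.flip(int(j))
        reverse = "delete"
    elif move == "delete":
        j = incl[rng.integers(incl.shape[0])]
        gamma_new = gamma.flip(int(j))
        reverse = "add"
    else:
        j_in = incl[rng.integers(incl.shape[0])]
        j_out = excl[rng.integers(excl.shape[0])]
        gamma_new = gamma.flip(int(j_in)).flip(int(j_out))
        reverse = "swap"
    s_cur = acc_engine.log_score(gamma) if log_score_cur is None else log_score_cur
    s_new = acc_engine.log_score(gamma_new)
    log_alpha = (s_new - s_cur) \
        + _log_move_prob(gamma_new, reverse, p) - _log_move_prob(gamma, move, p)
    if np.log(rng.random()) < min(0.0, log_alpha):
        return gamma_new, True, s_new
    return gamma, False, s_cur


def run_ads(data: Dataset, prior: PriorSpec, n_iter: int, burnin: int,
            acceptance_engine: str = "cpm",
            rng: Optional[np.random.Generator] = None,
            seed: Optional[int] = None,
            gamma0: Optional[ModelIndicator] = None,
            learn_g: bool = False, learn_k: bool = False,
            log_k: Optional[float] = None,
            cpm_N: int = 32, cpm_rho: float = 0.99,
            record_models: bool = False):
    """Plain add-delete-swap chain with the chosen acceptance-side engine;
    returns a ChainOutput comparable with run_parni's."""
    from .marglik import make_engine
    from .sampler import ChainOutput, TuningState

    if rng is None:
        rng = np.random.default_rng(seed)
    if data.family == "weibull" and log_k is None:
        log_k = 0.0
    gamma = gamma0 if gamma0 is not None else ModelIndicator.empty(data.p)
    kwargs = dict(N=cpm_N, rho=cpm_rho) if acceptance_engine == "cpm" else {}
    acc = make_engine(acceptance_engine, data, prior, log_k=log_k, rng=rng, **kwargs)
    hyper = HyperState(g=prior.g, log_k=log_k if log_k is not None else 0.0)

    log_post = np.empty(n_iter)
    accepts = np.zeros(n_iter, dtype=bool)
    post_counts = np.zeros(data.p)
    models = [] if record_models else None
    s_cur = None
    for it in range(n_iter):
        acc.refresh(rng, gamma)
        if acc.name in ("cpm", "da") or s_cur is None:
            s_cur = acc.log_score(gamma)
        gamma, accepted, s_cur = ads_step(gamma, acc, None, rng, log_score_cur=s_cur)
        accepts[it] = accepted
        log_post[it] = s_cur
        if learn_g:
            hyper = update_g(hyper, acc, gamma, data, prior, rng)
            prior.g = hyper.g
            acc.set_hyper(g=hyper.g)
            s_cur = None
        if learn_k and data.family == "weibull":
            hyper = update_log_k(hyper, gamma, acc, data, prior, rng)
            acc.set_hyper(log_k=hyper.log_k)
            s_cur = None
        if it >= burnin:
            post_counts += gamma.gamma
        if record_models:
            models.append(gamma.included.copy())
    pips = post_counts / max(n_iter - burnin, 1)
    return ChainOutput(models=models, log_post_trace=log_post,
                       accept_flags=accepts, pip_estimate=pips,
                       acceptance_rate=float(accepts.mean()),
                       n_prop_evals=np.zeros(n_iter, dtype=np.int64),
                       p_k_trace=np.zeros(n_iter, dtype=np.int64),
                       tuning=None)


# ---------------------------------------------------------------------------
# hyper-parameter moves

def _draw_beta_gamma(engine, gamma: ModelIndicator, data: Dataset,
                     prior: PriorSpec, rng: np.random.Generator) -> np.ndarray:
    """A draw of the selectable coefficients beta_gamma for the g update:
    exact Polya-gamma conditional under the DA engine, otherwise a draw from
    the Laplace normal approximation N(theta_hat, H^{-1})."""
    from .marglik import DAEngine, pg_draw_theta, map_estimate, _chol_with_jitter

    if gamma.p_gamma == 0:
        return np.empty(0)
    if isinstance(engine, DAEngine):
        theta = pg_draw_theta(gamma, engine.pg_state, data, prior, rng)
        return np.atleast_1d(theta.beta_gamma)
    log_k = getattr(engine, "log_k", None)
    if hasattr(engine, "_map"):
        mode, L = engine._map(gamma)
    elif hasattr(engine, "_cache") and gamma.key() in engine._cache:
        est = engine._cache[gamma.key()]
        mode, L = est.mode, est.neg_hessian_chol
    else:
        mode, H = map_estimate(gamma, data, prior, log_k=log_k)
        L = _chol_with_jitter(H)
    theta = mode.packed() + solve_triangular(
        L, rng.standard_normal(L.shape[0]), lower=True, trans="T")
    return theta[data.q:]


def update_g(hyper: HyperState, engine, gamma: ModelIndicator, data: Dataset,
             prior: PriorSpec, rng: np.random.Generator) -> HyperState:
    """Gibbs update of the slab variance g under a half-Cauchy C+(0,1)
    hyper-prior on the slab scale sqrt(g), via the exact inverse-gamma
    scale-mixture representation (as in horseshoe-type samplers):

        a ~ IG(1/2, 1),   g | a ~ IG(1/2, 1/a)   =>   sqrt(g) ~ C+(0, 1),

    giving the conjugate sweep
        g | a, beta ~ IG((p_gamma+1)/2, beta^T beta / 2 + 1/a),
        a | g ~ IG(1, 1 + 1/g).
    With p_gamma = 0 the move samples from the hyper-prior."""
    beta = _draw_beta_gamma(engine, gamma, data, prior, rng)
    pg = beta.shape[0]
    # a | g
    a = 1.0 / rng.gamma(1.0, 1.0 / (1.0 + 1.0 / hyper.g))
    # g | a, beta
    shape = (pg + 1.0) / 2.0
    scale = 0.5 * float(np.dot(beta, beta)) + 1.0 / a
    g = 1.0 / rng.gamma(shape, 1.0 / scale)
    hyper.g = float(np.clip(g, 1e-8, 1e8))
    hyper.aux_inv_gamma = a
    return hyper


def update_log_k(hyper: HyperState, gamma: ModelIndicator, acc_engine,
                 data: Dataset, prior: PriorSpec,
                 rng: np.random.Generator, target: float = 0.44) -> HyperState:
    """Adaptive random-walk MH on log k (Weibull shape).

    The proposal is symmetric, so it cancels in the acceptance ratio; the
    engine's marginal-likelihood value already includes the N(0, sigma_k^2)
    prior on log k, so the ratio of engine values is the full MH ratio.
    The step size follows a Robbins-Monro recursion toward the target
    acceptance rate with diminishing step L^{-0.7}.
    """
    if data.family != "weibull":
        raise ValueError("log k update applies to the Weibull family only")
    hyper.n_k_updates += 1
    cur = acc_engine.estimate(gamma).log_value
    log_k_new = hyper.log_k + hyper.rw_scale * rng.standard_normal()
    saved = acc_engine.log_k
    acc_engine.set_hyper(log_k=log_k_new)
    new = acc_engine.estimate(gamma).log_value
    log_alpha = new - cur
    alpha = float(np.exp(min(0.0, log_alpha)))
    if np.log(rng.random()) < min(0.0, log_alpha):
        hyper.log_k = float(log_k_new)
    else:
        acc_engine.set_hyper(log_k=saved)
    step = hyper.n_k_updates ** -0.7
    hyper.rw_scale = float(np.clip(
        np.exp(np.log(hyper.rw_scale) + step * (alpha - target)), 1e-3, 10.0))
    return hyper
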
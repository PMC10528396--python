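"""The point-wise adaptive random-neighbourhood informed (PARNI) proposal.

One iteration:

1. draw a flip-set k, with k_j ~ Bernoulli(A_j) where gamma_j = 0 and
   Bernoulli(D_j) where gamma_j = 1, and a uniformly random order over the
   active positions;
2. walk through the p_k two-model sub-neighbourhoods, at each step flipping
   the current position with the locally informed probability built from the
   balancing function g_H(x) = min(1, x) applied to the ratio of
   proposal-side posterior scores (times the p(k|gamma) ratio), damped by
   the non-informative jumping factor (zeta/(1-zeta))^{d_H};
3. accept or reject the endpoint with the Metropolis-Hastings ratio under
   the acceptance-side engine, where the reverse-path probability re-walks
   the same sub-neighbourhood pairs in reverse order (no extra engine
   calls);
4. adapt: ergodic PIP averages blended with the warm-start estimate through
   the phi_L schedule drive A and D; zeta follows a Robbins-Monro recursion
   on the logit scale; the adaptive-ALA initial guess eta_hat is the running
   mean of MAP linear predictors of the sampled models.

All adaptation steps are diminishing, so the chain keeps the invariant
distribution defined by the acceptance-side engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model_core import Dataset, ModelIndicator, PriorSpec, build_design, log_model_prior
from .marglik import make_engine, warm_start_pips, _EngineBase
from .aux_samplers import HyperState, update_g, update_log_k

__all__ = [
    "TuningState", "NeighbourhoodDraw", "ChainOutput", "sample_k", "hamming",
    "balancing_gH", "log_k_density", "pointwise_propose", "mh_accept",
    "adapt_pips", "adapt_zeta", "adapt_eta_hat", "run_parni",
]


@dataclass
class TuningState:
    """All PARNI adaptive quantities."""

    A: np.ndarray
    D: np.ndarray
    zeta: float
    pi_warm: np.ndarray              # warm-start PIP estimate pi~(0)
    inclusion_counts: np.ndarray     # running sum of gamma over iterations
    iter: int
    N_b: int
    eta_hat: np.ndarray
    epsilon: float = 1e-3
    alpha_target: float = 0.234
    adapt_zeta_flag: bool = True

    @staticmethod
    def initial(pi_warm: np.ndarray, n: int, N_b: int, epsilon: float = 1e-3,
                zeta: float = 0.5, alpha_target: float = 0.234,
                adapt_zeta_flag: bool = True) -> "TuningState":
        pi0 = np.clip(pi_warm, epsilon, 1.0 - epsilon)
        A = np.clip(np.minimum(1.0, pi0 / (1.0 - pi0)), epsilon, 1.0 - epsilon)
        D = np.clip(np.minimum(1.0, (1.0 - pi0) / pi0), epsilon, 1.0 - epsilon)
        return TuningState(A=A, D=D, zeta=zeta, pi_warm=pi0,
                           inclusion_counts=np.zeros(pi0.shape[0]), iter=0,
                           N_b=N_b, eta_hat=np.zeros(n), epsilon=epsilon,
                           alpha_target=alpha_target,
                           adapt_zeta_flag=adapt_zeta_flag)


@dataclass
class NeighbourhoodDraw:
    k: np.ndarray
    order: np.ndarray      # random permutation of the active positions

    @property
    def p_k(self) -> int:
        return int(self.order.shape[0])


@dataclass
class ChainOutput:
    models: list
    log_post_trace: np.ndarray
    accept_flags: np.ndarray
    pip_estimate: np.ndarray
    acceptance_rate: float
    n_prop_evals: np.ndarray      # proposal-side engine calls per iteration
    p_k_trace: np.ndarray
    tuning: TuningState
    g_trace: Optional[np.ndarray] = None
    log_k_trace: Optional[np.ndarray] = None


def hamming(gamma1: ModelIndicator, gamma2: ModelIndicator) -> int:
    if gamma1.gamma.shape != gamma2.gamma.shape:
        raise ValueError("length mismatch")
    return int(np.sum(gamma1.gamma != gamma2.gamma))


def balancing_gH(x: float) -> float:
    """Hastings' balancing function min(1, x); satisfies g(x) = x g(1/x)."""
    if x <= 0:
        raise ValueError("balancing function requires x > 0")
    return min(1.0, x)


def sample_k(gamma: ModelIndicator, tuning: TuningState,
             rng: np.random.Generator) -> NeighbourhoodDraw:
    """k_j ~ Bern(A_j) off the model, Bern(D_j) on it, independently."""
    probs = np.where(gamma.gamma == 1, tuning.D, tuning.A)
    k = (rng.random(probs.shape[0]) < probs).astype(np.int8)
    active = np.flatnonzero(k)
    order = rng.permutation(active)
    return NeighbourhoodDraw(k, order)


def log_k_density(k: np.ndarray, gamma: ModelIndicator, tuning: TuningState) -> float:
    """log p(k | gamma) under the product-Bernoulli neighbourhood law."""
    probs = np.where(gamma.gamma == 1, tuning.D, tuning.A)
    return float(np.sum(np.where(k == 1, np.log(probs), np.log1p(-probs))))


def _log_k_ratio_at(j: int, gamma_from: ModelIndicator, tuning: TuningState) -> float:
    """log p(k_j=1 | flipped gamma_j) - log p(k_j=1 | gamma_j): only position
    j contributes to the p(k|gamma') / p(k|gamma) ratio of a single flip."""
    if gamma_from.gamma[j] == 0:   # flip turns it on: A_j -> D_j
        return float(np.log(tuning.D[j]) - np.log(tuning.A[j]))
    return float(np.log(tuning.A[j]) - np.log(tuning.D[j]))


def pointwise_propose(gamma: ModelIndicator, draw: NeighbourhoodDraw,
                      tuning: TuningState, engine: _EngineBase,
                      rng: np.random.Generator):
    """Walk the sub-neighbourhoods in the drawn order; return the proposal,
    both path log-probabilities and the per-iteration evaluation count.

    Each two-model kernel gives the flip log-odds
        lf = log g_H( exp(ds + dk) ) + log(zeta/(1-zeta))
    where ds is the proposal-side score difference, dk the p(k|.) ratio term
    and the Hamming factor contributes (zeta/(1-zeta))^1 for the flip and
    ^0 for staying.  The reverse path probability is accumulated by
    re-walking the identical pairs in reverse order, reusing the cached
    scores, so the engine is called exactly twice per sub-neighbourhood.
    """
    log_zeta_odds = float(np.log(tuning.zeta) - np.log1p(-tuning.zeta))
    cur = gamma
    n_evals = 0
    # forward walk
    steps = []      # (j, s_cur, s_flip, flipped)
    log_q_fwd = 0.0
    for j in draw.order:
        s_cur = engine.log_score(cur)
        flip_model = cur.flip(int(j))
        s_flip = engine.log_score(flip_model)
        n_evals += 2
        if not np.isfinite(s_flip) and not np.isfinite(s_cur):
            lf = -np.inf
        else:
            ds = s_flip - s_cur + _log_k_ratio_at(int(j), cur, tuning)
            lf = min(0.0, ds) + log_zeta_odds
        log_p_flip = lf - np.logaddexp(0.0, lf)
        log_p_stay = -np.logaddexp(0.0, lf)
        flipped = np.log(rng.random()) < log_p_flip
        steps.append((int(j), s_cur, s_flip, bool(flipped)))
        if flipped:
            log_q_fwd += log_p_flip
            cur = flip_model
        else:
            log_q_fwd += log_p_stay
    gamma_prime = cur
    # reverse walk over the same pairs in reverse order: at the step for
    # position j the reverse chain sits at the post-step model and must move
    # to the pre-step model
    log_q_rev = 0.0
    for j, s_cur, s_flip, flipped in reversed(steps):
        # the reverse chain sits at the post-step model of this pair; its
        # position-j value decides the direction of the p(k|.) ratio
        if flipped:
            s_at, s_to = s_flip, s_cur
            cur_val = 1 - int(gamma.gamma[j])
        else:
            s_at, s_to = s_cur, s_flip
            cur_val = int(gamma.gamma[j])
        ds = s_to - s_at
        if cur_val == 0:
            ds += float(np.log(tuning.D[j]) - np.log(tuning.A[j]))
        else:
            ds += float(np.log(tuning.A[j]) - np.log(tuning.D[j]))
        lf = min(0.0, ds) + log_zeta_odds
        if flipped:
            log_q_rev += lf - np.logaddexp(0.0, lf)
        else:
            log_q_rev += -np.logaddexp(0.0, lf)
    return gamma_prime, log_q_fwd, log_q_rev, n_evals


def mh_accept(gamma: ModelIndicator, gamma_prime: ModelIndicator,
              draw: NeighbourhoodDraw, log_q_fwd: float, log_q_rev: float,
              acc_engine: _EngineBase, tuning: TuningState,
              rng: np.random.Generator,
              log_score_cur: Optional[float] = None):
    """MH correction with the acceptance-side engine:
    alpha = min{1, [p-hat(y|g')p(g')p(k|g') q_k(g',g)] / [p-hat(y|g)p(g)p(k|g) q_k(g,g')]}.
    Returns (accepted, new_gamma, log_score_new, alpha)."""
    if hamming(gamma, gamma_prime) == 0:
        s = acc_engine.log_score(gamma) if log_score_cur is None else log_score_cur
        return True, gamma, s, 1.0
    s_cur = acc_engine.log_score(gamma) if log_score_cur is None else log_score_cur
    s_new = acc_engine.log_score(gamma_prime)
    # p(k|gamma')/p(k|gamma): only flipped positions contribute
    dk = 0.0
    for j in np.flatnonzero(gamma.gamma != gamma_prime.gamma):
        dk += _log_k_ratio_at(int(j), gamma, tuning)
    log_alpha = (s_new - s_cur) + dk + (log_q_rev - log_q_fwd)
    alpha = min(1.0, float(np.exp(min(0.0, log_alpha))))
    if np.log(rng.random()) < min(0.0, log_alpha):
        return True, gamma_prime, s_new, alpha
    return False, gamma, s_cur, alpha


def _phi(l: int, N_b: int) -> float:
    """Warm-start/ergodic blending weight: > 1/2 during burn-in, 1/2 at the
    boundary, decaying like l^{-1/2} afterwards."""
    if l <= N_b:
        return 1.0 - 0.5 * (N_b - l + 1) ** -0.5
    return 0.5 * (l - N_b) ** -0.5


def adapt_pips(tuning: TuningState, gamma_new: ModelIndicator) -> TuningState:
    """Ergodic PIP average blended with the warm start; A and D follow the
    informed map A = min(1, pi/(1-pi)), D = min(1, (1-pi)/pi), clipped."""
    tuning.iter += 1
    tuning.inclusion_counts += gamma_new.gamma
    L = tuning.iter
    pi_erg = tuning.inclusion_counts / L
    phi = _phi(L, tuning.N_b)
    pi_hat = np.clip(phi * tuning.pi_warm + (1.0 - phi) * pi_erg,
                     tuning.epsilon, 1.0 - tuning.epsilon)
    eps = tuning.epsilon
    tuning.A = np.clip(np.minimum(1.0, pi_hat / (1.0 - pi_hat)), eps, 1.0 - eps)
    tuning.D = np.clip(np.minimum(1.0, (1.0 - pi_hat) / pi_hat), eps, 1.0 - eps)
    return tuning


def adapt_zeta(tuning: TuningState, alpha: float) -> TuningState:
    """Robbins-Monro on logit(zeta) toward the target acceptance rate, with
    diminishing step L^{-0.7}."""
    if not tuning.adapt_zeta_flag:
        return tuning
    L = max(tuning.iter, 1)
    logit = np.log(tuning.zeta) - np.log1p(-tuning.zeta)
    logit += L ** -0.7 * (alpha - tuning.alpha_target)
    z = 1.0 / (1.0 + np.exp(-logit))
    tuning.zeta = float(np.clip(z, tuning.epsilon, 1.0 - tuning.epsilon))
    return tuning


def adapt_eta_hat(tuning: TuningState, eta_mode: Optional[np.ndarray]) -> TuningState:
    """Running mean of MAP linear predictors of the sampled models; skipped
    when the acceptance-side engine exposes no mode (DA)."""
    if eta_mode is None:
        return tuning
    L = max(tuning.iter, 1)
    tuning.eta_hat += (eta_mode - tuning.eta_hat) / L
    return tuning


def run_parni(data: Dataset, prior: PriorSpec, n_iter: int, burnin: int,
              proposal_engine: str = "adaptive_ala",
              acceptance_engine: str = "cpm",
              rng: Optional[np.random.Generator] = None,
              seed: Optional[int] = None,
              gamma0: Optional[ModelIndicator] = None,
              epsilon: float = 1e-3, zeta: float = 0.5,
              adapt_zeta_flag: bool = True, alpha_target: float = 0.234,
              learn_g: bool = False, learn_k: bool = False,
              log_k: Optional[float] = None,
              cpm_N: int = 32, cpm_rho: float = 0.99,
              record_models: bool = False) -> ChainOutput:
    """Run the full PARNI chain (Algorithm: warm start, then iterate
    sample_k -> informed walk -> MH correction -> adaptation, with optional
    hyper-parameter moves for g and the Weibull shape)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if burnin >= n_iter:
        raise ValueError("burnin must be smaller than n_iter")
    if data.family == "weibull" and log_k is None:
        log_k = 0.0
    gamma = gamma0 if gamma0 is not None else ModelIndicator.empty(data.p)

    prop_kwargs = dict(N=cpm_N, rho=cpm_rho) if proposal_engine == "cpm" else {}
    acc_kwargs = dict(N=cpm_N, rho=cpm_rho) if acceptance_engine == "cpm" else {}
    prop = make_engine(proposal_engine, data, prior, log_k=log_k, rng=rng, **prop_kwargs)
    if acceptance_engine == proposal_engine:
        acc = prop
    else:
        acc = make_engine(acceptance_engine, data, prior, log_k=log_k, rng=rng, **acc_kwargs)

    pi_warm = warm_start_pips(gamma, data, prior, log_k=log_k, epsilon=epsilon)
    tuning = TuningState.initial(pi_warm, data.n, burnin, epsilon, zeta,
                                 alpha_target, adapt_zeta_flag)

    hyper = HyperState(g=prior.g, log_k=log_k if log_k is not None else 0.0)

    log_post = np.empty(n_iter)
    accepts = np.zeros(n_iter, dtype=bool)
    n_evals = np.zeros(n_iter, dtype=np.int64)
    p_k_trace = np.zeros(n_iter, dtype=np.int64)
    post_counts = np.zeros(data.p)
    models = [] if record_models else None
    g_trace = np.empty(n_iter) if learn_g else None
    k_trace = np.empty(n_iter) if learn_k else None
    s_cur: Optional[float] = None

    for it in range(n_iter):
        acc.refresh(rng, gamma)
        if acc is not prop:
            prop.refresh(rng, gamma)
        if acc.name in ("cpm", "da") or s_cur is None:
            s_cur = acc.log_score(gamma)      # shared randomness scores both sides
        draw = sample_k(gamma, tuning, rng)
        p_k_trace[it] = draw.p_k
        gamma_new, lq_f, lq_r, ne = pointwise_propose(gamma, draw, tuning, prop, rng)
        n_evals[it] = ne
        accepted, gamma, s_cur, alpha = mh_accept(
            gamma, gamma_new, draw, lq_f, lq_r, acc, tuning, rng,
            log_score_cur=s_cur)
        accepts[it] = accepted and draw.p_k > 0
        log_post[it] = s_cur

        adapt_pips(tuning, gamma)
        adapt_zeta(tuning, alpha if draw.p_k > 0 else tuning.alpha_target)
        if getattr(prop, "name", "") == "adaptive_ala":
            eta_mode = acc.mode_eta(gamma) if acc.has_mode else None
            adapt_eta_hat(tuning, eta_mode)
            prop.eta_hat = tuning.eta_hat

        if learn_g:
            hyper = update_g(hyper, acc, gamma, data, prior, rng)
            prior.g = hyper.g
            prop.set_hyper(g=hyper.g)
            if acc is not prop:
                acc.set_hyper(g=hyper.g)
            s_cur = None
            g_trace[it] = hyper.g
        if learn_k and data.family == "weibull":
            hyper = update_log_k(hyper, gamma, acc, data, prior, rng)
            prop.set_hyper(log_k=hyper.log_k)
            if acc is not prop:
                acc.set_hyper(log_k=hyper.log_k)
            s_cur = None
            k_trace[it] = hyper.log_k

        if it >= burnin:
            post_counts += gamma.gamma
        if record_models:
            models.append(gamma.included.copy())

    pips = post_counts / max(n_iter - burnin, 1)
    return ChainOutput(models=models, log_post_trace=log_post,
                       accept_flags=accepts, pip_estimate=pips,
                       acceptance_rate=float(accepts.mean()),
                       n_prop_evals=n_evals, p_k_trace=p_k_trace,
                       tuning=tuning, g_trace=g_trace, log_k_trace=k_trace)
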
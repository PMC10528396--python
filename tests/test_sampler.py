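"""PARNI proposal machinery: neighbourhoods, informed walk, MH correction,
adaptation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from parnibvs import (
    ModelIndicator, PriorSpec, enumerate_posterior, make_enumerable_fixture,
    run_parni,
)
from parnibvs.marglik import LAEngine, make_engine
from parnibvs.sampler import (
    NeighbourhoodDraw, TuningState, _phi, adapt_eta_hat, adapt_pips,
    adapt_zeta, balancing_gH, hamming, log_k_density, mh_accept,
    pointwise_propose, sample_k,
)


class FlatEngine:
    """Engine stub with a constant score: the flat target."""

    name = "flat"
    exact_target = True
    has_mode = False

    def __init__(self, value=0.0):
        self.value = value
        self.n_calls = 0

    def log_score(self, gamma):
        self.n_calls += 1
        return self.value

    def refresh(self, rng, gamma=None):
        pass


class TableEngine:
    """Engine stub scoring models from an explicit table."""

    name = "table"
    exact_target = True
    has_mode = False

    def __init__(self, table):
        self.table = table
        self.n_calls = 0

    def log_score(self, gamma):
        self.n_calls += 1
        return self.table[tuple(gamma.gamma.tolist())]

    def refresh(self, rng, gamma=None):
        pass


def _tuning(p, A=0.5, D=0.5, zeta=0.5, eps=1e-3):
    return TuningState(A=np.full(p, A), D=np.full(p, D), zeta=zeta,
                       pi_warm=np.full(p, 0.5), inclusion_counts=np.zeros(p),
                       iter=0, N_b=100, eta_hat=np.zeros(4), epsilon=eps)


def test_hamming_basic():
    a = ModelIndicator(np.array([0, 0, 0], dtype=np.int8))
    b = ModelIndicator(np.array([1, 0, 1], dtype=np.int8))
    assert hamming(a, b) == 2
    assert hamming(a, a) == 0
    assert hamming(a, b) == hamming(b, a)
    with pytest.raises(ValueError):
        hamming(a, ModelIndicator(np.array([0, 1], dtype=np.int8)))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(min_value=-12, max_value=12))
def test_balancing_function_identity(logx):
    x = float(np.exp(logx))
    assert abs(balancing_gH(x) - x * balancing_gH(1.0 / x)) < 1e-12
    assert balancing_gH(1.0) == 1.0
    assert balancing_gH(4.0) == 1.0
    assert balancing_gH(0.25) == 0.25


def test_balancing_function_rejects_nonpositive():
    with pytest.raises(ValueError):
        balancing_gH(0.0)


def test_sample_k_marginal_frequencies():
    p = 4
    tun = _tuning(p)
    tun.A = np.array([0.3, 0.3, 0.3, 0.3])
    tun.D = np.array([0.7, 0.7, 0.7, 0.7])
    gamma = ModelIndicator(np.array([0, 0, 1, 1], dtype=np.int8))
    rng = np.random.default_rng(0)
    n = 100_000
    counts = np.zeros(p)
    for _ in range(n):
        counts += sample_k(gamma, tun, rng).k
    freq = counts / n
    for j, target in enumerate([0.3, 0.3, 0.7, 0.7]):
        se = np.sqrt(target * (1 - target) / n)
        assert abs(freq[j] - target) < 3.5 * se


def test_k_density_matches_simulation():
    """Chi-square GOF of simulated k vectors against the product density."""
    from scipy.stats import chisquare
    p = 5
    tun = _tuning(p)
    tun.A = np.array([0.2, 0.5, 0.8, 0.3, 0.6])
    tun.D = np.array([0.7, 0.1, 0.4, 0.9, 0.5])
    gamma = ModelIndicator(np.array([0, 1, 0, 1, 0], dtype=np.int8))
    rng = np.random.default_rng(1)
    n = 100_000
    counts = {}
    for _ in range(n):
        k = tuple(sample_k(gamma, tun, rng).k.tolist())
        counts[k] = counts.get(k, 0) + 1
    ks = list(itertools.product((0, 1), repeat=p))
    obs = np.array([counts.get(k, 0) for k in ks], dtype=float)
    expected = np.array([
        np.exp(log_k_density(np.array(k, dtype=np.int8), gamma, tun))
        for k in ks]) * n
    stat, pval = chisquare(obs, expected)
    assert pval > 1e-3


def test_expected_flipset_size_at_epsilon():
    p = 50
    eps = 0.01
    tun = _tuning(p, A=eps, D=eps)
    gamma = ModelIndicator.empty(p)
    rng = np.random.default_rng(2)
    sizes = [sample_k(gamma, tun, rng).p_k for _ in range(20_000)]
    assert np.mean(sizes) == pytest.approx(p * eps, abs=0.02)


def test_empty_flipset_returns_identity():
    p = 4
    tun = _tuning(p)
    gamma = ModelIndicator.empty(p)
    draw = NeighbourhoodDraw(np.zeros(p, dtype=np.int8), np.empty(0, dtype=int))
    eng = FlatEngine()
    g2, lf, lr, ne = pointwise_propose(gamma, draw, tun, eng, np.random.default_rng(3))
    assert hamming(gamma, g2) == 0 and lf == 0.0 and lr == 0.0 and ne == 0


def test_flat_target_flips_with_probability_half():
    p = 4
    tun = _tuning(p, zeta=0.5)
    gamma = ModelIndicator.empty(p)
    rng = np.random.default_rng(4)
    eng = FlatEngine()
    dists = []
    for _ in range(20_000):
        k = np.array([1, 1, 0, 0], dtype=np.int8)
        draw = NeighbourhoodDraw(k, np.array([0, 1]))
        g2, *_ = pointwise_propose(gamma, draw, tun, eng, rng)
        dists.append(hamming(gamma, g2))
    # each of the two positions flips independently w.p. 1/2
    assert np.mean(dists) == pytest.approx(1.0, abs=0.02)


def test_forward_path_probabilities_sum_to_one():
    """Brute-force path-sum oracle: over all 2^{p_k} flip patterns (for the
    same drawn order), the walk probabilities sum to 1, and the reported
    log_q_forward matches an independent reimplementation."""
    p = 4
    rng = np.random.default_rng(5)
    table = {bits: float(v) for bits, v in zip(
        itertools.product((0, 1), repeat=p),
        rng.normal(scale=2.0, size=2 ** p))}
    eng = TableEngine(table)
    tun = _tuning(p, A=0.3, D=0.6, zeta=0.4)
    gamma = ModelIndicator(np.array([0, 1, 0, 0], dtype=np.int8))
    k = np.array([1, 1, 1, 0], dtype=np.int8)
    order = np.array([2, 0, 1])
    lzo = np.log(tun.zeta) - np.log1p(-tun.zeta)

    def k_ratio(j, gam):
        if gam.gamma[j] == 0:
            return np.log(tun.D[j]) - np.log(tun.A[j])
        return np.log(tun.A[j]) - np.log(tun.D[j])

    def path_logprob(pattern):
        cur = gamma
        lq = 0.0
        for j, flip in zip(order, pattern):
            ds = (eng.log_score(cur.flip(int(j))) - eng.log_score(cur)
                  + k_ratio(int(j), cur))
            lf = min(0.0, ds) + lzo
            lp_flip = lf - np.logaddexp(0.0, lf)
            lp_stay = -np.logaddexp(0.0, lf)
            if flip:
                lq += lp_flip
                cur = cur.flip(int(j))
            else:
                lq += lp_stay
        return lq, cur

    total = 0.0
    endpoint_logq = {}
    for pattern in itertools.product((0, 1), repeat=3):
        lq, endpoint = path_logprob(pattern)
        total += np.exp(lq)
        endpoint_logq[endpoint.key()] = lq
    assert total == pytest.approx(1.0, abs=1e-12)

    draw = NeighbourhoodDraw(k, order)
    g2, lqf, lqr, ne = pointwise_propose(gamma, draw, tun, eng,
                                         np.random.default_rng(6))
    assert lqf == pytest.approx(endpoint_logq[g2.key()], abs=1e-12)
    assert ne == 2 * 3


def test_trivial_proposal_always_accepted():
    p = 3
    tun = _tuning(p)
    gamma = ModelIndicator.empty(p)
    eng = FlatEngine()
    draw = NeighbourhoodDraw(np.zeros(p, dtype=np.int8), np.empty(0, dtype=int))
    accepted, g2, s, alpha = mh_accept(gamma, gamma, draw, 0.0, 0.0, eng, tun,
                                       np.random.default_rng(7))
    assert accepted and alpha == 1.0


def test_single_flip_alpha_matches_two_state_hastings_ratio():
    """Forced p_k=1 flip with a deterministic engine on both sides: the MH
    alpha equals the closed-form two-state informed-flip ratio."""
    p = 3
    rng = np.random.default_rng(8)
    table = {bits: float(v) for bits, v in zip(
        itertools.product((0, 1), repeat=p), rng.normal(size=8))}
    eng = TableEngine(table)
    tun = _tuning(p, A=0.25, D=0.65, zeta=0.35)
    gamma = ModelIndicator(np.array([0, 1, 0], dtype=np.int8))
    j = 0
    k = np.array([1, 0, 0], dtype=np.int8)
    draw = NeighbourhoodDraw(k, np.array([j]))
    # force the flip by trying seeds until the walk flips
    for seed in range(100):
        g2, lqf, lqr, _ = pointwise_propose(gamma, draw, tun, eng,
                                            np.random.default_rng(seed))
        if hamming(gamma, g2) == 1:
            break
    assert hamming(gamma, g2) == 1
    _, _, _, alpha = mh_accept(gamma, g2, draw, lqf, lqr, eng, tun,
                               np.random.default_rng(9))
    # closed form: pi(g')p(k|g')q(g'->g) / pi(g)p(k|g)q(g->g')
    lzo = np.log(tun.zeta) - np.log1p(-tun.zeta)
    s, s2 = table[tuple(gamma.gamma.tolist())], table[tuple(g2.gamma.tolist())]
    dk = np.log(tun.D[j]) - np.log(tun.A[j])          # gamma_j: 0 -> 1
    lf_fwd = min(0.0, (s2 - s) + dk) + lzo
    q_fwd = np.exp(lf_fwd) / (1 + np.exp(lf_fwd))
    lf_rev = min(0.0, (s - s2) - dk) + lzo
    q_rev = np.exp(lf_rev) / (1 + np.exp(lf_rev))
    expected = min(1.0, np.exp(s2 + dk - s) * q_rev / q_fwd)
    assert alpha == pytest.approx(expected, rel=1e-12)


def test_detailed_balance_on_enumerable_target():
    """Frozen tuning, LA engine on both sides, p=4: transition counts between
    model pairs are symmetric within Monte-Carlo error."""
    data, _ = make_enumerable_fixture("logistic", seed=60, n=60, p=4, n_effects=2)
    prior = PriorSpec(g=1.0, h=0.3)
    eng = LAEngine(data, prior)
    tun = _tuning(4, A=0.4, D=0.4, zeta=0.45)
    rng = np.random.default_rng(61)
    # start from a draw of the stationary distribution (enumeration)
    enum = enumerate_posterior(data, prior, eng)
    idx = rng.choice(len(enum["pmp"]), p=enum["pmp"])
    gamma = ModelIndicator(np.array(enum["gammas"][idx], dtype=np.int8))
    counts = {}
    n_steps = 100_000
    s_cur = eng.log_score(gamma)
    for _ in range(n_steps):
        draw = sample_k(gamma, tun, rng)
        g2, lqf, lqr, _ = pointwise_propose(gamma, draw, tun, eng, rng)
        prev = gamma
        accepted, gamma, s_cur, _ = mh_accept(prev, g2, draw, lqf, lqr, eng,
                                              tun, rng, log_score_cur=s_cur)
        key = (prev.key(), gamma.key())
        counts[key] = counts.get(key, 0) + 1
    checked = 0
    for (a, b), nab in counts.items():
        if a >= b:
            continue
        nba = counts.get((b, a), 0)
        if nab + nba < 200:
            continue
        checked += 1
        assert abs(nab - nba) < 4.5 * np.sqrt(nab + nba), (nab, nba)
    assert checked >= 3


def test_phi_schedule_shape():
    N_b = 100
    assert _phi(N_b, N_b) == pytest.approx(0.5)
    assert _phi(N_b + 4, N_b) == pytest.approx(0.25)
    assert _phi(N_b - 3, N_b) == pytest.approx(0.75)
    ls = np.arange(1, 400)
    vals = np.array([_phi(l, N_b) for l in ls])
    assert np.all(vals[: N_b - 1] > 0.5)
    assert np.all(np.diff(vals[N_b:]) <= 0)


def test_adapt_pips_symmetric_point_clips():
    p = 3
    tun = _tuning(p, eps=0.001)
    tun.pi_warm = np.full(p, 0.5)
    tun.inclusion_counts = np.array([49.0, 0.0, 25.0])
    tun.iter = 99
    tun.N_b = 100
    adapt_pips(tun, ModelIndicator(np.array([1, 0, 0], dtype=np.int8)))
    # pi_hat for j=0: phi=1/2 at the burn-in boundary and both the warm-start
    # and ergodic estimates equal 0.5, so A=D=1 -> clipped to 1-eps
    assert tun.A[0] == pytest.approx(1 - tun.epsilon)
    assert tun.D[0] == pytest.approx(1 - tun.epsilon)


def test_adapt_zeta_fixed_point_and_decay():
    tun = _tuning(3)
    tun.iter = 10
    z0 = tun.zeta
    adapt_zeta(tun, tun.alpha_target)
    assert tun.zeta == pytest.approx(z0)
    # all-reject stream drifts down, bounded steps
    prev_logit = np.log(tun.zeta / (1 - tun.zeta))
    for i in range(50):
        tun.iter += 1
        adapt_zeta(tun, 0.0)
        logit = np.log(tun.zeta / (1 - tun.zeta))
        assert logit < prev_logit
        assert abs(logit - prev_logit) <= tun.iter ** -0.7 * tun.alpha_target + 1e-12
        prev_logit = logit


def test_adapt_eta_hat_running_mean_identity():
    tun = _tuning(3)
    tun.eta_hat = np.zeros(4)
    rng = np.random.default_rng(62)
    etas = rng.normal(size=(20, 4))
    for i, e in enumerate(etas, start=1):
        tun.iter = i
        adapt_eta_hat(tun, e)
    np.testing.assert_allclose(tun.eta_hat, etas.mean(axis=0), atol=1e-10)


def test_run_parni_deterministic_under_seed(logistic_small):
    data, _ = logistic_small
    prior = PriorSpec(g=1.0, h=0.3)
    out1 = run_parni(data, prior, 500, 100, proposal_engine="la",
                     acceptance_engine="la", seed=7)
    out2 = run_parni(data, prior, 500, 100, proposal_engine="la",
                     acceptance_engine="la", seed=7)
    np.testing.assert_array_equal(out1.log_post_trace, out2.log_post_trace)
    np.testing.assert_array_equal(out1.pip_estimate, out2.pip_estimate)
    np.testing.assert_array_equal(out1.accept_flags, out2.accept_flags)


def test_run_parni_recovers_dominant_variable():
    """A single huge effect on an orthogonal-ish design is found quickly."""
    from parnibvs.synthetic import SimConfig, simulate
    cfg = SimConfig(n=300, p=20, family="logistic", true_support=(5,),
                    effect_sizes=(3.0,), correlation="independent", seed=63)
    data, truth = simulate(cfg)
    prior = PriorSpec(g=1.0, h=None, beta_binom=(1.0, 19.0))
    out = run_parni(data, prior, 5000, 1000, proposal_engine="adaptive_ala",
                    acceptance_engine="la", seed=64)
    assert out.pip_estimate[5] > 0.95
    null = np.delete(out.pip_estimate, 5)
    assert np.all(null < 0.2)


def test_proposal_evaluation_count_is_twice_flipset_size(logistic_small):
    data, _ = logistic_small
    prior = PriorSpec(g=1.0, h=0.3)
    out = run_parni(data, prior, 400, 100, proposal_engine="la",
                    acceptance_engine="la", seed=65)
    np.testing.assert_array_equal(out.n_prop_evals, 2 * out.p_k_trace)


def test_diminishing_adaptation_of_A():
    """sup_j |A^(L+1) - A^(L)| shrinks along the run."""
    data, _ = make_enumerable_fixture("logistic", seed=66, n=60, p=5, n_effects=2)
    prior = PriorSpec(g=1.0, h=0.3)
    rng = np.random.default_rng(67)
    from parnibvs.marglik import warm_start_pips
    pi0 = warm_start_pips(ModelIndicator.empty(5), data, prior)
    tun = TuningState.initial(pi0, data.n, N_b=200)
    eng = LAEngine(data, prior)
    gamma = ModelIndicator.empty(5)
    diffs = []
    s_cur = eng.log_score(gamma)
    for _ in range(2000):
        draw = sample_k(gamma, tun, rng)
        g2, lqf, lqr, _ = pointwise_propose(gamma, draw, tun, eng, rng)
        _, gamma, s_cur, _ = mh_accept(gamma, g2, draw, lqf, lqr, eng, tun,
                                       rng, log_score_cur=s_cur)
        A_prev = tun.A.copy()
        adapt_pips(tun, gamma)
        diffs.append(np.max(np.abs(tun.A - A_prev)))
    early = np.max(diffs[100:200])
    late = np.max(diffs[-100:])
    assert late <= early + 1e-12
    assert late < 0.05
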
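"""Full-enumeration oracle and the benchmark harness.

``enumerate_posterior`` scores every model on the 2^p lattice with a chosen
engine, normalises to posterior model probabilities and marginalises to
inclusion probabilities — the reference against which the samplers are
validated on small problems.

``benchmark`` reproduces the average-PIP-MSE comparison design: each
candidate sampler's PIP estimates are scored against a gold standard (an
enumeration or a much longer reference run) by the mean over covariates of
the squared error, and relative efficiency is the ratio of a baseline's
average MSE to the candidate's.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .model_core import Dataset, ModelIndicator, PriorSpec, log_model_prior

__all__ = ["enumerate_posterior", "benchmark", "average_pip_mse"]


def enumerate_posterior(data: Dataset, prior: PriorSpec, engine,
                        p_max: int = 15):
    """Evaluate log p-hat(y|gamma) + log p(gamma) for all 2^p models.

    ``engine`` is an engine instance or a name.  Returns a dict with keys
    ``gammas`` (list of tuples), ``log_post`` (unnormalised), ``pmp``
    (normalised probabilities) and ``pip``.
    """
    from .marglik import make_engine

    p = data.p
    if p > p_max:
        raise ValueError(f"p={p} exceeds p_max={p_max} for enumeration")
    if isinstance(engine, str):
        engine = make_engine(engine, data, prior)
    gammas = []
    log_post = np.empty(2 ** p)
    for i, bits in enumerate(itertools.product((0, 1), repeat=p)):
        gam = ModelIndicator(np.array(bits, dtype=np.int8))
        log_post[i] = engine.log_score(gam)
        gammas.append(bits)
    pmp = np.exp(log_post - logsumexp(log_post))
    pmp /= pmp.sum()
    G = np.array(gammas, dtype=float)
    pip = G.T @ pmp
    return {"gammas": gammas, "log_post": log_post, "pmp": pmp, "pip": pip}


def average_pip_mse(pip_est: np.ndarray, pip_gold: np.ndarray) -> float:
    """Mean over covariates of the squared PIP estimation error."""
    pip_est = np.asarray(pip_est, dtype=float)
    pip_gold = np.asarray(pip_gold, dtype=float)
    return float(np.mean((pip_est - pip_gold) ** 2))


def benchmark(run_fns: dict, gold_pips: np.ndarray, baseline: Optional[str] = None):
    """Run each candidate sampler (callables returning a ChainOutput) and
    score its PIPs against the gold standard.

    Returns a dict per candidate with ``average_mse``, ``runtime_s`` and
    ``relative_efficiency`` (baseline MSE / candidate MSE, when a baseline
    name is given).
    """
    report = {}
    for name, fn in run_fns.items():
        t0 = time.perf_counter()
        out = fn()
        dt = time.perf_counter() - t0
        report[name] = {
            "average_mse": average_pip_mse(out.pip_estimate, gold_pips),
            "runtime_s": dt,
            "acceptance_rate": out.acceptance_rate,
        }
    if baseline is not None and baseline in report:
        base = report[baseline]["average_mse"]
        for name in report:
            mse = report[name]["average_mse"]
            report[name]["relative_efficiency"] = base / mse if mse > 0 else np.inf
    return report
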
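"""Exact Polya-gamma PG(1, z) sampling.

PG(1, z) draws are obtained as J*(1, z/2) / 4, where J* is sampled by the
alternating-series rejection sampler of Polson, Scott & Windle (2013): the
proposal mixes a truncated inverse-Gaussian head on (0, t] with an
exponential tail on (t, inf), t = 0.64, and acceptance is decided by the
partial sums of the alternating series for the J* density.  The sampler is
exact (no truncation error) and compiled with numba; it accepts a
``numpy.random.Generator`` so all randomness is reproducible.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["pg1_draw", "pg_draw", "pg_mean"]

_TRUNC = 0.64
_HALF_PI2 = 0.5 * math.pi * math.pi


@njit(cache=True)
def _pnorm(x):
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@njit(cache=True)
def _a_coef(n, x):
    # n-th term of the alternating series for the J*(1,0) density at x
    K = (n + 0.5) * math.pi
    if x > _TRUNC:
        return K * math.exp(-0.5 * K * K * x)
    expnt = -1.5 * (math.log(0.5 * math.pi) + math.log(x)) + math.log(K) \
        - 2.0 * (n + 0.5) * (n + 0.5) / x
    return math.exp(expnt)


@njit(cache=True)
def _mass_texpon(z):
    # probability that the proposal draws from the exponential tail
    t = _TRUNC
    fz = 0.125 * math.pi * math.pi + 0.5 * z * z
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    xb = x0 - z + math.log(_pnorm(b))
    xa = x0 + z + math.log(_pnorm(a))
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(z, rng):
    # inverse-Gaussian IG(mu=1/z, lambda=1) truncated to (0, TRUNC]
    t = _TRUNC
    x = t + 1.0
    if z < 1.0 / t:  # mu > t: rejection with a scaled inverse-chi-square head
        alpha = 0.0
        while rng.random() > alpha:
            e1 = rng.standard_exponential()
            e2 = rng.standard_exponential()
            while e1 * e1 > 2.0 * e2 / t:
                e1 = rng.standard_exponential()
                e2 = rng.standard_exponential()
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            alpha = math.exp(-0.5 * z * z * x)
    else:
        mu = 1.0 / z
        while x > t:
            y = rng.standard_normal()
            y = y * y
            half_mu = 0.5 * mu
            mu_y = mu * y
            x = mu + half_mu * mu_y - half_mu * math.sqrt(4.0 * mu_y + mu_y * mu_y)
            if rng.random() > mu / (mu + x):
                x = mu * mu / x
    return x


@njit(cache=True)
def _sample_jstar(z, rng):
    fz = 0.125 * math.pi * math.pi + 0.5 * z * z
    while True:
        if rng.random() < _mass_texpon(z):
            x = _TRUNC + rng.standard_exponential() / fz
        else:
            x = _rtigauss(z, rng)
        s = _a_coef(0, x)
        y = rng.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return x
            else:
                s += _a_coef(n, x)
                if y > s:
                    break  # reject, retry with a fresh proposal


@njit(cache=True)
def _pg1_vec(zs, rng):
    out = np.empty(zs.shape[0])
    for i in range(zs.shape[0]):
        out[i] = 0.25 * _sample_jstar(0.5 * abs(zs[i]), rng)
    return out


def pg1_draw(z, rng: np.random.Generator) -> np.ndarray:
    """Vector of independent PG(1, z_i) draws."""
    zs = np.atleast_1d(np.asarray(z, dtype=float))
    return _pg1_vec(zs, rng)


def pg_draw(b: int, z: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """PG(b, z) draws for positive integer b (sum of b PG(1, z) variates)."""
    if b < 1 or b != int(b):
        raise ValueError("b must be a positive integer")
    zs = np.full(size * int(b), float(z))
    return _pg1_vec(zs, rng).reshape(size, int(b)).sum(axis=1)


def pg_mean(b: float, z: float) -> float:
    """E[PG(b, z)] = b/(2z) tanh(z/2), with the z -> 0 limit b/4."""
    if z == 0.0:
        return b / 4.0
    return b / (2.0 * z) * math.tanh(z / 2.0)
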
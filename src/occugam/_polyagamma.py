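"""Exact Polya-Gamma PG(1, z) sampling for logistic data augmentation.

A Bernoulli likelihood with logit-linear predictor psi becomes conditionally
Gaussian after augmenting each observation with omega ~ PG(1, psi), which is
what makes the spline, climate-coefficient and detection blocks of the Gibbs
sampler conjugate.  PG(1, z) equals J*(1, z/2)/4 where J* is the exponentially
tilted Jacobi distribution; we draw J* with Devroye's alternating-series
rejection sampler (the same algorithm used by the reference BayesLogit
implementation), which is exact.

Functions are numba-jitted; numba's internal PRNG state is used and must be
seeded through :func:`seed_pg` for reproducibility.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_TRUNC = 0.64  # series truncation point separating the two proposal pieces


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True)
def _pigauss(x, z):
    """CDF at x of an inverse-Gaussian(mu=1/z, lambda=1); valid at z = 0."""
    rx = 1.0 / math.sqrt(x)
    b = rx * (x * z - 1.0)
    a = -rx * (x * z + 1.0)
    return _norm_cdf(b) + math.exp(2.0 * z) * _norm_cdf(a)


@njit(cache=True)
def _a_coef(n, x):
    """n-th coefficient of Devroye's alternating series at x."""
    k = (n + 0.5) * math.pi
    if x > _TRUNC:
        return k * math.exp(-0.5 * k * k * x)
    # small-x branch of the Jacobi density series
    return math.exp(-1.5 * (math.log(0.5 * math.pi) + math.log(x))
                    + math.log(k) - 2.0 * (n + 0.5) ** 2 / x)


@njit(cache=True)
def _rtigauss(z):
    """Inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, _TRUNC)."""
    t = _TRUNC
    x = t + 1.0
    if z * t < 1.0:
        # mu > t (including z = 0): rejection from the one-sided stable proposal
        alpha = 0.0
        while np.random.random() > alpha:
            e1 = np.random.exponential()
            e2 = np.random.exponential()
            while e1 * e1 > 2.0 * e2 / t:
                e1 = np.random.exponential()
                e2 = np.random.exponential()
            x = t / ((1.0 + t * e1) ** 2)
            alpha = math.exp(-0.5 * z * z * x)
    else:
        mu = 1.0 / z
        while x > t:
            y = np.random.normal() ** 2
            muy = mu * y
            x = mu + 0.5 * mu * muy - 0.5 * mu * math.sqrt(4.0 * muy + muy * muy)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
    return x


@njit(cache=True)
def _pg1_draw(zin):
    """One draw from PG(1, zin)."""
    z = abs(zin) * 0.5
    t = _TRUNC
    fz = math.pi * math.pi / 8.0 + z * z / 2.0
    p = (0.5 * math.pi / fz) * math.exp(-fz * t)
    q = 2.0 * math.exp(-z) * _pigauss(t, z)
    while True:
        if np.random.random() < p / (p + q):
            x = t + np.random.exponential() / fz
        else:
            x = _rtigauss(z)
        # squeeze via the alternating series
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        accept = False
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    accept = True
                    break
            else:
                s += _a_coef(n, x)
                if y > s:
                    break
        if accept:
            return x / 4.0


@njit(cache=True)
def pg_draw_array(z):
    """Independent PG(1, z_i) draws for a 1-D array z."""
    out = np.empty(z.size)
    for i in range(z.size):
        out[i] = _pg1_draw(z[i])
    return out


@njit(cache=True)
def seed_pg(seed):
    """Seed numba's internal PRNG used by the PG draws."""
    np.random.seed(seed)


def pg_mean(z: np.ndarray) -> np.ndarray:
    """E[PG(1, z)] = tanh(z/2) / (2 z), with the z -> 0 limit 1/4."""
    z = np.asarray(z, dtype=float)
    out = np.full(z.shape, 0.25)
    nz = np.abs(z) > 1e-8
    out[nz] = np.tanh(z[nz] / 2.0) / (2.0 * z[nz])
    return out
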
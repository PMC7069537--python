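"""Exact Polya-Gamma PG(1, z) sampling.

The logistic likelihood admits conditionally Gaussian Gibbs updates once a
latent omega_i ~ PG(1, eta_i) is introduced for every observation. The
sampler here is the exact alternating-series accept/reject scheme of the
Devroye type: draw a proposal from the truncated-exponential /
truncated-inverse-Gaussian mixture for the tilted Jacobi J*(1, z/2) density,
then accept by evaluating partial sums of the alternating series; a PG(1, z)
variate is J*(1, z/2) / 4.

Moments used in tests: E[PG(1, z)] = tanh(z/2) / (2 z), so E[PG(1, 0)] = 1/4.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["sample_polya_gamma"]

_TRUNC = 0.64  # series crossover point t


@njit(cache=True)
def _log_phi(x):
    # log of the standard normal CDF, stable in the deep left tail
    if x > -8.0:
        return math.log(0.5 * math.erfc(-x / math.sqrt(2.0)))
    xx = x * x
    return (
        -0.5 * xx
        - math.log(-x)
        - 0.5 * math.log(2.0 * math.pi)
        + math.log1p(-1.0 / xx + 3.0 / (xx * xx))
    )


@njit(cache=True)
def _a_coef(n, x, t):
    # n-th term of the alternating series for the Jacobi density at x
    np5 = n + 0.5
    if x <= t:
        return (
            math.pi * np5 * (2.0 / (math.pi * x)) ** 1.5 * math.exp(-2.0 * np5 * np5 / x)
        )
    return math.pi * np5 * math.exp(-np5 * np5 * math.pi * math.pi * x / 2.0)


@njit(cache=True)
def _rtigauss(z, t, rng):
    # inverse-Gaussian(mu=1/z, shape=1) truncated to (0, t]
    if z < 1.0 / t:
        # mu > t: rejection from truncated chi-square proposal
        while True:
            while True:
                e1 = rng.exponential(1.0)
                e2 = rng.exponential(1.0)
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            if rng.random() <= math.exp(-0.5 * z * z * x):
                return x
    else:
        mu = 1.0 / z
        while True:
            y = rng.standard_normal()
            y = y * y
            x = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(4.0 * mu * y + mu * mu * y * y)
            if rng.random() > mu / (mu + x):
                x = mu * mu / x
            if x <= t:
                return x


@njit(cache=True)
def _pg1(zin, rng):
    z = 0.5 * abs(zin)
    t = _TRUNC
    fz = math.pi * math.pi / 8.0 + 0.5 * z * z
    # mixture weight of the truncated-exponential component
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    xb = x0 - z + _log_phi(b)
    xa = x0 + z + _log_phi(a)
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    w_exp = 1.0 / (1.0 + qdivp)
    while True:
        if rng.random() < w_exp:
            x = t + rng.exponential(1.0) / fz
        else:
            x = _rtigauss(z, t, rng)
        # alternating-series accept/reject (guaranteed to terminate)
        s = _a_coef(0, x, t)
        y = rng.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x, t)
                if y <= s:
                    return 0.25 * x
            else:
                s += _a_coef(n, x, t)
                if y > s:
                    break


@njit(cache=True)
def _pg1_fill(tilt, rng, out):
    for i in range(tilt.shape[0]):
        out[i] = _pg1(tilt[i], rng)


def sample_polya_gamma(tilt: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw independent omega_i ~ PG(1, tilt_i).

    Parameters
    ----------
    tilt
        Vector of tilting parameters (linear predictors); must be finite.
    rng
        numpy Generator; draws are a deterministic function of its state.
    """
    tilt = np.ascontiguousarray(tilt, dtype=np.float64)
    if tilt.ndim != 1:
        raise ValueError("tilt must be a 1-d vector")
    if not np.all(np.isfinite(tilt)):
        raise ValueError("tilt values must be finite")
    out = np.empty_like(tilt)
    _pg1_fill(tilt, rng, out)
    return out
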
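"""Standalone random-walk Metropolis sampler for the un-augmented posterior.

Targets exactly the Bayesian Lasso logistic hierarchy on a small dataset,
but WITHOUT Polya-Gamma augmentation: the (intercept, beta) block moves by a
Gaussian random walk accepted against the exact logistic likelihood times
the conditional normal prior, while tau^2 and lambda^2 use their conjugate
conditionals with a locally implemented inverse-Gaussian transform sampler
(Michael-Schucany-Haas). Shares no sampling code with the package.
"""

import math

import numpy as np


def _inverse_gaussian(mu, shape, rng):
    nu = rng.standard_normal() ** 2
    x = mu + mu * mu * nu / (2.0 * shape) - (mu / (2.0 * shape)) * math.sqrt(
        4.0 * mu * shape * nu + mu * mu * nu * nu
    )
    if rng.random() <= mu / (mu + x):
        return x
    return mu * mu / x


def _log_post_coef(b0, beta, x, y, tau2):
    eta = b0 + beta * x
    loglik = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return (
        loglik
        - 0.5 * b0 * b0 / 100.0
        - 0.5 * beta * beta / tau2
        - 0.5 * math.log(tau2)
    )


def mh_chain(x, y, r=10.0, delta=10.0, n_iter=80_000, burnin=10_000, seed=0,
             step=0.6):
    """Posterior draws of (b0, beta) for the 1-covariate hierarchy."""
    rng = np.random.default_rng(seed)
    b0, beta, tau2, lam2 = 0.0, 0.0, 1.0, r / delta
    kept_b0 = np.empty(n_iter - burnin)
    kept_beta = np.empty(n_iter - burnin)
    logp = _log_post_coef(b0, beta, x, y, tau2)
    for it in range(n_iter):
        prop_b0 = b0 + step * rng.standard_normal()
        prop_beta = beta + step * rng.standard_normal()
        prop_logp = _log_post_coef(prop_b0, prop_beta, x, y, tau2)
        if math.log(rng.random()) < prop_logp - logp:
            b0, beta, logp = prop_b0, prop_beta, prop_logp
        b2 = max(beta * beta, 1e-12)
        inv_tau2 = _inverse_gaussian(math.sqrt(lam2 / b2), lam2, rng)
        tau2 = 1.0 / inv_tau2
        lam2 = rng.gamma(r + 1.0, 1.0 / (delta + 0.5 * tau2))
        logp = _log_post_coef(b0, beta, x, y, tau2)  # tau2 changed
        if it >= burnin:
            kept_b0[it - burnin] = b0
            kept_beta[it - burnin] = beta
    return kept_b0, kept_beta


def batch_means_se(draws, n_batches=50):
    """Monte-Carlo standard error of the chain mean via batch means."""
    draws = np.asarray(draws)
    m = len(draws) // n_batches
    means = draws[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return float(means.std(ddof=1) / math.sqrt(n_batches))
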
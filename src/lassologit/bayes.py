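"""Bayesian Lasso logistic regression via Polya-Gamma Gibbs sampling.

Model (per-observation binary outcome y_i, linear predictor eta_i = b0 + x_i.beta):

    y_i ~ Bernoulli(p_i),  p_i = exp(eta_i) / (1 + exp(eta_i))
    beta_j | tau2_j ~ N(0, tau2_j)                    (independent across j)
    tau2_j | lambda2 ~ Exponential(rate = lambda2/2)  (Laplace scale mixture)
    lambda2 ~ Gamma(shape=r, rate=delta)              (default r = delta = 10)
    b0 ~ N(0, 100)                                    (vague, unpenalized)

This is the Park–Casella Bayesian Lasso hierarchy carried over to the
logistic likelihood. Polya-Gamma augmentation (omega_i ~ PG(1, eta_i))
renders every full conditional a named distribution:

    (b0, beta) | omega  ~  N(A^-1 Z^T kappa, A^-1),
        Z = [1 X], kappa = y - 1/2, A = Z^T diag(omega) Z + diag(1/100, 1/tau2)
    1/tau2_j            ~  Inverse-Gaussian(mean=sqrt(lambda2/beta_j^2), shape=lambda2)
    lambda2             ~  Gamma(r + p, delta + sum_j tau2_j / 2)

Variable selection follows the credible-interval rule: a coefficient whose
equal-tailed 95% interval contains zero is reported as exactly zero,
otherwise as its posterior median.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import expit

from ._polyagamma import sample_polya_gamma

__all__ = [
    "PriorSpec",
    "ChainConfig",
    "GibbsState",
    "PosteriorDraws",
    "PosteriorSummary",
    "gibbs_sweep",
    "run_gibbs",
    "summarize_posterior",
    "potential_scale_reduction",
]

_BETA2_FLOOR = 1e-12  # inverse-Gaussian mean undefined at beta_j = 0


@dataclass(frozen=True)
class PriorSpec:
    """Gamma(r, delta) hyperprior on the squared tuning parameter lambda^2."""

    r: float = 10.0
    delta: float = 10.0

    def __post_init__(self):
        if self.r <= 0 or self.delta <= 0:
            raise ValueError("r and delta must be positive")


@dataclass(frozen=True)
class ChainConfig:
    n_iterations: int = 12_000
    n_burnin: int = 2_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.n_burnin < self.n_iterations:
            raise ValueError("need 0 <= n_burnin < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thin


@dataclass
class GibbsState:
    intercept: float
    beta: np.ndarray
    tau2: np.ndarray
    lambda2: float


@dataclass
class PosteriorDraws:
    """Kept Gibbs draws; coefficient draws are on the scale of the X passed in."""

    beta_draws: np.ndarray
    intercept_draws: np.ndarray
    tau2_draws: np.ndarray
    lambda2_draws: np.ndarray
    config: ChainConfig
    prior: PriorSpec
    column_names: list[str] | None = None
    rhat: np.ndarray | None = None  # split-chain PSRF per coefficient (reported)


@dataclass
class PosteriorSummary:
    median: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    selected: np.ndarray
    point_estimate: np.ndarray
    intercept: float
    level: float = 0.95


def _draw_lambda2(rng: np.random.Generator, prior: PriorSpec, tau2: np.ndarray) -> float:
    """Conjugate Gamma(r + p, delta + sum tau2 / 2) update of lambda^2."""
    shape = prior.r + tau2.shape[0]
    rate = prior.delta + 0.5 * float(tau2.sum())
    return float(rng.gamma(shape, 1.0 / rate))


def gibbs_sweep(
    state: GibbsState,
    X: np.ndarray,
    y: np.ndarray,
    prior: PriorSpec,
    rng: np.random.Generator,
    *,
    intercept_variance: float = 100.0,
    fixed_lambda2: float | None = None,
) -> GibbsState:
    """One full-conditional cycle; returns a new state.

    With ``n = 0`` the likelihood steps are skipped and the sweep samples the
    prior hierarchy (useful as a prior-recovery check). ``fixed_lambda2``
    disables the hyperprior update and holds lambda^2 at the given value.
    """
    n, p = X.shape
    beta = state.beta
    if n > 0:
        eta = state.intercept + X @ beta
        omega = sample_polya_gamma(eta, rng)
        Z = np.empty((n, p + 1))
        Z[:, 0] = 1.0
        Z[:, 1:] = X
        A = (Z * omega[:, None]).T @ Z
        prior_prec = np.empty(p + 1)
        prior_prec[0] = 1.0 / intercept_variance
        prior_prec[1:] = 1.0 / state.tau2
        A[np.diag_indices_from(A)] += prior_prec
        b = Z.T @ (y - 0.5)
        for attempt in range(2):
            try:
                L = np.linalg.cholesky(A)
                break
            except np.linalg.LinAlgError:
                if attempt == 1:
                    raise
                A[np.diag_indices_from(A)] += 1e-8 * np.trace(A) / (p + 1)
        mean = solve_triangular(
            L.T,
            solve_triangular(L, b, lower=True, check_finite=False),
            lower=False,
            check_finite=False,
        )
        # theta = mean + L^-T xi with A = L L^T
        xi = rng.standard_normal(p + 1)
        theta = mean + solve_triangular(L, xi, lower=True, trans="T", check_finite=False)
        intercept = float(theta[0])
        beta = theta[1:]
    else:
        intercept = float(rng.normal(0.0, np.sqrt(intercept_variance)))
        beta = rng.normal(0.0, np.sqrt(state.tau2))

    lambda2 = state.lambda2 if fixed_lambda2 is None else float(fixed_lambda2)
    beta2 = np.maximum(beta * beta, _BETA2_FLOOR)
    ig_mean = np.sqrt(lambda2 / beta2)
    inv_tau2 = rng.wald(ig_mean, lambda2)
    tau2 = 1.0 / inv_tau2
    if fixed_lambda2 is None:
        lambda2 = _draw_lambda2(rng, prior, tau2)
    if not (
        np.isfinite(intercept)
        and np.all(np.isfinite(beta))
        and np.all(np.isfinite(tau2))
        and np.isfinite(lambda2)
    ):
        raise FloatingPointError("non-finite draw in Gibbs sweep")
    return GibbsState(intercept=intercept, beta=beta, tau2=tau2, lambda2=lambda2)


def run_gibbs(
    X: np.ndarray,
    y: np.ndarray,
    prior: PriorSpec = PriorSpec(),
    config: ChainConfig = ChainConfig(),
    *,
    standardize: bool = True,
    intercept_variance: float = 100.0,
    fixed_lambda2: float | None = None,
    column_names: list[str] | None = None,
) -> PosteriorDraws:
    """Run the Gibbs sampler and return kept draws.

    Columns are standardized internally (so the common prior scale is fair
    across covariates) and coefficient draws are mapped back to the input
    scale; tau2/lambda2 draws refer to the standardized scale. The chain is
    a deterministic function of ``config.seed``. Initialization: beta = 0,
    tau2 = 1, lambda2 = r / delta.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if standardize and n > 0:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd > 0.0, sd, 1.0)
        Xs = (X - mu) / sd
    else:
        mu, sd = np.zeros(p), np.ones(p)
        Xs = X
    rng = np.random.default_rng(config.seed)
    state = GibbsState(
        intercept=0.0,
        beta=np.zeros(p),
        tau2=np.ones(p),
        lambda2=prior.r / prior.delta if fixed_lambda2 is None else float(fixed_lambda2),
    )
    n_kept = config.n_kept
    beta_draws = np.empty((n_kept, p))
    intercept_draws = np.empty(n_kept)
    tau2_draws = np.empty((n_kept, p))
    lambda2_draws = np.empty(n_kept)
    k = 0
    for sweep in range(config.n_iterations):
        try:
            state = gibbs_sweep(
                state,
                Xs,
                y,
                prior,
                rng,
                intercept_variance=intercept_variance,
                fixed_lambda2=fixed_lambda2,
            )
        except FloatingPointError as exc:
            raise FloatingPointError(f"chain failure at sweep {sweep}: {exc}") from exc
        idx = sweep - config.n_burnin
        if idx >= 0 and idx % config.thin == 0 and k < n_kept:
            # back-transform to the input scale
            beta_draws[k] = state.beta / sd
            intercept_draws[k] = state.intercept - float(np.sum(state.beta * mu / sd))
            tau2_draws[k] = state.tau2
            lambda2_draws[k] = state.lambda2
            k += 1
    draws = PosteriorDraws(
        beta_draws=beta_draws,
        intercept_draws=intercept_draws,
        tau2_draws=tau2_draws,
        lambda2_draws=lambda2_draws,
        config=config,
        prior=prior,
        column_names=column_names,
    )
    draws.rhat = potential_scale_reduction(beta_draws)
    return draws


def potential_scale_reduction(draws: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor (PSRF) per column.

    The kept chain is split in half; values near 1 indicate the two halves
    agree in mean and variance. Reported as a diagnostic, not enforced.
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.ndim == 1:
        draws = draws[:, None]
    m = draws.shape[0] // 2
    a, b = draws[:m], draws[m : 2 * m]
    W = 0.5 * (a.var(axis=0, ddof=1) + b.var(axis=0, ddof=1))
    b_over_m = 0.5 * (a.mean(axis=0) - b.mean(axis=0)) ** 2
    var_plus = (m - 1) / m * W + b_over_m
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    return rhat


def summarize_posterior(draws: PosteriorDraws, level: float = 0.95) -> PosteriorSummary:
    """Equal-tailed credible intervals, medians, and the zero-or-median rule.

    ``selected[j]`` is True when the interval excludes zero;
    ``point_estimate[j]`` is the median when selected and exactly 0 otherwise.
    """
    if draws.beta_draws.shape[0] < 100:
        raise ValueError("need at least 100 kept draws to summarize")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    alpha = (1.0 - level) / 2.0
    med = np.median(draws.beta_draws, axis=0)
    lo = np.quantile(draws.beta_draws, alpha, axis=0)
    hi = np.quantile(draws.beta_draws, 1.0 - alpha, axis=0)
    selected = (lo > 0.0) | (hi < 0.0)
    point = np.where(selected, med, 0.0)
    return PosteriorSummary(
        median=med,
        ci_low=lo,
        ci_high=hi,
        selected=selected,
        point_estimate=point,
        intercept=float(np.median(draws.intercept_draws)),
        level=level,
    )
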
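"""Gibbs sampler for the Bayesian Lasso logistic hierarchy."""

import numpy as np
import pytest
from scipy.special import expit

from lassologit.bayes import (
    ChainConfig,
    GibbsState,
    PosteriorDraws,
    PriorSpec,
    _draw_lambda2,
    gibbs_sweep,
    run_gibbs,
    summarize_posterior,
)


def test_prior_spec_validation():
    with pytest.raises(ValueError):
        PriorSpec(r=0.0)
    with pytest.raises(ValueError):
        ChainConfig(n_iterations=100, n_burnin=100)


def test_lambda2_conditional_is_conjugate_gamma():
    """With p=8 and sum(tau2)/2 = 3 the update is Gamma(18, 13)."""
    rng = np.random.default_rng(0)
    tau2 = np.full(8, 6.0 / 8.0)
    draws = np.array([_draw_lambda2(rng, PriorSpec(), tau2) for _ in range(200_000)])
    mean, var = 18.0 / 13.0, 18.0 / 13.0**2
    assert draws.mean() == pytest.approx(mean, abs=4 * np.sqrt(var / 2e5) + 1e-3)
    assert draws.var() == pytest.approx(var, rel=0.03)


def test_no_data_chain_recovers_lambda2_prior():
    """With n = 0 the Gibbs chain samples the Gamma(10, 10) prior of lambda^2."""
    config = ChainConfig(n_iterations=25_000, n_burnin=1_000, seed=11)
    draws = run_gibbs(np.empty((0, 2)), np.empty(0), config=config)
    assert draws.lambda2_draws.mean() == pytest.approx(1.0, abs=0.05)
    assert draws.lambda2_draws.var() == pytest.approx(0.1, abs=0.03)
    assert np.median(draws.beta_draws) == pytest.approx(0.0, abs=0.02)


def test_sweep_guard_at_zero_beta():
    """The tau2 update stays finite when beta_j is exactly zero."""
    rng = np.random.default_rng(1)
    state = GibbsState(intercept=0.0, beta=np.zeros(3), tau2=np.ones(3), lambda2=1.0)
    out = gibbs_sweep(state, np.empty((0, 3)), np.empty(0), PriorSpec(), rng)
    assert np.all(np.isfinite(out.tau2)) and np.all(out.tau2 > 0)


def test_chain_deterministic(toy_logistic):
    X, y, _ = toy_logistic
    config = ChainConfig(n_iterations=400, n_burnin=100, seed=9)
    a = run_gibbs(X[:80], y[:80], config=config)
    b = run_gibbs(X[:80], y[:80], config=config)
    assert np.array_equal(a.beta_draws, b.beta_draws)
    assert np.array_equal(a.lambda2_draws, b.lambda2_draws)


def test_posterior_concentrates_on_true_support(toy_logistic):
    X, y, truth = toy_logistic
    draws = run_gibbs(X, y, config=ChainConfig(n_iterations=4_000, n_burnin=1_000, seed=2))
    s = summarize_posterior(draws)
    assert set(np.flatnonzero(s.selected)) >= {0, 1}
    assert np.sign(s.median[0]) == np.sign(truth[0])
    assert np.max(draws.rhat) < 1.05


def test_null_data_intervals_cover_zero():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((500, 8))
    y = (rng.random(500) < 0.5).astype(float)
    draws = run_gibbs(X, y, config=ChainConfig(n_iterations=4_000, n_burnin=1_000, seed=5))
    s = summarize_posterior(draws)
    assert (~s.selected).sum() >= 7


def test_shrinkage_monotone_in_fixed_lambda2(toy_logistic):
    """Larger fixed lambda^2 shrinks every posterior median toward zero."""
    X, y, _ = toy_logistic
    X, y = X[:120], y[:120]
    mags = []
    for lam2 in (0.1, 25.0, 2_500.0):
        draws = run_gibbs(
            X, y, config=ChainConfig(n_iterations=4_000, n_burnin=1_000, seed=3),
            fixed_lambda2=lam2,
        )
        mags.append(np.abs(summarize_posterior(draws).median))
    mc_slack = 0.05
    assert np.all(mags[1] <= mags[0] + mc_slack)
    assert np.all(mags[2] <= mags[1] + mc_slack)
    assert mags[2].max() < mags[0].max()


def _fake_draws(beta_draws):
    k = beta_draws.shape[0]
    return PosteriorDraws(
        beta_draws=beta_draws,
        intercept_draws=np.zeros(k),
        tau2_draws=np.ones_like(beta_draws),
        lambda2_draws=np.ones(k),
        config=ChainConfig(n_iterations=k, n_burnin=0, seed=0),
        prior=PriorSpec(),
    )


def test_summary_degenerate_chain_selected():
    draws = _fake_draws(np.full((200, 1), 1.7))
    s = summarize_posterior(draws)
    assert s.selected[0]
    assert s.median[0] == s.ci_low[0] == s.ci_high[0] == 1.7
    assert s.point_estimate[0] == 1.7


def test_summary_symmetric_chain_zeroed():
    rng = np.random.default_rng(0)
    sym = rng.standard_normal((1_000, 1))
    s = summarize_posterior(_fake_draws(sym))
    assert not s.selected[0]
    assert s.point_estimate[0] == 0.0


def test_summary_sparsity_rule_and_ordering():
    rng = np.random.default_rng(4)
    draws = _fake_draws(rng.standard_normal((500, 6)) + np.array([0, 3, -3, 0.1, 0, 5.0]))
    s = summarize_posterior(draws)
    assert np.all(s.ci_low <= s.median) and np.all(s.median <= s.ci_high)
    covered = (s.ci_low <= 0) & (0 <= s.ci_high)
    assert np.all(s.point_estimate[covered] == 0.0)
    assert np.all(s.point_estimate[~covered] == s.median[~covered])


def test_summary_needs_enough_draws():
    with pytest.raises(ValueError):
        summarize_posterior(_fake_draws(np.zeros((50, 2))))


def test_posterior_odds_ratio_reporting():
    """exp of a selected median reproduces the OR scale (e.g. -1.4 -> 0.25)."""
    from lassologit.metrics import odds_ratio_report

    orr, (lo, hi) = odds_ratio_report(-1.4, -2.5, -0.16)
    assert orr == pytest.approx(0.25, abs=0.005)
    assert lo < orr < hi
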
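"""Coordinate-descent L1 logistic solver and cross-validated tuning."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from lassologit.lasso import (
    LassoFit,
    binomial_deviance,
    cv_select_lambda,
    fit_lasso,
    kkt_violation,
    lambda_path,
    predict_prob,
    soft_threshold,
)
from lassologit.simulate import scenario1_spec, simulate_scenario


@pytest.mark.parametrize(
    "z,gamma,expected", [(3.0, 1.0, 2.0), (-0.5, 1.0, 0.0), (-4.0, 1.5, -2.5), (2.2, 0.0, 2.2)]
)
def test_soft_threshold_examples(z, gamma, expected):
    assert soft_threshold(z, gamma) == pytest.approx(expected)


@settings(max_examples=50, deadline=None)
@given(z=st.floats(-50, 50), gamma=st.floats(0, 50))
def test_soft_threshold_shrinks_toward_zero(z, gamma):
    out = soft_threshold(z, gamma)
    assert abs(out) == pytest.approx(max(abs(z) - gamma, 0.0))
    assert out * z >= 0.0


def test_unpenalized_fit_matches_mle(toy_logistic):
    """lambda = 0 reproduces the ordinary logistic MLE."""
    X, y, _ = toy_logistic
    fit = fit_lasso(X, y, 0.0)
    mle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    assert np.max(np.abs(np.r_[fit.intercept, fit.beta] - mle.params)) < 1e-6


def test_lambda_max_gives_null_model(toy_logistic):
    X, y, _ = toy_logistic
    grid = lambda_path(X, y)
    fit = fit_lasso(X, y, grid[0])
    assert fit.active_set.size == 0
    assert fit.intercept == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-8)
    assert kkt_violation(fit, X, y) < 1e-6


def test_lambda_path_endpoints_and_errors(toy_logistic):
    X, y, _ = toy_logistic
    grid = lambda_path(X, y, n_lambda=2, ratio=0.01)
    assert len(grid) == 2
    assert grid[1] == pytest.approx(0.01 * grid[0])
    with pytest.raises(ValueError):
        lambda_path(X, np.ones_like(y))
    with pytest.raises(ValueError):
        lambda_path(X, y, ratio=1.5)


@pytest.mark.parametrize("grid_index", [10, 40, 70])
def test_kkt_certificate_along_path(toy_logistic, grid_index):
    """Subgradient optimality holds at every converged solution."""
    X, y, _ = toy_logistic
    lam = lambda_path(X, y)[grid_index]
    fit = fit_lasso(X, y, lam)
    assert fit.converged
    assert kkt_violation(fit, X, y) < 1e-5


def test_agreement_with_saga_oracle(toy_logistic):
    """Independent solver (sklearn saga, same objective) agrees to ~1e-6."""
    X, y, _ = toy_logistic
    n = len(y)
    for lam in lambda_path(X, y)[[25, 45]]:
        ours = fit_lasso(X, y, lam, standardize=False)
        oracle = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (n * lam), solver="saga", tol=1e-12, max_iter=500_000
        ).fit(X, y)
        assert np.max(np.abs(ours.beta - oracle.coef_[0])) < 1e-5
        assert abs(ours.intercept - oracle.intercept_[0]) < 1e-5


def _brute_force_1d(X, y, lam):
    """Dense grid search over (b0, beta) for p = 1."""
    b0s = np.linspace(-2, 2, 401)
    betas = np.linspace(-3, 3, 1201)
    B0, B = np.meshgrid(b0s, betas, indexing="ij")
    eta = B0[..., None] + B[..., None] * X[:, 0]
    nll = np.mean(np.logaddexp(0, eta) - y * eta, axis=-1) + lam * np.abs(B)
    i, j = np.unravel_index(np.argmin(nll), nll.shape)
    return b0s[i], betas[j]


def test_brute_force_grid_oracle_p1():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((25, 1))
    y = (rng.random(25) < expit(0.2 + 1.1 * X[:, 0])).astype(float)
    for lam in (0.02, 0.1):
        fit = fit_lasso(X, y, lam, standardize=False)
        b0, b1 = _brute_force_1d(X, y, lam)
        assert abs(fit.beta[0] - b1) < 1e-2  # grid resolution 5e-3
        assert abs(fit.intercept - b0) < 1e-2


def test_slope_vanishes_for_independent_outcome():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((400, 1))
    y = (rng.random(400) < 0.5).astype(float)
    mags = [abs(fit_lasso(X, y, lam).beta[0]) for lam in (0.001, 0.01, 0.1)]
    assert mags[-1] == 0.0
    assert mags[0] >= mags[-1]


def test_objective_not_above_warm_start(toy_logistic):
    """Path continuity: each solution improves on its warm-start initializer."""
    from lassologit.lasso import _pen_nll, _standardize

    X, y, _ = toy_logistic
    Xs = _standardize(X)[0]
    grid = lambda_path(X, y, n_lambda=20, ratio=0.01)
    warm = None
    for lam in grid:
        fit = fit_lasso(X, y, lam, warm=warm)
        if warm is not None:
            start = _pen_nll(Xs, y, warm[0], np.asarray(warm[1]), lam)
            end = _pen_nll(Xs, y, fit.intercept_std_, fit.beta_std_, lam)
            assert end <= start + 1e-10
        warm = (fit.intercept_std_, fit.beta_std_)


def test_predict_prob_basics(toy_logistic):
    X, y, _ = toy_logistic
    fit = LassoFit(
        intercept=0.0, beta=np.zeros(8), lam=1.0,
        active_set=np.array([], dtype=int), converged=True, n_iterations=0,
    )
    assert np.allclose(predict_prob(fit, X), 0.5)
    fit.intercept = 30.0
    assert predict_prob(fit, X).min() > 0.999
    one = LassoFit(
        intercept=0.0, beta=np.array([1.0]), lam=0.0,
        active_set=np.array([0]), converged=True, n_iterations=0,
    )
    assert predict_prob(one, np.array([[0.97]]))[0] == pytest.approx(0.725, abs=5e-4)
    with pytest.raises(ValueError):
        predict_prob(one, np.zeros((3, 2)))


def test_cv_deterministic(toy_logistic):
    X, y, _ = toy_logistic
    a = cv_select_lambda(X, y, n_folds=10, seed=42)
    b = cv_select_lambda(X, y, n_folds=10, seed=42)
    assert a.lambda_min == b.lambda_min
    assert np.array_equal(a.fold_assignment, b.fold_assignment)
    assert np.all(np.diff(a.lambda_grid) < 0)
    assert a.lambda_min in a.lambda_grid


def test_cv_rejects_tiny_samples(toy_logistic):
    X, y, _ = toy_logistic
    with pytest.raises(ValueError):
        cv_select_lambda(X[:15], y[:15], n_folds=10)


def test_cv_noise_selects_few_variables():
    """On pure-noise data the CV-tuned fit stays near-null most of the time."""
    hits = 0
    n_seeds = 25
    for seed in range(n_seeds):
        rng = np.random.default_rng(1_000 + seed)
        X = rng.standard_normal((150, 8))
        y = (rng.random(150) < 0.5).astype(float)
        cv = cv_select_lambda(X, y, n_folds=10, seed=seed)
        fit = fit_lasso(X, y, cv.lambda_min)
        hits += fit.active_set.size <= 2
    assert hits >= 0.8 * n_seeds


def test_cv_recovers_true_support_large_sample():
    train, _, truth = simulate_scenario(scenario1_spec(2000, 0.2, seed=6))
    cv = cv_select_lambda(train.X, train.y, n_folds=10, seed=1)
    fit = fit_lasso(train.X, train.y, cv.lambda_min)
    assert {0, 1, 4} <= set(fit.active_set)


def test_binomial_deviance_matches_hand_value():
    y = np.array([1.0, 0.0, 1.0])
    p = np.array([0.8, 0.3, 0.6])
    expected = -2.0 * (np.log(0.8) + np.log(0.7) + np.log(0.6)) / 3
    assert binomial_deviance(y, p) == pytest.approx(expected)
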
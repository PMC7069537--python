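"""Repeated train/test model comparison.

Protocol: split the encoded cohort 60/40 into train and test, fit the
CV-tuned Lasso and the Bayesian Lasso on the train part, compute EBIC, AIC,
sensitivity, specificity, accuracy and precision on the test part, record
which variables each model selected, and repeat (default 100 times) with
per-repeat seeds spawned from one master seed. Both models see the same
splits, so the comparison is head-to-head. Averaged indices and per-variable
selection frequencies summarize the repeats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import ChainConfig, PriorSpec, run_gibbs, summarize_posterior
from .cohort import DesignMatrix, split_train_test
from .lasso import cv_select_lambda, fit_lasso, predict_prob
from .metrics import IndexSet, aic, binomial_loglik, confusion_metrics, ebic
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationRecord",
    "RepeatResults",
    "run_repeats",
    "selection_frequency",
    "aggregate_indices",
    "INDEX_COLUMNS",
]

INDEX_COLUMNS = ("ebic", "aic", "sensitivity", "specificity", "accuracy", "precision")


@dataclass
class EvaluationRecord:
    model: str  # "lasso" | "bayes"
    repeat_id: int
    indices: IndexSet
    selected: np.ndarray  # length-p 0/1
    coefficients: np.ndarray  # length-p point estimates (sparse for both models)
    lambda_value: float  # CV-selected lambda (lasso) / posterior mean lambda (bayes)

    def __post_init__(self):
        if self.model not in ("lasso", "bayes"):
            raise ValueError("model must be 'lasso' or 'bayes'")


@dataclass
class RepeatResults:
    per_repeat: list[EvaluationRecord]
    n_repeats: int
    master_seed: int
    column_names: list[str]
    failures: list[tuple[int, str, str]] = field(default_factory=list)


def _score(
    y_test: np.ndarray,
    prob: np.ndarray,
    k_active: int,
    p: int,
    threshold: float,
    ebic_gamma: float,
) -> IndexSet:
    ll = binomial_loglik(prob, y_test)
    sens, spec, acc, prec = confusion_metrics(y_test, prob, threshold)
    return IndexSet(
        ebic=ebic(ll, k_active, n=len(y_test), p=p, gamma=ebic_gamma),
        aic=aic(ll, k_active),
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        precision=prec,
        k_active=k_active,
        loglik=ll,
    )


def _fit_lasso_repeat(train, test, seed, n_folds, threshold, ebic_gamma):
    cv = cv_select_lambda(train.X, train.y, n_folds=n_folds, seed=seed)
    fit = fit_lasso(train.X, train.y, cv.lambda_min)
    prob = predict_prob(fit, test.X)
    selected = (fit.beta != 0.0).astype(int)
    indices = _score(
        test.y, prob, int(selected.sum()), train.p, threshold, ebic_gamma
    )
    return EvaluationRecord(
        model="lasso",
        repeat_id=-1,
        indices=indices,
        selected=selected,
        coefficients=fit.beta.copy(),
        lambda_value=cv.lambda_min,
    )


def _fit_bayes_repeat(train, test, seed, prior, chain, threshold, ebic_gamma):
    config = ChainConfig(
        n_iterations=chain.n_iterations,
        n_burnin=chain.n_burnin,
        thin=chain.thin,
        seed=seed,
    )
    draws = run_gibbs(train.X, train.y, prior=prior, config=config)
    summary = summarize_posterior(draws)
    point = summary.point_estimate
    prob = expit(summary.intercept + test.X @ point)
    selected = summary.selected.astype(int)
    indices = _score(
        test.y, prob, int(selected.sum()), train.p, threshold, ebic_gamma
    )
    return EvaluationRecord(
        model="bayes",
        repeat_id=-1,
        indices=indices,
        selected=selected,
        coefficients=point.copy(),
        lambda_value=float(np.sqrt(draws.lambda2_draws).mean()),
    )


def run_repeats(
    dm: DesignMatrix,
    n_repeats: int = 100,
    master_seed: int = 0,
    *,
    train_fraction: float = 0.6,
    n_folds: int = 10,
    prior: PriorSpec = PriorSpec(),
    chain: ChainConfig = ChainConfig(),
    threshold: float = 0.5,
    ebic_gamma: float = 0.5,
) -> RepeatResults:
    """Run the repeated-split comparison; deterministic in ``master_seed``.

    Per-repeat seeds for the split, the CV folds and the Gibbs chain are
    spawned counter-style from the master seed so each repeat is
    independently re-runnable. Failed repeat/model fits are logged and
    skipped (never resampled), keeping the repeat count honest.
    """
    if dm.n < 30:
        raise ValueError("need at least 30 rows for the repeat protocol")
    records: list[EvaluationRecord] = []
    failures: list[tuple[int, str, str]] = []
    children = np.random.SeedSequence(master_seed).spawn(n_repeats)
    for rep in range(n_repeats):
        split_seed, cv_seed, chain_seed = (
            int(s) % (2**31) for s in children[rep].generate_state(3)
        )
        train, test = split_train_test(dm, train_fraction, split_seed)
        for name, fitter in (
            ("lasso", lambda: _fit_lasso_repeat(train, test, cv_seed, n_folds, threshold, ebic_gamma)),
            ("bayes", lambda: _fit_bayes_repeat(train, test, chain_seed, prior, chain, threshold, ebic_gamma)),
        ):
            try:
                rec = fitter()
            except Exception as exc:  # noqa: BLE001 - repeat-level isolation
                logger.warning("repeat %d %s failed: %s", rep, name, exc)
                failures.append((rep, name, str(exc)))
                continue
            rec.repeat_id = rep
            records.append(rec)
    return RepeatResults(
        per_repeat=records,
        n_repeats=n_repeats,
        master_seed=master_seed,
        column_names=list(dm.column_names),
        failures=failures,
    )


def selection_frequency(results: RepeatResults) -> pd.DataFrame:
    """Per-variable, per-model selection counts, ranked.

    Rank is by descending count, ties broken by mean absolute point
    estimate over the repeats. Also carries each model's mean number of
    selected variables per repeat in ``.attrs['mean_selected']``.
    """
    if not results.per_repeat:
        raise ValueError("no evaluation records")
    rows = []
    mean_selected = {}
    for model in ("lasso", "bayes"):
        recs = [r for r in results.per_repeat if r.model == model]
        if not recs:
            continue
        sel = np.vstack([r.selected for r in recs])
        coefs = np.vstack([np.abs(r.coefficients) for r in recs])
        counts = sel.sum(axis=0)
        mean_abs = coefs.mean(axis=0)
        order = np.lexsort((-mean_abs, -counts))
        ranks = np.empty_like(order)
        ranks[order] = np.arange(1, len(order) + 1)
        mean_selected[model] = float(sel.sum(axis=1).mean())
        for j, name in enumerate(results.column_names):
            rows.append(
                {
                    "model": model,
                    "variable": name,
                    "count": int(counts[j]),
                    "n_repeats": len(recs),
                    "mean_abs_coef": mean_abs[j],
                    "rank": int(ranks[j]),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["mean_selected"] = mean_selected
    return out


def aggregate_indices(results: RepeatResults) -> pd.DataFrame:
    """Per-model mean of each comparison index over successful repeats.

    NaN index values (zero-denominator ratios) are excluded from their
    average with a reported count. Columns: the six indices, mean lambda,
    mean number of active variables, and repeat counts.
    """
    rows = []
    for model in ("lasso", "bayes"):
        recs = [r for r in results.per_repeat if r.model == model]
        if not recs:
            continue
        row: dict[str, object] = {"model": model, "n_success": len(recs)}
        for name in INDEX_COLUMNS:
            vals = np.array([getattr(r.indices, name) for r in recs], dtype=float)
            finite = np.isfinite(vals)
            row[name] = float(vals[finite].mean()) if finite.any() else float("nan")
            row[f"{name}_undefined"] = int((~finite).sum())
        row["mean_lambda"] = float(np.mean([r.lambda_value for r in recs]))
        row["mean_k_active"] = float(np.mean([r.indices.k_active for r in recs]))
        rows.append(row)
    if not rows:
        raise ValueError("zero successful repeats; nothing to aggregate")
    return pd.DataFrame(rows)
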
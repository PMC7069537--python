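"""Model-comparison indices: log-likelihood, AIC, EBIC, confusion metrics, ORs.

Conventions: the positive class is death (y = 1); the intercept counts as one
parameter in AIC/EBIC; ratios with a zero denominator are reported as NaN
(never silently as 0) and excluded from averages upstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "IndexSet",
    "binomial_loglik",
    "aic",
    "ebic",
    "confusion_metrics",
    "odds_ratio_report",
]

_PROB_CLIP = 1e-12


@dataclass
class IndexSet:
    """Per-evaluation goodness-of-fit and classification indices."""

    ebic: float
    aic: float
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    k_active: int
    loglik: float

    def __post_init__(self):
        for name in ("sensitivity", "specificity", "accuracy", "precision"):
            v = getattr(self, name)
            if not (math.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        expected = -2.0 * self.loglik + 2.0 * (self.k_active + 1)
        if not math.isclose(self.aic, expected, rel_tol=0, abs_tol=1e-8):
            raise ValueError("aic inconsistent with loglik and k_active")


def binomial_loglik(prob: np.ndarray, y: np.ndarray) -> float:
    """Bernoulli log-likelihood sum_i [y log p + (1-y) log(1-p)], p clipped."""
    prob = np.asarray(prob, dtype=float)
    y = np.asarray(y, dtype=float)
    if prob.shape != y.shape:
        raise ValueError("prob and y must have the same shape")
    prob = np.clip(prob, _PROB_CLIP, 1.0 - _PROB_CLIP)
    return float(np.sum(y * np.log(prob) + (1.0 - y) * np.log(1.0 - prob)))


def aic(loglik: float, k_active: int) -> float:
    """Akaike information criterion -2 loglik + 2 (k_active + 1)."""
    if k_active < 0:
        raise ValueError("k_active must be non-negative")
    return -2.0 * loglik + 2.0 * (k_active + 1)


def ebic(loglik: float, k_active: int, n: int, p: int, gamma: float = 0.5) -> float:
    """Extended BIC: -2 loglik + (k+1) log n + 2 gamma log C(p, k).

    gamma = 0 reduces to the classical BIC; the model-space term penalizes
    selecting k out of p candidates.
    """
    if not 0 <= k_active <= p:
        raise ValueError("need 0 <= k_active <= p")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    return (
        -2.0 * loglik
        + (k_active + 1) * math.log(n)
        + 2.0 * gamma * math.log(math.comb(p, k_active))
    )


def confusion_metrics(
    y_true: np.ndarray, prob: np.ndarray, threshold: float = 0.5
) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, accuracy, precision) at a probability cut-off.

    Predicted positive iff prob >= threshold. Zero-denominator ratios are NaN.
    """
    y_true = np.asarray(y_true)
    if not np.isin(y_true, [0, 1]).all():
        raise ValueError("y_true must be binary 0/1")
    prob = np.asarray(prob, dtype=float)
    pred = prob >= threshold
    pos = y_true == 1
    tp = int(np.sum(pred & pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    fp = int(np.sum(pred & ~pos))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / len(y_true) if len(y_true) else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    return sens, spec, acc, prec


def odds_ratio_report(
    beta: float, ci_low: float, ci_high: float, ndigits: int | None = 2
) -> tuple[float, tuple[float, float]]:
    """Exponentiate a log-odds coefficient and its CI into an OR report.

    ``ndigits`` applies display rounding (two decimals, the usual reporting
    style); pass None for unrounded values.
    """
    orr, lo, hi = math.exp(beta), math.exp(ci_low), math.exp(ci_high)
    if ndigits is not None:
        orr, lo, hi = round(orr, ndigits), round(lo, ndigits), round(hi, ndigits)
    return orr, (lo, hi)
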
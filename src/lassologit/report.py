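"""Text and CSV rendering of descriptive and comparison results."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import odds_ratio_report

__all__ = [
    "render_table_one",
    "coefficient_report",
    "render_coefficient_report",
    "render_indices",
]


def render_table_one(table: pd.DataFrame) -> str:
    """Human-readable death-stratified frequency table."""
    lines = [
        f"{'Variable':<16}{'Level':<16}{'Total (%)':>14}{'Alive (%)':>14}{'Died (%)':>14}"
    ]
    prev = None
    for _, row in table.iterrows():
        var = row["variable"] if row["variable"] != prev else ""
        prev = row["variable"]
        lines.append(
            f"{var:<16}{row['level']:<16}"
            f"{row['total_n']:>7} ({row['total_pct']:>4.1f})"
            f"{row['alive_n']:>7} ({row['alive_pct']:>4.1f})"
            f"{row['died_n']:>7} ({row['died_pct']:>4.1f})"
        )
    n = table.attrs.get("n_total")
    if n is not None:
        lines.append(
            f"\nN = {n}; died {table.attrs['n_died']} ({table.attrs['died_pct']}%)"
        )
    return "\n".join(lines)


def coefficient_report(
    names: list[str],
    beta: np.ndarray,
    ci_low: np.ndarray | None = None,
    ci_high: np.ndarray | None = None,
) -> pd.DataFrame:
    """Coefficient / OR / CI-of-OR table; rows with beta == 0 are omitted.

    With no intervals (ordinary Lasso point fit) the CI columns are NaN.
    """
    rows = []
    for j, name in enumerate(names):
        b = float(beta[j])
        if b == 0.0:
            continue
        if ci_low is not None and ci_high is not None:
            orr, (lo, hi) = odds_ratio_report(b, float(ci_low[j]), float(ci_high[j]))
        else:
            orr, (lo, hi) = odds_ratio_report(b, 0.0, 0.0)
            lo = hi = float("nan")
        rows.append(
            {"variable": name, "beta": round(b, 2), "OR": orr, "OR_low": lo, "OR_high": hi}
        )
    return pd.DataFrame(rows, columns=["variable", "beta", "OR", "OR_low", "OR_high"])


def render_coefficient_report(report: pd.DataFrame, model: str) -> str:
    lines = [f"[{model}]", f"{'Variable':<28}{'beta':>8}{'OR':>8}  95% CI OR"]
    if report.empty:
        lines.append("  (no variables selected)")
        return "\n".join(lines)
    for _, row in report.iterrows():
        ci = (
            f"({row['OR_low']:.2f}-{row['OR_high']:.2f})"
            if np.isfinite(row["OR_low"])
            else "-"
        )
        lines.append(
            f"{row['variable']:<28}{row['beta']:>8.2f}{row['OR']:>8.2f}  {ci}"
        )
    return "\n".join(lines)


def render_indices(agg: pd.DataFrame) -> str:
    """Model-comparison index table (EBIC, AIC, Sens, Spec, Acc, Prec, Mean lambda)."""
    cols = [
        ("EBIC", "ebic"), ("AIC", "aic"), ("Sens", "sensitivity"),
        ("Spec", "specificity"), ("Acc", "accuracy"), ("Prec", "precision"),
        ("Mean(lambda)", "mean_lambda"),
    ]
    lines = ["Model".ljust(16) + "".join(h.rjust(14) for h, _ in cols)]
    for _, row in agg.iterrows():
        lines.append(
            str(row["model"]).ljust(16)
            + "".join(f"{row[c]:>14.3f}" for _, c in cols)
        )
    return "\n".join(lines)
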
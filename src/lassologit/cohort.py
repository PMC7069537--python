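"""Patient-level cohort handling for binary mortality analyses.

A cohort is a table of gastric-cancer-registry-style records: a binary death
indicator (alive=0, dead=1), twelve categorical covariates (sex, smoking,
opium addiction, residence, surgery/chemotherapy/radiotherapy history,
histological grade, stage, tumor morphology, metastasis, family history) and
two continuous ones (age in years, diagnosis-to-event duration in months).

This module reads and validates such tables, produces descriptive "Table 1"
style summaries stratified by death status, encodes the covariates into a
numeric design matrix with explicit reference levels, and provides
seed-deterministic train/test splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORICAL_LEVELS",
    "CONTINUOUS_COVARIATES",
    "CohortTable",
    "DesignMatrix",
    "CohortValidationError",
    "SchemaError",
    "read_cohort",
    "validate_cohort",
    "table_one",
    "encode_design",
    "split_train_test",
    "destandardize_coefficients",
]

#: Allowed levels per categorical covariate; the first level is the
#: reference used when dummy coding ("no"/"male"/"rural"/"neoplasm" etc.).
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "smoking": ("no", "yes"),
    "opium": ("no", "yes"),
    "residence": ("rural", "urban"),
    "surgery": ("no", "yes"),
    "chemotherapy": ("no", "yes"),
    "radiotherapy": ("no", "yes"),
    "grade": ("well", "moderate", "poor"),
    "stage": ("1", "2", "3", "4"),
    "morphology": ("neoplasm", "carcinoma", "adenocarcinoma"),
    "metastasis": ("no", "yes"),
    "family_history": ("no", "yes"),
}

CONTINUOUS_COVARIATES: tuple[str, ...] = ("age", "diagnosis_duration")

OUTCOME = "death_status"

ALL_COLUMNS: tuple[str, ...] = (
    (OUTCOME,) + tuple(CATEGORICAL_LEVELS) + CONTINUOUS_COVARIATES
)


class SchemaError(ValueError):
    """A required column is missing or the schema mapping is malformed."""


class CohortValidationError(ValueError):
    """One or more rows hold values outside the cohort schema.

    ``rows`` lists the offending 0-based row indices (in file order).
    """

    def __init__(self, messages: list[str], rows: list[int]):
        self.rows = rows
        super().__init__("; ".join(messages))


@dataclass
class CohortTable:
    """A validated patient-level cohort.

    ``data`` uses the canonical column names of :data:`CATEGORICAL_LEVELS`
    plus ``death_status``, ``age`` and ``diagnosis_duration``; categorical
    columns are pandas Categoricals with the full level sets.
    ``n_dropped`` counts rows removed by complete-case filtering.
    """

    data: pd.DataFrame
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.data)

    @property
    def records(self) -> list[dict]:
        return self.data.to_dict(orient="records")


def validate_cohort(df: pd.DataFrame) -> CohortTable:
    """Validate a raw frame with canonical column names into a CohortTable.

    Rows with missing values are dropped (complete-case) with a logged
    count; rows with *present but invalid* values raise
    :class:`CohortValidationError` naming the rows.
    """
    missing = [c for c in ALL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = df.loc[:, list(ALL_COLUMNS)].copy()
    df = df.reset_index(drop=True)

    n_before = len(df)
    complete = df.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("complete-case filter dropped %d of %d rows", n_dropped, n_before)
    df = df.loc[complete].reset_index(drop=True)

    problems: list[str] = []
    bad_rows: set[int] = set()
    for col, levels in CATEGORICAL_LEVELS.items():
        values = df[col].astype(str).str.strip().str.lower()
        ok = values.isin(levels)
        if not ok.all():
            for i in np.flatnonzero(~ok.to_numpy()):
                problems.append(
                    f"row {i}: {col}={df[col].iloc[i]!r} not in {levels}"
                )
                bad_rows.add(int(i))
        df[col] = pd.Categorical(values, categories=levels)

    death = pd.to_numeric(df[OUTCOME], errors="coerce")
    ok = death.isin([0, 1])
    for i in np.flatnonzero(~ok.to_numpy()):
        problems.append(f"row {i}: death_status={df[OUTCOME].iloc[i]!r} not in {{0,1}}")
        bad_rows.add(int(i))
    df[OUTCOME] = death

    for col, lower_ok in (("age", False), ("diagnosis_duration", True)):
        vals = pd.to_numeric(df[col], errors="coerce")
        ok = vals.notna() & ((vals >= 0) if lower_ok else (vals > 0))
        for i in np.flatnonzero(~ok.to_numpy()):
            problems.append(f"row {i}: {col}={df[col].iloc[i]!r} out of range")
            bad_rows.add(int(i))
        df[col] = vals.astype(float)

    if problems:
        raise CohortValidationError(problems, sorted(bad_rows))
    df[OUTCOME] = df[OUTCOME].astype(int)
    return CohortTable(data=df, n_dropped=n_dropped)


def read_cohort(path, schema: dict[str, str] | None = None) -> CohortTable:
    """Read a cohort CSV, optionally remapping column names.

    Parameters
    ----------
    path
        CSV file with a header row, one record per patient.
    schema
        Optional map from canonical column name (e.g. ``"sex"``) to the
        column name used in the file. Unmapped names are taken verbatim.
    """
    raw = pd.read_csv(path)
    schema = schema or {}
    rename = {}
    for canonical in ALL_COLUMNS:
        source = schema.get(canonical, canonical)
        if source not in raw.columns:
            raise SchemaError(
                f"column {source!r} (for {canonical!r}) not found in {path}"
            )
        rename[source] = canonical
    return validate_cohort(raw.rename(columns=rename))


def table_one(cohort: CohortTable) -> pd.DataFrame:
    """Descriptive death-stratified frequency table for every categorical covariate.

    One row per (covariate, level) with counts and within-column percentages
    (total / alive / died), percentages rounded to one decimal.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    df = cohort.data
    died = df[OUTCOME] == 1
    n_total, n_died = len(df), int(died.sum())
    n_alive = n_total - n_died
    rows = []
    for col, levels in CATEGORICAL_LEVELS.items():
        for level in levels:
            is_level = df[col] == level
            t = int(is_level.sum())
            d = int((is_level & died).sum())
            a = t - d
            rows.append(
                {
                    "variable": col,
                    "level": level,
                    "total_n": t,
                    "total_pct": round(100.0 * t / n_total, 1),
                    "alive_n": a,
                    "alive_pct": round(100.0 * a / n_alive, 1) if n_alive else np.nan,
                    "died_n": d,
                    "died_pct": round(100.0 * d / n_died, 1) if n_died else np.nan,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_total"] = n_total
    out.attrs["n_died"] = n_died
    out.attrs["died_pct"] = round(100.0 * n_died / n_total, 1)
    return out


@dataclass
class DesignMatrix:
    """Encoded numeric design with outcome and encoding bookkeeping.

    ``standardization`` maps column name -> (mean, scale) applied as
    ``(x - mean) / scale``; identity for unstandardized columns.
    """

    X: np.ndarray
    y: np.ndarray
    column_names: list[str]
    reference_levels: dict[str, str] = field(default_factory=dict)
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)
    degenerate_columns: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if self.X.shape[1] != len(self.column_names):
            raise ValueError("column_names length mismatch")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, rows: np.ndarray) -> "DesignMatrix":
        return DesignMatrix(
            X=self.X[rows],
            y=self.y[rows],
            column_names=list(self.column_names),
            reference_levels=dict(self.reference_levels),
            standardization=dict(self.standardization),
            degenerate_columns=list(self.degenerate_columns),
        )


def encode_design(cohort: CohortTable, standardize: bool = True) -> DesignMatrix:
    """Encode a cohort into a numeric design matrix.

    Each k-level categorical yields k-1 dummy columns against its first
    (reference) level; continuous covariates are standardized to mean 0,
    scale 1 when ``standardize`` is set, with the transform recorded for
    back-transformation. Constant columns are retained but flagged.
    """
    df = cohort.data
    cols: list[np.ndarray] = []
    names: list[str] = []
    refs: dict[str, str] = {}
    std: dict[str, tuple[float, float]] = {}
    for col, levels in CATEGORICAL_LEVELS.items():
        refs[col] = levels[0]
        for level in levels[1:]:
            name = col if len(levels) == 2 else f"{col}[{level}]"
            cols.append((df[col] == level).to_numpy(dtype=float))
            names.append(name)
            std[name] = (0.0, 1.0)
    for col in CONTINUOUS_COVARIATES:
        x = df[col].to_numpy(dtype=float)
        if standardize:
            mu = float(x.mean())
            scale = float(x.std(ddof=0))
            if scale <= 0.0:
                scale = 1.0
            x = (x - mu) / scale
            std[col] = (mu, scale)
        else:
            std[col] = (0.0, 1.0)
        cols.append(x)
        names.append(col)
    X = np.column_stack(cols)
    degenerate = [names[j] for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0.0]
    if degenerate:
        logger.warning("degenerate (constant) design columns: %s", degenerate)
    return DesignMatrix(
        X=X,
        y=df[OUTCOME].to_numpy(dtype=int),
        column_names=names,
        reference_levels=refs,
        standardization=std,
        degenerate_columns=degenerate,
    )


def destandardize_coefficients(
    dm: DesignMatrix, intercept: float, beta: np.ndarray
) -> tuple[float, np.ndarray]:
    """Map coefficients fitted on the standardized design back to raw scale.

    If column j was standardized as (x - mu_j)/s_j, the raw-scale slope is
    beta_j / s_j and the intercept absorbs -sum_j beta_j mu_j / s_j.
    """
    beta = np.asarray(beta, dtype=float)
    raw = beta.copy()
    b0 = float(intercept)
    for j, name in enumerate(dm.column_names):
        mu, scale = dm.standardization.get(name, (0.0, 1.0))
        raw[j] = beta[j] / scale
        b0 -= beta[j] * mu / scale
    return b0, raw


def split_train_test(
    dm: DesignMatrix, train_fraction: float, seed: int
) -> tuple[DesignMatrix, DesignMatrix]:
    """Deterministic disjoint-exhaustive row split.

    Train size is round(n * train_fraction) (half-up); the split is a pure
    function of ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = dm.n
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    n_train = int(np.floor(n * train_fraction + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return dm.subset(np.sort(perm[:n_train])), dm.subset(np.sort(perm[n_train:]))
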
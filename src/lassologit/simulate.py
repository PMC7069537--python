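"""Synthetic data generation.

Two generators back the test and comparison machinery:

* :func:`simulate_scenario` — the two-scenario simulation design: AR(1)-style
  correlated covariates (corr(x_i, x_j) = rho^|i-j|), a stated true
  coefficient vector, and a Bernoulli outcome through the logistic link.
  Scenario 1 has eight continuous covariates with
  beta = (3, 1.5, 0, 0, 2, 0, 0, 0); scenario 2 has nine covariates, the
  first four dichotomized at the latent median, with
  beta = (2, -1, 0, 0, 1, -2, 0, 0, 0).

* :func:`simulate_cohort` — a registry-style gastric-cancer cohort with
  stated marginal level frequencies and a logistic death model whose
  default effects are the reported log-odds (female +0.97, adenocarcinoma
  -1.96, standardized diagnosis-to-event duration -1.55), the intercept
  calibrated so the expected death proportion hits a target (default 0.575).

* :func:`exact_margin_cohort` — a deterministic 339-row synthetic cohort
  whose per-level death-stratified counts reproduce the published
  descriptive table exactly (216 men, 195 deaths, 263 adenocarcinomas, ...).
  Columns are filled independently within the alive/died strata, so joint
  distributions across covariates are not meaningful — it exists to make
  descriptive summaries exactly checkable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import (
    CATEGORICAL_LEVELS,
    CohortTable,
    DesignMatrix,
    validate_cohort,
)

__all__ = [
    "packaged_cohort_path",
    "ScenarioSpec",
    "CohortGeneratorSpec",
    "make_correlation",
    "simulate_scenario",
    "simulate_cohort",
    "exact_margin_cohort",
    "scenario1_spec",
    "scenario2_spec",
    "write_cohort_csv",
    "TABLE1_MARGINS",
]

def packaged_cohort_path() -> str:
    """Path to the packaged 339-row synthetic cohort CSV.

    Generated by :func:`simulate_cohort` with seed 20 (see its sidecar
    manifest); a synthetic stand-in for the undeposited hospital registry.
    """
    from importlib.resources import files

    return str(files("lassologit").joinpath("data/synthetic_cohort_339.csv"))


SCENARIO1_BETA = (3.0, 1.5, 0.0, 0.0, 2.0, 0.0, 0.0, 0.0)
SCENARIO2_BETA = (2.0, -1.0, 0.0, 0.0, 1.0, -2.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation-scenario cell."""

    beta: tuple[float, ...]
    rho: float
    n_train: int
    n_test: int
    binary_columns: tuple[int, ...] = ()  # 0-based covariate indices
    binary_threshold: float = 0.0  # latent cut; 0 gives 50/50 binaries
    intercept: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        p = len(self.beta)
        if any(not 0 <= j < p for j in self.binary_columns):
            raise ValueError("binary_columns out of range")

    @property
    def p(self) -> int:
        return len(self.beta)


def scenario1_spec(n_train: int, rho: float, seed: int = 0) -> ScenarioSpec:
    """Scenario 1: eight continuous covariates, beta = (3,1.5,0,0,2,0,0,0)."""
    return ScenarioSpec(
        beta=SCENARIO1_BETA, rho=rho, n_train=n_train, n_test=n_train // 2, seed=seed
    )


def scenario2_spec(n_train: int, rho: float, seed: int = 0) -> ScenarioSpec:
    """Scenario 2: nine covariates (first four binary), beta = (2,-1,0,0,1,-2,0,0,0)."""
    return ScenarioSpec(
        beta=SCENARIO2_BETA,
        rho=rho,
        n_train=n_train,
        n_test=n_train // 2,
        binary_columns=(0, 1, 2, 3),
        seed=seed,
    )


def make_correlation(p: int, rho: float) -> np.ndarray:
    """AR(1)-style correlation matrix with entry (i, j) = rho^|i-j|."""
    if p < 1:
        raise ValueError("p must be at least 1")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    idx = np.arange(p)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _draw_block(
    spec: ScenarioSpec, n: int, chol: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    for attempt in range(2):
        X = rng.standard_normal((n, spec.p)) @ chol.T
        for j in spec.binary_columns:
            X[:, j] = (X[:, j] > spec.binary_threshold).astype(float)
        eta = spec.intercept + X @ np.asarray(spec.beta)
        y = (rng.random(n) < expit(eta)).astype(int)
        if 0 < y.sum() < n:
            return X, y
    raise RuntimeError("degenerate sample: outcome constant after one resample")


def simulate_scenario(
    spec: ScenarioSpec,
) -> tuple[DesignMatrix, DesignMatrix, np.ndarray]:
    """Simulate independent train and test sets for one scenario cell.

    Covariates are zero-mean multivariate normal with the rho^|i-j|
    correlation; ``binary_columns`` are dichotomized at the latent threshold
    (dependence preserved through the latent draw); the true coefficients
    multiply the observed, post-dichotomization design. Fully determined by
    ``spec.seed``. An all-0 or all-1 outcome is resampled once, then raised.
    """
    rng = np.random.default_rng(spec.seed)
    chol = np.linalg.cholesky(make_correlation(spec.p, spec.rho))
    names = [f"x{j + 1}" for j in range(spec.p)]
    X_tr, y_tr = _draw_block(spec, spec.n_train, chol, rng)
    X_te, y_te = _draw_block(spec, spec.n_test, chol, rng)
    train = DesignMatrix(X=X_tr, y=y_tr, column_names=names)
    test = DesignMatrix(X=X_te, y=y_te, column_names=names)
    return train, test, np.asarray(spec.beta)


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

#: Published per-level marginal frequencies (total column of the descriptive
#: table), used as generator defaults for the covariates the table prints.
TABLE1_MARGINS: dict[str, dict[str, float]] = {
    "sex": {"male": 216 / 339, "female": 123 / 339},
    "residence": {"rural": 67 / 339, "urban": 272 / 339},
    "smoking": {"yes": 91 / 339, "no": 248 / 339},
    "grade": {"well": 11 / 339, "moderate": 270 / 339, "poor": 58 / 339},
    "stage": {"1": 9 / 339, "2": 205 / 339, "3": 91 / 339, "4": 34 / 339},
    "morphology": {
        "neoplasm": 23 / 339,
        "carcinoma": 53 / 339,
        "adenocarcinoma": 263 / 339,
    },
}

#: Field-realistic defaults for covariates the descriptive table omits.
_EXTRA_MARGINS: dict[str, dict[str, float]] = {
    "opium": {"no": 0.8, "yes": 0.2},
    "surgery": {"no": 0.5, "yes": 0.5},
    "chemotherapy": {"no": 0.6, "yes": 0.4},
    "radiotherapy": {"no": 0.75, "yes": 0.25},
    "metastasis": {"no": 0.7, "yes": 0.3},
    "family_history": {"no": 0.85, "yes": 0.15},
}

#: Default death-model effects: the reported log-odds for female sex,
#: adenocarcinoma morphology, and (per SD) diagnosis-to-event duration.
DEFAULT_EFFECTS: dict[str, float] = {
    "sex=female": 0.97,
    "morphology=adenocarcinoma": -1.96,
    "diagnosis_duration": -1.55,
}

# age ~ N(62.84, 14.53^2) truncated to (18, 100); duration ~ Gamma(1.5, scale 12) months
_AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI = 62.84, 14.53, 18.0, 100.0
_DUR_SHAPE, _DUR_SCALE = 1.5, 12.0
_DUR_MEAN = _DUR_SHAPE * _DUR_SCALE
_DUR_SD = np.sqrt(_DUR_SHAPE) * _DUR_SCALE

_CALIBRATION_DRAWS = 200_000


def _default_margins() -> dict[str, dict[str, float]]:
    return {**{k: dict(v) for k, v in TABLE1_MARGINS.items()},
            **{k: dict(v) for k, v in _EXTRA_MARGINS.items()}}


@dataclass(frozen=True)
class CohortGeneratorSpec:
    """Model-based synthetic-cohort recipe.

    ``effect_log_odds`` keys are either ``"covariate=level"`` (indicator
    effect) or a continuous covariate name (effect per standard deviation of
    its generating distribution). ``intercept`` None means: calibrate by
    bisection so the expected death proportion equals ``target_prevalence``.
    """

    n: int = 339
    marginal_frequencies: dict[str, dict[str, float]] = field(
        default_factory=_default_margins
    )
    effect_log_odds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    target_prevalence: float = 0.575
    intercept: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be at least 1")
        for cov, probs in self.marginal_frequencies.items():
            if cov not in CATEGORICAL_LEVELS:
                raise ValueError(f"unknown covariate {cov!r}")
            if set(probs) != set(CATEGORICAL_LEVELS[cov]):
                raise ValueError(f"levels for {cov!r} incomplete")
            if abs(sum(probs.values()) - 1.0) > 1e-8:
                raise ValueError(f"probabilities for {cov!r} do not sum to 1")


def _draw_covariates(spec: CohortGeneratorSpec, n: int, rng: np.random.Generator):
    cols: dict[str, np.ndarray] = {}
    for cov, levels in CATEGORICAL_LEVELS.items():
        probs = spec.marginal_frequencies[cov]
        pvec = np.array([probs[level] for level in levels])
        cols[cov] = rng.choice(np.array(levels, dtype=object), size=n, p=pvec)
    age = rng.normal(_AGE_MEAN, _AGE_SD, size=n)
    while True:  # truncate by redraw
        bad = (age <= _AGE_LO) | (age >= _AGE_HI)
        if not bad.any():
            break
        age[bad] = rng.normal(_AGE_MEAN, _AGE_SD, size=int(bad.sum()))
    cols["age"] = np.round(age, 1)
    cols["diagnosis_duration"] = np.round(
        rng.gamma(_DUR_SHAPE, _DUR_SCALE, size=n), 1
    )
    return cols


def _linear_predictor(spec: CohortGeneratorSpec, cols: dict[str, np.ndarray]) -> np.ndarray:
    n = len(next(iter(cols.values())))
    eta = np.zeros(n)
    for key, coef in spec.effect_log_odds.items():
        if "=" in key:
            cov, level = key.split("=", 1)
            eta += coef * (cols[cov] == level)
        elif key == "age":
            eta += coef * (cols["age"] - _AGE_MEAN) / _AGE_SD
        elif key == "diagnosis_duration":
            eta += coef * (cols["diagnosis_duration"] - _DUR_MEAN) / _DUR_SD
        else:
            raise ValueError(f"unknown effect key {key!r}")
    return eta


def _calibrate_intercept(spec: CohortGeneratorSpec) -> float:
    """Bisection on the intercept so E[death] hits the target prevalence.

    The expectation is estimated on a large covariate sample drawn with a
    fixed internal seed, so the calibrated value is deterministic for a
    given spec regardless of spec.n or spec.seed.
    """
    target = spec.target_prevalence
    if not 0.0 < target < 1.0:
        raise ValueError("target prevalence must lie strictly in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=202_406))
    cols = _draw_covariates(spec, _CALIBRATION_DRAWS, rng)
    eta = _linear_predictor(spec, cols)
    lo, hi = -30.0, 30.0
    if not expit(lo + eta).mean() < target < expit(hi + eta).mean():
        raise ValueError("target prevalence unreachable given the stated effects")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expit(mid + eta).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(spec: CohortGeneratorSpec = CohortGeneratorSpec()) -> CohortTable:
    """Draw a synthetic cohort: independent covariates, logistic death model."""
    intercept = spec.intercept if spec.intercept is not None else _calibrate_intercept(spec)
    rng = np.random.default_rng(spec.seed)
    cols = _draw_covariates(spec, spec.n, rng)
    eta = intercept + _linear_predictor(spec, cols)
    death = (rng.random(spec.n) < expit(eta)).astype(int)
    frame = pd.DataFrame({"death_status": death, **cols})
    cohort = validate_cohort(frame)
    cohort.data.attrs["intercept"] = intercept
    return cohort


#: Death-stratified per-level counts (alive, died) of the published
#: descriptive table; alive totals sum to 144 and died totals to 195.
_TABLE1_STRATIFIED: dict[str, dict[str, tuple[int, int]]] = {
    "sex": {"male": (95, 121), "female": (49, 74)},
    "residence": {"rural": (33, 34), "urban": (111, 161)},
    "smoking": {"yes": (38, 53), "no": (106, 142)},
    "grade": {"well": (5, 6), "moderate": (119, 151), "poor": (20, 38)},
    "stage": {"1": (3, 6), "2": (94, 111), "3": (35, 56), "4": (12, 22)},
    "morphology": {
        "neoplasm": (3, 20),
        "carcinoma": (21, 32),
        "adenocarcinoma": (120, 143),
    },
}


def exact_margin_cohort(seed: int = 0) -> CohortTable:
    """Synthetic 339-row cohort with the published death-stratified counts.

    For each tabulated covariate, level counts within the alive (144) and
    died (195) strata match the published table exactly; columns are filled
    independently within strata (shuffled with ``seed``), so cross-covariate
    joint structure is synthetic. Untabulated covariates and the continuous
    ones are drawn from the generator defaults.
    """
    rng = np.random.default_rng(seed)
    n_alive, n_died = 144, 195
    death = np.array([0] * n_alive + [1] * n_died)
    cols: dict[str, np.ndarray] = {"death_status": death}
    for cov, level_counts in _TABLE1_STRATIFIED.items():
        col = np.empty(n_alive + n_died, dtype=object)
        for stratum, size, offset in ((0, n_alive, 0), (1, n_died, n_alive)):
            vals: list[str] = []
            for level, counts in level_counts.items():
                vals.extend([level] * counts[stratum])
            assert len(vals) == size
            col[offset : offset + size] = rng.permutation(np.array(vals, dtype=object))
        cols[cov] = col
    spec = CohortGeneratorSpec()
    extra = _draw_covariates(spec, n_alive + n_died, rng)
    for cov in list(_EXTRA_MARGINS) + ["age", "diagnosis_duration"]:
        cols[cov] = extra[cov]
    return validate_cohort(pd.DataFrame(cols))


def write_cohort_csv(cohort: CohortTable, path, spec=None) -> None:
    """Write a cohort CSV plus a sidecar JSON manifest (spec hash, row count)."""
    path = str(path)
    cohort.data.to_csv(path, index=False)
    manifest = {"n": len(cohort)}
    if spec is not None:
        blob = json.dumps(asdict(spec), sort_keys=True, default=str)
        manifest["spec"] = json.loads(blob)
        manifest["spec_sha256"] = hashlib.sha256(blob.encode()).hexdigest()
    with open(path + ".manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
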
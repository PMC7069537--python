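"""Cohort reading, validation, descriptive summaries, encoding, splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from lassologit.cohort import (
    CohortValidationError,
    SchemaError,
    destandardize_coefficients,
    encode_design,
    read_cohort,
    split_train_test,
    table_one,
    validate_cohort,
)
from lassologit.simulate import exact_margin_cohort, simulate_cohort, CohortGeneratorSpec

_ROW = {
    "death_status": 1, "sex": "male", "smoking": "no", "opium": "no",
    "residence": "urban", "surgery": "yes", "chemotherapy": "no",
    "radiotherapy": "no", "grade": "moderate", "stage": "2",
    "morphology": "adenocarcinoma", "metastasis": "no",
    "family_history": "no", "age": 60.0, "diagnosis_duration": 12.0,
}


def _frame(rows):
    return pd.DataFrame(rows)


def test_read_cohort_roundtrip(tmp_path):
    rows = [dict(_ROW), dict(_ROW, death_status=0, sex="female"), dict(_ROW, stage="4")]
    path = tmp_path / "c.csv"
    _frame(rows).to_csv(path, index=False)
    cohort = read_cohort(path)
    assert len(cohort) == 3
    assert cohort.data.loc[1, "sex"] == "female"


def test_read_cohort_schema_remap(tmp_path):
    df = _frame([dict(_ROW)]).rename(columns={"sex": "gender"})
    path = tmp_path / "c.csv"
    df.to_csv(path, index=False)
    with pytest.raises(SchemaError):
        read_cohort(path)
    cohort = read_cohort(path, schema={"sex": "gender"})
    assert len(cohort) == 1


def test_invalid_category_names_row():
    bad = _frame([dict(_ROW), dict(_ROW, sex="M")])
    with pytest.raises(CohortValidationError) as err:
        validate_cohort(bad)
    assert err.value.rows == [1]
    assert "sex" in str(err.value)


@pytest.mark.parametrize(
    "field,value", [("age", -3.0), ("diagnosis_duration", -1.0), ("death_status", 2)]
)
def test_out_of_range_values_rejected(field, value):
    with pytest.raises(CohortValidationError):
        validate_cohort(_frame([dict(_ROW, **{field: value})]))


def test_complete_case_filter_logged():
    rows = [dict(_ROW), dict(_ROW, age=np.nan)]
    cohort = validate_cohort(_frame(rows))
    assert len(cohort) == 1
    assert cohort.n_dropped == 1


def test_packaged_fixture_has_339_records(cohort339):
    assert len(cohort339) == 339


def test_table_one_exact_published_margins():
    """The exact-margin synthetic cohort reproduces the published percentages."""
    tab = table_one(exact_margin_cohort(seed=0))
    assert tab.attrs["died_pct"] == 57.5
    male = tab.query("variable == 'sex' and level == 'male'").iloc[0]
    assert male.total_n == 216 and male.total_pct == 63.7
    adeno = tab.query("variable == 'morphology' and level == 'adenocarcinoma'").iloc[0]
    assert adeno.total_n == 263 and adeno.total_pct == 77.6
    neo = tab.query("variable == 'morphology' and level == 'neoplasm'").iloc[0]
    assert (neo.alive_n, neo.died_n) == (3, 20)


def test_table_one_tiny_cohort():
    cohort = validate_cohort(_frame([dict(_ROW), dict(_ROW, death_status=0)]))
    tab = table_one(cohort)
    assert tab.attrs["died_pct"] == 50.0


def test_table_one_percentages_sum_per_covariate(cohort339):
    tab = table_one(cohort339)
    for _, grp in tab.groupby("variable"):
        for col in ("total_pct", "alive_pct", "died_pct"):
            assert abs(grp[col].sum() - 100.0) <= 0.2


def test_table_one_empty_rejected():
    cohort = validate_cohort(_frame([dict(_ROW)]))
    cohort.data = cohort.data.iloc[:0]
    with pytest.raises(ValueError):
        table_one(cohort)


def test_encode_design_column_count_and_refs(dm339):
    # 7 binaries + 2(grade) + 3(stage) + 2(morphology) + metastasis +
    # family_history + age + duration = 18
    assert dm339.p == 18
    assert dm339.reference_levels["sex"] == "male"
    assert dm339.reference_levels["morphology"] == "neoplasm"
    assert dm339.reference_levels["residence"] == "rural"
    assert {"age", "diagnosis_duration"} <= set(dm339.standardization)
    for name in ("age", "diagnosis_duration"):
        col = dm339.X[:, dm339.column_names.index(name)]
        assert abs(col.mean()) < 1e-12 and abs(col.std() - 1.0) < 1e-12


def test_encode_design_degenerate_flagged():
    rows = [dict(_ROW, death_status=i % 2) for i in range(6)]  # all male
    dm = encode_design(validate_cohort(_frame(rows)))
    assert "sex" in dm.degenerate_columns
    assert np.ptp(dm.X[:, dm.column_names.index("sex")]) == 0.0


def test_two_level_morphology_subset_single_dummy():
    rows = [dict(_ROW, morphology=m, death_status=i % 2)
            for i, m in enumerate(["neoplasm", "adenocarcinoma"] * 3)]
    dm = encode_design(validate_cohort(_frame(rows)))
    carc = dm.X[:, dm.column_names.index("morphology[carcinoma]")]
    adeno = dm.X[:, dm.column_names.index("morphology[adenocarcinoma]")]
    assert np.ptp(carc) == 0.0  # empty level encodes as constant 0
    assert set(adeno) == {0.0, 1.0}


def test_standardization_back_transform_reproduces_predictor():
    cohort = simulate_cohort(CohortGeneratorSpec(n=80, seed=3))
    dm_std = encode_design(cohort, standardize=True)
    dm_raw = encode_design(cohort, standardize=False)
    rng = np.random.default_rng(0)
    beta_std = rng.standard_normal(dm_std.p)
    b0_raw, beta_raw = destandardize_coefficients(dm_std, 0.4, beta_std)
    eta_std = 0.4 + dm_std.X @ beta_std
    eta_raw = b0_raw + dm_raw.X @ beta_raw
    assert np.max(np.abs(expit(eta_std) - expit(eta_raw))) < 1e-10


@pytest.mark.parametrize(
    "n,fraction,expected_train",
    [(339, 0.6, 203), (100, 0.5, 50), (101, 0.37, 37)],
)
def test_split_sizes(n, fraction, expected_train, dm339):
    dm = dm339.subset(np.arange(n)) if n <= dm339.n else dm339
    train, test = split_train_test(dm, fraction, seed=7)
    assert train.n == expected_train and test.n == n - expected_train


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 2**31 - 1), frac=st.floats(0.1, 0.9))
def test_split_partition_disjoint_exhaustive(seed, frac, dm339):
    dm = dm339.subset(np.arange(60))
    dm.X = dm.X.copy()
    dm.X[:, 0] = np.arange(60)  # row identities
    train, test = split_train_test(dm, frac, seed)
    ids = np.concatenate([train.X[:, 0], test.X[:, 0]])
    assert sorted(ids.astype(int)) == list(range(60))


def test_split_deterministic(dm339):
    a = split_train_test(dm339, 0.6, seed=5)[0]
    b = split_train_test(dm339, 0.6, seed=5)[0]
    assert np.array_equal(a.X, b.X) and np.array_equal(a.y, b.y)


def test_split_bad_fraction(dm339):
    with pytest.raises(ValueError):
        split_train_test(dm339, 1.2, seed=0)
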
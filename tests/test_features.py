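"""Feature extraction windows, Charlson scoring, and descriptive statistics."""

import numpy as np
import pandas as pd
import pytest

from tjarisk import catalog
from tjarisk.features import (
    build_features,
    charlson_score,
    cramers_v_matrix,
    descriptive_stats,
    kendall_tau_matrix,
)
from tjarisk.synth import CohortBundle

from conftest import toy_cases

CREATION = pd.Timestamp("2018-01-01")


def _mini_bundle(cases, labs=None, encounters=None, diagnoses=None, meds=None,
                 social=None):
    empty = dict(
        labs=pd.DataFrame(columns=["patient_id", "lab_name", "value",
                                   "collect_date"]),
        encounters=pd.DataFrame(columns=["encounter_id", "patient_id",
                                         "encounter_type", "admit_date",
                                         "length_of_stay", "chief_complaint",
                                         "planned_grouper"]),
        diagnoses=pd.DataFrame(columns=["patient_id", "category",
                                        "charlson_weight", "dx_date"]),
        meds=pd.DataFrame(columns=["patient_id", "med_class", "order_date"]),
        social=pd.DataFrame(columns=["patient_id", "item", "value",
                                     "recorded_date"]),
    )
    for df in empty.values():
        for col in df.columns:
            if "date" in col:
                df[col] = df[col].astype("datetime64[ns]")
    sensitive = pd.DataFrame({
        "patient_id": cases["patient_id"].unique(),
        "female": 1, "medicare": 0, "medicaid": 0,
        "birth_date": CREATION - pd.Timedelta(int(65 * 365.25), "D")})
    tables = dict(empty)
    for k, v in dict(labs=labs, encounters=encounters, diagnoses=diagnoses,
                     meds=meds, social=social).items():
        if v is not None:
            tables[k] = v
    return CohortBundle(cases=cases, sensitive=sensitive, truth=pd.DataFrame(),
                        truth_features=pd.DataFrame(), **tables)


def _lab_rows(rows):
    return pd.DataFrame(rows, columns=["patient_id", "lab_name", "value",
                                       "collect_date"])


def test_lab_window_boundary_and_most_recent_wins():
    cases = toy_cases([{"case_creation_date": CREATION}])
    labs = _lab_rows([
        ("P0", "a1c", 9.0, CREATION - pd.Timedelta(731, "D")),   # 2y + 1d: out
        ("P0", "albumin", 4.0, CREATION - pd.Timedelta(730, "D")),  # boundary: in
        ("P0", "creatinine", 1.0, CREATION - pd.Timedelta(400, "D")),
        ("P0", "creatinine", 2.0, CREATION - pd.Timedelta(10, "D")),  # most recent
    ])
    fm = build_features(_mini_bundle(cases, labs=labs))
    row = fm.data.iloc[0]
    assert np.isnan(row["a1c"])
    assert row["albumin"] == 4.0
    assert row["creatinine"] == 2.0


def test_most_recent_tie_breaks_to_last_file_row():
    cases = toy_cases([{"case_creation_date": CREATION}])
    d = CREATION - pd.Timedelta(5, "D")
    labs = _lab_rows([("P0", "a1c", 6.0, d), ("P0", "a1c", 7.5, d)])
    fm = build_features(_mini_bundle(cases, labs=labs))
    assert fm.data.iloc[0]["a1c"] == 7.5


def test_utilization_counts_respect_windows():
    cases = toy_cases([{"case_creation_date": CREATION}])
    enc = pd.DataFrame({
        "encounter_id": [f"E{i}" for i in range(5)],
        "patient_id": "P0",
        "encounter_type": ["ED", "ED", "ED", "ED", "inpatient"],
        "admit_date": [CREATION - pd.Timedelta(d, "D")
                       for d in (10, 300, 730, 731, 100)],
        "length_of_stay": [0, 0, 0, 0, 4],
        "chief_complaint": ["chest_pain", "none", "none", "none", "none"],
        "planned_grouper": "",
    })
    fm = build_features(_mini_bundle(cases, encounters=enc))
    row = fm.data.iloc[0]
    assert row["n_ed_visits"] == 3          # one ED visit is a day out of window
    assert row["n_inpatient_admissions"] == 1
    assert row["max_stay_length"] == 4
    assert row["cc_chest_pain"] == 1 and row["cc_abdominal_pain"] == 0


def test_charlson_set_semantics_and_bounds():
    assert charlson_score([]) == 0
    assert charlson_score(["myocardial_infarction", "renal_disease"]) == 3
    # duplicated category counts once (set semantics oracle: explicit
    # duplicated toy records give the same score as the unique ones)
    dup = ["dementia", "dementia", "aids"]
    assert charlson_score(dup) == charlson_score(set(dup)) == 7
    with pytest.raises(ValueError, match="weights"):
        charlson_score(["x"], weight_map={"x": 7})


def test_charlson_from_diagnosis_table_counts_categories_once():
    cases = toy_cases([{"case_creation_date": CREATION}])
    d = CREATION - pd.Timedelta(30, "D")
    dx = pd.DataFrame({
        "patient_id": "P0",
        "category": ["charlson:dementia", "charlson:dementia", "charlson:aids"],
        "charlson_weight": [1, 1, 6],
        "dx_date": [d, d - pd.Timedelta(1, "D"), d],
    })
    fm = build_features(_mini_bundle(cases, diagnoses=dx))
    assert fm.data.iloc[0]["charlson_score"] == 7


def test_matrix_is_invariant_to_global_date_shift(small_bundle):
    base = build_features(small_bundle).data
    shift = pd.Timedelta(37, "D")
    shifted = CohortBundle(
        cases=small_bundle.cases.assign(
            case_creation_date=small_bundle.cases["case_creation_date"] + shift,
            surgery_date=small_bundle.cases["surgery_date"] + shift,
            discharge_date=small_bundle.cases["discharge_date"] + shift),
        encounters=small_bundle.encounters.assign(
            admit_date=small_bundle.encounters["admit_date"] + shift),
        labs=small_bundle.labs.assign(
            collect_date=small_bundle.labs["collect_date"] + shift),
        meds=small_bundle.meds.assign(
            order_date=small_bundle.meds["order_date"] + shift),
        diagnoses=small_bundle.diagnoses.assign(
            dx_date=small_bundle.diagnoses["dx_date"] + shift),
        social=small_bundle.social.assign(
            recorded_date=small_bundle.social["recorded_date"] + shift),
        sensitive=small_bundle.sensitive.assign(
            birth_date=small_bundle.sensitive["birth_date"] + shift),
        truth=small_bundle.truth, truth_features=small_bundle.truth_features)
    pd.testing.assert_frame_equal(base, build_features(shifted).data)


def test_full_matrix_reproduces_generator_truth(small_bundle):
    fm = build_features(small_bundle)
    truth = small_bundle.truth_features.set_index("case_id")
    for col in truth.columns:
        a = fm.data[col].astype(float)
        t = truth[col].astype(float)
        match = (a.isna() & t.isna()) | (np.abs(a - t) < 1e-9)
        assert match.all(), col


def test_kendall_tau_matches_brute_force_enumeration(rng):
    def brute_tau_b(x, y):
        n = len(x)
        c = d = 0
        tx = ty = 0
        for i in range(n):
            for j in range(i + 1, n):
                sx = np.sign(x[i] - x[j])
                sy = np.sign(y[i] - y[j])
                if sx == 0 and sy == 0:
                    tx += 1
                    ty += 1
                elif sx == 0:
                    tx += 1
                elif sy == 0:
                    ty += 1
                elif sx == sy:
                    c += 1
                else:
                    d += 1
        n0 = n * (n - 1) / 2
        return (c - d) / np.sqrt((n0 - tx) * (n0 - ty))

    # worked example: all 6 pairs enumerated, (C-D)/(n(n-1)/2) = (5-1)/6
    x = np.array([1, 2, 3, 4.0])
    y = np.array([1, 3, 2, 4.0])
    m = kendall_tau_matrix(pd.DataFrame({"x": x, "y": y}))
    assert m.loc["x", "y"] == pytest.approx(2 / 3)
    assert m.loc["x", "x"] == 1.0
    m_rev = kendall_tau_matrix(pd.DataFrame({"x": x, "y": x[::-1]}))
    assert m_rev.loc["x", "y"] == pytest.approx(-1.0)
    for _ in range(5):
        a = rng.integers(0, 5, size=12).astype(float)
        b = rng.integers(0, 5, size=12).astype(float)
        if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
            continue
        got = kendall_tau_matrix(pd.DataFrame({"a": a, "b": b})).loc["a", "b"]
        assert got == pytest.approx(brute_tau_b(a, b), abs=1e-12)


def test_cramers_v_bounds_and_determinism(rng):
    a = rng.integers(0, 2, 500)
    df = pd.DataFrame({"a": a, "same": a, "indep": rng.integers(0, 2, 500)})
    m = cramers_v_matrix(df)
    assert m.loc["a", "same"] == pytest.approx(1.0)
    assert 0 <= m.loc["a", "indep"] < 0.15
    assert ((m.fillna(0) >= 0) & (m.fillna(0) <= 1)).all().all()


def test_constant_column_reports_undefined_association():
    df = pd.DataFrame({"c": np.ones(50), "x": np.arange(50.0)})
    m = kendall_tau_matrix(df)
    assert np.isnan(m.loc["c", "x"])


def test_flagged_high_tau_pairs_are_exactly_the_planted_ones(medium_truth):
    truth_features, _ = medium_truth
    stats = descriptive_stats(truth_features)
    got = {tuple(sorted((a, b))) for a, b, _ in
           stats["high_tau_pairs"].itertuples(index=False)}
    planted = {tuple(sorted(p)) for p in [
        ("red_blood_cell", "hematocrit"), ("red_blood_cell", "hemoglobin"),
        ("hematocrit", "hemoglobin"),
        ("max_stay_length", "n_inpatient_admissions")]}
    assert got == planted


def test_descriptive_summary_matches_target_moments(medium_truth):
    truth_features, _ = medium_truth
    stats = descriptive_stats(truth_features)
    cont = stats["continuous"]
    assert abs(cont.loc["age", "mean"] - 66.54) < 0.35
    assert abs(cont.loc["bmi", "mean"] - 31.68) < 0.35
    assert cont.loc["protein_in_urine", "missing_frac"] > 0.70
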
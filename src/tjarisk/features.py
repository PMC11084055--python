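"""Case-level feature extraction and descriptive statistics.

Every feature is extracted over a lookback window anchored at the surgical
case creation date: diagnoses as binary flags over 1 year, medications as
binary pharmaceutical-class flags over 90 days, labs as the most recent
value within 2 years (missing when no result exists in the window),
utilization counts over feature-specific windows, and social/demographic
flags from the most recent record. Windowing is anchor-consistent: shifting
every date in the bundle by a constant leaves the matrix unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import contingency

from . import catalog
from .catalog import CHARLSON_WEIGHTS, FeatureSpec
from .synth import CohortBundle


@dataclass
class FeatureMatrix:
    """Named case-level feature vectors with per-column provenance."""

    data: pd.DataFrame      # one row per case; index = case_id
    meta: pd.DataFrame      # per-column family / window_days / aggregation

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    @property
    def case_ids(self) -> pd.Index:
        return self.data.index


def charlson_score(categories, weight_map: dict[str, int] | None = None) -> int:
    """Charlson comorbidity index: sum of weights over *distinct* categories.

    ``categories`` is any iterable of comorbidity-category names present in
    the lookback window; duplicates count once. A score of zero means no
    comorbidities were found. Weights must lie in [1, 6].
    """
    weight_map = weight_map if weight_map is not None else CHARLSON_WEIGHTS
    if any(not (1 <= w <= 6) for w in weight_map.values()):
        raise ValueError("Charlson weights must lie in [1, 6]")
    return int(sum(weight_map[c] for c in set(categories) if c in weight_map))


def _window_merge(cases: pd.DataFrame, table: pd.DataFrame, date_col: str,
                  window_days: int | None) -> pd.DataFrame:
    """Join a patient-level event table to cases and keep in-window rows.

    In-window means the event is ``delta`` days before case creation with
    0 <= delta <= window_days (``window_days=None``: any time at or before
    creation, used for 'most recent record' semantics).
    """
    merged = table.merge(cases[["case_id", "patient_id", "case_creation_date"]],
                         on="patient_id")
    delta = (merged["case_creation_date"] - merged[date_col]).dt.days
    keep = delta >= 0
    if window_days is not None:
        keep &= delta <= window_days
    return merged.loc[keep]


def _most_recent(df: pd.DataFrame, date_col: str, value_col: str,
                 by: str = "case_id") -> pd.Series:
    """Latest value per case; ties on the timestamp break to the last row in
    file order (stable sort), keeping extraction deterministic."""
    s = df.sort_values(date_col, kind="stable").groupby(by)[value_col].last()
    return s


def build_features(bundle: CohortBundle,
                   specs: tuple[FeatureSpec, ...] = catalog.ALL_GENERATED_FEATURES,
                   ) -> FeatureMatrix:
    """Construct the case-level feature matrix from the bundle tables."""
    cases = bundle.cases
    idx = pd.Index(cases["case_id"], name="case_id")
    out = pd.DataFrame(index=idx)
    by_name = {s.name: s for s in specs}

    def want(name):
        return name in by_name

    # Demographics ---------------------------------------------------------
    sens = bundle.sensitive.set_index("patient_id")
    pidx = cases["patient_id"]
    if want("age"):
        birth = pidx.map(sens["birth_date"])
        out["age"] = ((cases["case_creation_date"].to_numpy() - birth.to_numpy())
                      / np.timedelta64(1, "D")) / 365.25
    for col in ("female", "medicare", "medicaid"):
        if want(col):
            out[col] = pidx.map(sens[col]).to_numpy()

    # Labs (most recent value in the 2-year window) ------------------------
    lab_specs = [s for s in specs if s.family == "lab"] \
        + ([by_name["bmi"]] if want("bmi") else [])
    if lab_specs and len(bundle.labs):
        in_win = _window_merge(cases, bundle.labs, "collect_date", catalog.DAYS_LAB)
        for spec in lab_specs:
            rows = in_win.loc[in_win["lab_name"] == spec.name]
            out[spec.name] = _most_recent(rows, "collect_date", "value").reindex(idx)
    else:
        for spec in lab_specs:
            out[spec.name] = np.nan

    # Utilization counts and flags -----------------------------------------
    enc = bundle.encounters
    def _count(enc_type, window):
        rows = _window_merge(cases, enc.loc[enc["encounter_type"] == enc_type],
                             "admit_date", window)
        return rows.groupby("case_id").size().reindex(idx, fill_value=0).astype(float)

    if want("n_ed_visits"):
        out["n_ed_visits"] = _count("ED", catalog.DAYS_ED)
    if want("n_inpatient_admissions"):
        out["n_inpatient_admissions"] = _count("inpatient", catalog.DAYS_INPATIENT)
    if want("n_office_visits"):
        out["n_office_visits"] = _count("office", catalog.DAYS_APPT)
    if want("n_no_show_appts"):
        out["n_no_show_appts"] = _count("no_show", catalog.DAYS_APPT)
    if want("n_cancelled_appts"):
        out["n_cancelled_appts"] = _count("cancelled", catalog.DAYS_APPT)
    if want("n_surgeries"):
        out["n_surgeries"] = _count("surgery", catalog.DAYS_SURGERY_HISTORY)
    if want("max_stay_length"):
        rows = _window_merge(cases, enc.loc[enc["encounter_type"] == "inpatient"],
                             "admit_date", catalog.DAYS_MAX_STAY)
        out["max_stay_length"] = (rows.groupby("case_id")["length_of_stay"].max()
                                  .reindex(idx, fill_value=0).astype(float))
    cc_map = {"cc_abdominal_pain": "abdominal_pain", "cc_chest_pain": "chest_pain",
              "cc_shortness_of_breath": "shortness_of_breath"}
    ed_rows = _window_merge(cases, enc.loc[enc["encounter_type"] == "ED"],
                            "admit_date", catalog.DAYS_ED)
    for feat, complaint in cc_map.items():
        if want(feat):
            hit = ed_rows.loc[ed_rows["chief_complaint"] == complaint, "case_id"]
            out[feat] = idx.isin(set(hit)).astype(np.int8)

    # Diagnoses (binary over 1 year) and the Charlson score ----------------
    dx_in_win = _window_merge(cases, bundle.diagnoses, "dx_date",
                              catalog.DAYS_DIAGNOSIS)
    dx_specs = [s for s in specs if s.family == "diagnosis"]
    for spec in dx_specs:
        hit = dx_in_win.loc[dx_in_win["category"] == spec.name, "case_id"]
        out[spec.name] = idx.isin(set(hit)).astype(np.int8)
    if want("charlson_score"):
        ch = dx_in_win.loc[dx_in_win["charlson_weight"] > 0,
                           ["case_id", "category", "charlson_weight"]]
        score = (ch.drop_duplicates(["case_id", "category"])
                 .groupby("case_id")["charlson_weight"].sum())
        out["charlson_score"] = score.reindex(idx, fill_value=0).astype(float)

    # Medications (binary by class over 90 days) ---------------------------
    med_specs = [s for s in specs if s.family == "medication"]
    if med_specs:
        med_in_win = _window_merge(cases, bundle.meds, "order_date",
                                   catalog.DAYS_MEDICATION)
        for spec in med_specs:
            hit = med_in_win.loc[med_in_win["med_class"] == spec.name, "case_id"]
            out[spec.name] = idx.isin(set(hit)).astype(np.int8)

    # Social history: most recent record at or before case creation;
    # flowsheet fall items additionally respect their 1-year window.
    soc_any = _window_merge(cases, bundle.social, "recorded_date", None)
    soc_1yr = _window_merge(cases, bundle.social, "recorded_date",
                            catalog.DAYS_DIAGNOSIS)
    for name in ("tobacco_use", "alcohol_use", "illegal_drug_use",
                 "relationship_status", "has_pcp", "fall_risk", "fall_history"):
        if want(name):
            src = soc_1yr if name in ("fall_risk", "fall_history") else soc_any
            rows = src.loc[src["item"] == name]
            vals = _most_recent(rows, "recorded_date", "value").reindex(idx)
            out[name] = vals  # NaN where no record exists

    meta = pd.DataFrame(
        [(c, by_name[c].family, by_name[c].window_days, by_name[c].aggregation)
         for c in out.columns if c in by_name],
        columns=["feature", "family", "window_days", "aggregation"],
    ).set_index("feature")
    unknown = [c for c in out.columns if c not in by_name]
    if unknown:
        raise ValueError(f"features without a spec: {unknown}")
    return FeatureMatrix(data=out, meta=meta)


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

def kendall_tau_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Kendall tau-b (tie-corrected) over continuous columns.

    Computed on pairwise-complete observations; NaN for pairs where either
    column is constant (tau undefined).
    """
    cols = list(df.columns)
    m = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            sub = df[[a, b]].dropna()
            if len(sub) < 2 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
                tau = np.nan
            else:
                tau = stats.kendalltau(sub[a], sub[b]).statistic
            m.loc[a, b] = m.loc[b, a] = tau
    return m


def cramers_v_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Cramér's V over categorical/binary columns (in [0, 1]);
    NaN where a column is constant on the pairwise-complete rows."""
    cols = list(df.columns)
    m = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            sub = df[[a, b]].dropna()
            if len(sub) == 0 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
                v = np.nan
            else:
                table = pd.crosstab(sub[a], sub[b]).to_numpy()
                v = contingency.association(table, method="cramer", correction=False)
            m.loc[a, b] = m.loc[b, a] = v
    return m


def descriptive_stats(matrix: FeatureMatrix | pd.DataFrame,
                      tau_threshold: float = 0.65) -> dict[str, pd.DataFrame]:
    """Summary tables for a feature matrix.

    Returns ``continuous`` (mean/SD/min/quartiles/max per continuous
    feature), ``kendall_tau`` and ``cramers_v`` association matrices, and
    ``high_tau_pairs`` — the feature pairs with \\|tau\\| above the threshold.
    """
    df = matrix.data if isinstance(matrix, FeatureMatrix) else matrix
    cont_cols = [c for c in df.columns
                 if c in catalog.FEATURE_INDEX and catalog.FEATURE_INDEX[c].is_continuous]
    cat_cols = [c for c in df.columns
                if c in catalog.FEATURE_INDEX and not catalog.FEATURE_INDEX[c].is_continuous]
    cont = df[cont_cols]
    summary = pd.DataFrame({
        "mean": cont.mean(), "sd": cont.std(),
        "min": cont.min(), "q25": cont.quantile(0.25),
        "median": cont.quantile(0.50), "q75": cont.quantile(0.75),
        "max": cont.max(),
        "missing_frac": cont.isna().mean(),
    })
    tau = kendall_tau_matrix(cont)
    v = cramers_v_matrix(df[cat_cols]) if cat_cols else pd.DataFrame()
    pairs = []
    for i, a in enumerate(tau.columns):
        for b in tau.columns[i + 1:]:
            t = tau.loc[a, b]
            if np.isfinite(t) and abs(t) > tau_threshold:
                pairs.append((a, b, t))
    high = pd.DataFrame(pairs, columns=["feature_i", "feature_j", "tau"])
    return {"continuous": summary, "kendall_tau": tau, "cramers_v": v,
            "high_tau_pairs": high}
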
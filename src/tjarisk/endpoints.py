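"""Combined-endpoint labeling and case exclusion rules.

A surgical case is positive when at least one of the following holds:

a) an inpatient admission with admit date within 30 days after the surgical
   discharge date (inclusive on both ends),
b) an ED encounter within the same window, or
c) a discharge disposition to a SNF/rehab facility — unless the patient was
   already admitted from a SNF (the SNF-to-SNF carve-out).

Planned readmissions (encounters whose grouper matches a configured list,
e.g. pregnancy/delivery or organ transplantation) never count as endpoint
mechanisms, and cases carrying one are excluded from the cohort entirely
when ``exclude_planned`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import PLANNED_GROUPERS

REASONS = ("inpatient_30d", "ed_30d", "snf_discharge")


@dataclass
class ExclusionConfig:
    """Which encounter groupers mark planned readmissions, and the window."""

    planned_groupers: tuple[str, ...] = PLANNED_GROUPERS
    window_days: int = 30
    #: Whether a same-day (day 0) post-discharge encounter counts. The window
    #: is [0, window_days] when True, [1, window_days] otherwise.
    include_day_zero: bool = True
    exclude_planned: bool = True
    #: Drop SNF discharge as an endpoint mechanism (sensitivity toggle).
    use_snf_rule: bool = True


def label_cohort(cases: pd.DataFrame, encounters: pd.DataFrame,
                 config: ExclusionConfig | None = None) -> pd.DataFrame:
    """Label every case against the combined endpoint.

    Returns one row per case: ``case_id``, ``label`` (nullable Int8 — NA when
    the case is excluded or unlabelable), ``reasons`` (``|``-joined subset of
    {inpatient_30d, ed_30d, snf_discharge}), ``excluded`` and
    ``exclusion_reason``, and ``error`` for cases that could not be labeled
    (e.g. missing discharge date). Labeling is a pure function of the case
    row and the patient's encounters; encounter row order is irrelevant.
    """
    config = config or ExclusionConfig()
    lo = 0 if config.include_day_zero else 1
    hi = config.window_days

    out = cases[["case_id", "patient_id"]].copy()
    missing_discharge = cases["discharge_date"].isna().to_numpy()

    enc = encounters.merge(
        cases[["case_id", "patient_id", "discharge_date"]], on="patient_id")
    delta = (enc["admit_date"] - enc["discharge_date"]).dt.days
    in_window = (delta >= lo) & (delta <= hi)
    planned = enc["planned_grouper"].fillna("").isin(config.planned_groupers) \
        & (enc["planned_grouper"].fillna("") != "")
    is_ip = enc["encounter_type"] == "inpatient"
    is_ed = enc["encounter_type"] == "ED"

    ip_hit = enc.loc[in_window & is_ip & ~planned, "case_id"].unique()
    ed_hit = enc.loc[in_window & is_ed & ~planned, "case_id"].unique()
    planned_hit = enc.loc[in_window & is_ip & planned, "case_id"].unique()

    out["inpatient_30d"] = out["case_id"].isin(ip_hit)
    out["ed_30d"] = out["case_id"].isin(ed_hit)
    snf = (cases["discharge_disposition"] == "snf_rehab") \
        & (cases["admitted_from_snf"].astype(bool) == False)  # noqa: E712
    out["snf_discharge"] = snf.to_numpy() if config.use_snf_rule else False

    excluded = out["case_id"].isin(planned_hit) if config.exclude_planned \
        else pd.Series(False, index=out.index)
    out["excluded"] = excluded.astype(np.int8)
    out["exclusion_reason"] = np.where(excluded, "planned_readmission", "")
    out["error"] = np.where(missing_discharge, "missing_discharge_date", "")

    label = (out[list(REASONS)].any(axis=1)).astype("Int8")
    label[excluded.to_numpy() | missing_discharge] = pd.NA
    out["label"] = label
    out["reasons"] = [
        "|".join(r for r in REASONS if row[r]) if lab is not pd.NA else ""
        for (_, row), lab in zip(out.iterrows(), label)
    ]
    return out[["case_id", "label", "reasons", "inpatient_30d", "ed_30d",
                "snf_discharge", "excluded", "exclusion_reason", "error"]]


def label_case(case: pd.Series, encounters: pd.DataFrame,
               config: ExclusionConfig | None = None) -> pd.Series:
    """Label a single case (thin wrapper over :func:`label_cohort`)."""
    if pd.isna(case.get("discharge_date")):
        raise ValueError(f"case {case.get('case_id')}: missing discharge date")
    res = label_cohort(pd.DataFrame([case]), encounters, config)
    return res.iloc[0]


CASE_EXCLUSION_FLAGS = (
    ("pre_existing_fracture", "fracture"),
    ("revision_or_partial", "revision_or_partial"),
    ("intraop_fatality", "intraop_fatality"),
)


def apply_case_exclusions(cases: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove non-elective / non-total-replacement / fatality cases.

    Returns the retained cases and a per-reason exclusion ledger; a case
    matching several flags is counted under the first matching reason
    (fracture, then revision, then intra-operative fatality).
    """
    counted = pd.Series(False, index=cases.index)
    ledger: dict[str, int] = {}
    drop = pd.Series(False, index=cases.index)
    for col, reason in CASE_EXCLUSION_FLAGS:
        flag = cases[col].astype(bool) if col in cases.columns \
            else pd.Series(False, index=cases.index)
        ledger[reason] = int((flag & ~counted).sum())
        counted |= flag
        drop |= flag
    return cases.loc[~drop].reset_index(drop=True), ledger
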
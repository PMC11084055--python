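"""Feature catalog for the total-joint-arthroplasty risk pipeline.

The catalog is the single source of truth shared by the synthetic cohort
generator and the feature builder: every case-level feature has a name, a
family (demographic, social, diagnosis, medication, lab, utilization, score),
a lookback window anchored at the surgical-case creation date, and an
aggregation rule. Continuous features additionally carry marginal-distribution
targets (mean, SD, min, max) used by the generator's Gaussian copula.

Windows follow the pipeline's extraction conventions: diagnoses are binary
flags over a 1-year lookback, medications binary by pharmaceutical class over
90 days, labs are the most recent value within 2 years, utilization counts
use feature-specific windows (ED visits 2 years, inpatient admissions 1 year,
no-shows/cancellations/office visits 90 days, maximum length of stay 2 years).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

Family = Literal[
    "demographic", "social", "diagnosis", "medication", "lab", "utilization", "score"
]
Aggregation = Literal["any", "count", "most_recent", "max"]

DAYS_DIAGNOSIS = 365
DAYS_MEDICATION = 90
DAYS_LAB = 730
DAYS_ED = 730
DAYS_INPATIENT = 365
DAYS_APPT = 90
DAYS_MAX_STAY = 730
DAYS_NOTES = 120
DAYS_SURGERY_HISTORY = 365


@dataclass(frozen=True)
class FeatureSpec:
    """One case-level feature: identity, provenance window and aggregation."""

    name: str
    family: Family
    window_days: int
    aggregation: Aggregation
    # Marginal targets for continuous features (generator side); None for binary.
    mean: float | None = None
    sd: float | None = None
    vmin: float | None = None
    vmax: float | None = None
    marginal: Literal["truncnorm", "lognorm", "nbinom", "charlson"] | None = None
    # Bernoulli prevalence for binary features (generator side).
    prevalence: float | None = None
    missing_rate: float = 0.0

    @property
    def is_continuous(self) -> bool:
        return self.mean is not None


def _lab(name, mean, sd, vmin, vmax, marginal, missing):
    return FeatureSpec(name, "lab", DAYS_LAB, "most_recent",
                       mean, sd, vmin, vmax, marginal, missing_rate=missing)


def _count(name, mean, sd, vmax, window):
    return FeatureSpec(name, "utilization", window, "count",
                       mean, sd, 0.0, vmax, "nbinom")


def _dx(name, prevalence):
    return FeatureSpec(name, "diagnosis", DAYS_DIAGNOSIS, "any", prevalence=prevalence)


def _med(name, prevalence):
    return FeatureSpec(name, "medication", DAYS_MEDICATION, "any", prevalence=prevalence)


#: Continuous features with moment targets matching the study cohort summaries.
CONTINUOUS_FEATURES: tuple[FeatureSpec, ...] = (
    FeatureSpec("age", "demographic", 0, "most_recent",
                66.54, 10.09, 18.06, 98.92, "truncnorm"),
    FeatureSpec("bmi", "score", DAYS_LAB, "most_recent",
                31.68, 6.06, 13.65, 70.49, "truncnorm", missing_rate=0.03),
    _count("n_ed_visits", 0.53, 1.49, 65, DAYS_ED),
    _count("max_stay_length", 0.71, 2.14, 59, DAYS_MAX_STAY),
    _lab("a1c", 6.0, 0.92, 4.1, 15.1, "lognorm", 0.45),
    FeatureSpec("charlson_score", "score", DAYS_DIAGNOSIS, "most_recent",
                2.06, 2.54, 0.0, 21.0, "charlson"),
    _count("n_no_show_appts", 0.18, 0.59, 28, DAYS_APPT),
    _lab("prothrombin_time", 13.46, 5.0, 8.4, 88.9, "lognorm", 0.78),
    _count("n_office_visits", 1.56, 1.81, 25, DAYS_APPT),
    _lab("total_bilirubin", 0.5, 0.28, 0.1, 5.9, "lognorm", 0.20),
    _count("n_cancelled_appts", 1.08, 2.07, 62, DAYS_APPT),
    _lab("albumin", 4.25, 0.35, 1.5, 5.5, "truncnorm", 0.15),
    _lab("blood_urea_nitrogen", 16.48, 6.33, 2.0, 103.0, "lognorm", 0.15),
    _lab("total_protein", 6.88, 0.5, 3.8, 10.0, "truncnorm", 0.74),
    _lab("alanine_transaminase", 21.68, 15.72, 3.0, 650.0, "lognorm", 0.20),
    FeatureSpec("fall_risk", "score", DAYS_DIAGNOSIS, "most_recent",
                44.09, 27.88, 0.0, 100.0, "truncnorm", missing_rate=0.72),
    _lab("alkaline_phosphatase", 82.05, 31.48, 12.0, 1622.0, "lognorm", 0.20),
    _lab("hemoglobin", 13.17, 1.77, 6.0, 20.3, "truncnorm", 0.10),
    _lab("creatinine", 0.92, 0.39, 0.2, 15.1, "lognorm", 0.15),
    _lab("white_blood_cell", 7.69, 2.87, 0.7, 71.6, "lognorm", 0.10),
    _lab("red_blood_cell", 4.42, 0.58, 1.98, 7.43, "truncnorm", 0.10),
    _lab("hematocrit", 39.75, 4.9, 18.3, 62.1, "truncnorm", 0.10),
    _lab("platelets", 248.71, 70.52, 29.0, 993.0, "truncnorm", 0.10),
    _count("n_inpatient_admissions", 0.18, 0.49, 17, DAYS_INPATIENT),
    _lab("partial_thromboplastin_time", 30.14, 8.66, 17.0, 142.2, "lognorm", 0.76),
    _count("n_surgeries", 0.36, 0.7, 15, DAYS_SURGERY_HISTORY),
    _lab("protein_in_urine", 35.17, 50.73, 3.0, 282.1, "lognorm", 0.80),
)

#: Binary diagnosis flags (CCS-style categories, 1-year lookback).
DIAGNOSIS_FEATURES: tuple[FeatureSpec, ...] = (
    _dx("dx_connective_tissue", 0.54),
    _dx("dx_hypertension", 0.51),
    _dx("dx_respiratory_disorder", 0.18),
    _dx("dx_nervous_system", 0.14),
    _dx("dx_abdominal_pain", 0.08),
    _dx("dx_heart_disorder", 0.12),
    _dx("dx_cardiac_dysrhythmia", 0.11),
    _dx("dx_fluid_electrolyte", 0.07),
    _dx("dx_copd", 0.09),
    _dx("dx_urinary_tract_infection", 0.06),
    _dx("dx_upper_respiratory_infection", 0.07),
    _dx("dx_asthma", 0.08),
    _dx("dx_nausea_vomiting", 0.04),
    _dx("dx_back_problem", 0.22),
    _dx("dx_syncope", 0.03),
    _dx("dx_thromboembolism", 0.03),
    _dx("dx_heart_valve", 0.05),
    _dx("dx_cognitive_disorder", 0.03),
    _dx("dx_nutritional_disorder", 0.06),
    _dx("dx_gi_hemorrhage", 0.02),
    _dx("dx_substance_disorder", 0.03),
    _dx("dx_gastroenteritis", 0.02),
    _dx("dx_cerebrovascular", 0.02),
    _dx("dx_respiratory_failure", 0.01),
    _dx("dx_acute_mi", 0.01),
    _dx("dx_hiv", 0.003),
    _dx("dx_spinal_cord_injury", 0.002),
    _dx("dx_diabetes", 0.21),
    _dx("dx_anemia", 0.10),
    _dx("dx_depression", 0.16),
    _dx("dx_osteoporosis", 0.09),
    _dx("dx_renal_failure", 0.05),
    _dx("dx_obesity", 0.24),
    _dx("dx_sleep_apnea", 0.13),
    _dx("dx_hypothyroidism", 0.14),
    _dx("dx_gerd", 0.19),
    _dx("dx_chronic_pain", 0.15),
    _dx("dx_hyperlipidemia", 0.38),
    _dx("dx_peripheral_vascular", 0.04),
)

#: Binary medication flags (active orders by pharmaceutical class, 90 days).
MEDICATION_FEATURES: tuple[FeatureSpec, ...] = (
    _med("med_anticoagulant", 0.09),
    _med("med_hematopoietic", 0.02),
    _med("med_diuretic", 0.16),
    _med("med_antirheumatic", 0.05),
    _med("med_beta_blocker", 0.22),
    _med("med_antidiabetic", 0.15),
    _med("med_calcium_blocker", 0.14),
    _med("med_antiemetic", 0.06),
    _med("med_corticosteroid", 0.10),
    _med("med_vitamin", 0.30),
    _med("med_antiparkinsonian", 0.02),
    _med("med_narcotic_analgesic", 0.25),
    _med("med_antianginal", 0.03),
    _med("med_antipsychotic", 0.02),
    _med("med_antihypertensive", 0.28),
    _med("med_antidepressant", 0.20),
    _med("med_antibiotic", 0.08),
    _med("med_bronchodilator", 0.07),
)

#: Social-history flags from the most recent record.
SOCIAL_FEATURES: tuple[FeatureSpec, ...] = (
    FeatureSpec("tobacco_use", "social", DAYS_DIAGNOSIS, "most_recent", prevalence=0.12),
    FeatureSpec("alcohol_use", "social", DAYS_DIAGNOSIS, "most_recent", prevalence=0.40),
    FeatureSpec("illegal_drug_use", "social", DAYS_DIAGNOSIS, "most_recent", prevalence=0.03),
    FeatureSpec("relationship_status", "social", DAYS_DIAGNOSIS, "most_recent", prevalence=0.60),
    FeatureSpec("has_pcp", "social", DAYS_DIAGNOSIS, "most_recent", prevalence=0.85),
    FeatureSpec("fall_history", "social", DAYS_DIAGNOSIS, "any",
                prevalence=0.15, missing_rate=0.72),
)

#: Sensitive attributes (also model features, per the study design).
SENSITIVE_FEATURES: tuple[FeatureSpec, ...] = (
    FeatureSpec("female", "demographic", 0, "most_recent", prevalence=0.59),
    FeatureSpec("medicare", "demographic", 0, "most_recent", prevalence=0.60),
    FeatureSpec("medicaid", "demographic", 0, "most_recent", prevalence=0.10),
)

#: ED chief-complaint flags over the 2-year ED window.
CHIEF_COMPLAINT_FEATURES: tuple[FeatureSpec, ...] = (
    FeatureSpec("cc_abdominal_pain", "utilization", DAYS_ED, "any", prevalence=0.10),
    FeatureSpec("cc_chest_pain", "utilization", DAYS_ED, "any", prevalence=0.12),
    FeatureSpec("cc_shortness_of_breath", "utilization", DAYS_ED, "any", prevalence=0.08),
)

# Chief-complaint prevalences above are conditional on having >= 1 ED visit in
# the window; a case with no ED visits necessarily carries 0 on all three.

ALL_GENERATED_FEATURES: tuple[FeatureSpec, ...] = (
    CONTINUOUS_FEATURES
    + DIAGNOSIS_FEATURES
    + MEDICATION_FEATURES
    + SOCIAL_FEATURES
    + SENSITIVE_FEATURES
    + CHIEF_COMPLAINT_FEATURES
)

#: Features appended downstream of the generator: the note-derived risk score
#: (scored by the notes module) and the BMI imputation indicator (added by the
#: imputation stage). Together with the generated set this is the 98-feature
#: design.
DOWNSTREAM_FEATURES: tuple[FeatureSpec, ...] = (
    FeatureSpec("nlp_risk_score", "score", DAYS_NOTES, "most_recent",
                0.38, 0.19, 0.03, 0.9, None),
    FeatureSpec("imputed_bmi", "score", 0, "any", prevalence=None),
)

FEATURE_INDEX: dict[str, FeatureSpec] = {
    f.name: f for f in ALL_GENERATED_FEATURES + DOWNSTREAM_FEATURES
}

CONTINUOUS_NAMES: tuple[str, ...] = tuple(f.name for f in CONTINUOUS_FEATURES)
BINARY_NAMES: tuple[str, ...] = tuple(
    f.name for f in ALL_GENERATED_FEATURES if not f.is_continuous
)

#: Classic Charlson comorbidity categories and weights (each category counted
#: once; the score is the sum of weights over distinct categories present).
CHARLSON_WEIGHTS: dict[str, int] = {
    "myocardial_infarction": 1,
    "congestive_heart_failure": 1,
    "peripheral_vascular_disease": 1,
    "cerebrovascular_disease": 1,
    "dementia": 1,
    "chronic_pulmonary_disease": 1,
    "rheumatologic_disease": 1,
    "peptic_ulcer_disease": 1,
    "mild_liver_disease": 1,
    "diabetes": 1,
    "hemiplegia": 2,
    "renal_disease": 2,
    "diabetes_with_complications": 2,
    "any_malignancy": 2,
    "leukemia": 2,
    "lymphoma": 2,
    "moderate_severe_liver_disease": 3,
    "metastatic_solid_tumor": 6,
    "aids": 6,
}

JOINT_TYPES: tuple[str, ...] = ("knee", "hip", "shoulder")

#: Cohort composition targets: share of cases and endpoint rate by joint type,
#: calibrated to the reference cohort composition (21,903 knee / 13,021 hip /
#: 3,657 shoulder of 38,581 cases; positives 4,025 / 1,938 / 457).
JOINT_MIX: dict[str, float] = {"knee": 21903 / 38581,
                               "hip": 13021 / 38581,
                               "shoulder": 3657 / 38581}
JOINT_ENDPOINT_RATE: dict[str, float] = {"knee": 4025 / 21903,
                                         "hip": 1938 / 13021,
                                         "shoulder": 457 / 3657}
TOTAL_ENDPOINT_RATE: float = 6420 / 38581


def feature_count() -> int:
    """Size of the full candidate design (generated + downstream features)."""
    return len(ALL_GENERATED_FEATURES) + len(DOWNSTREAM_FEATURES)
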
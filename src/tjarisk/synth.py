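"""Synthetic EHR cohort generator for total joint arthroplasty cases.

The generator emulates the statistical structure the downstream risk pipeline
assumes: a cohort of knee/hip/shoulder replacement cases with a combined
endpoint (30-day inpatient readmission, 30-day ED visit, or SNF/rehab
discharge) at ~16% prevalence, continuous features drawn through a Gaussian
copula so designated pairs (red blood cell count / hematocrit / hemoglobin;
maximum stay length / inpatient admissions) carry high rank correlation,
heavy missingness in designated labs, and additive sensitive-attribute
treatment effects (female, Medicare, Medicaid) planted on the probability
scale with counterfactual outcomes recorded for validation.

Case-level features are drawn first, then *materialized* into relational
tables (encounters, labs, medications, diagnoses, social history) dated so
that the feature builder's lookback windows recover exactly the drawn values.
Sibling cases of the same patient are spaced at least ``MIN_SIBLING_GAP_DAYS``
apart so their extraction windows never overlap.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from . import catalog
from .catalog import (
    CHARLSON_WEIGHTS,
    CONTINUOUS_FEATURES,
    JOINT_ENDPOINT_RATE,
    JOINT_MIX,
    JOINT_TYPES,
    FeatureSpec,
)

SPAN_START = pd.Timestamp("2015-01-01")
SPAN_END = pd.Timestamp("2021-12-31")
#: Minimum days between two surgeries of the same patient; chosen so that no
#: lookback window (max 2 years + decoy margin) of one case can contain rows
#: materialized for the sibling case.
MIN_SIBLING_GAP_DAYS = 1200

#: Planted additive risk effects on the probability scale (treatment-effect
#: semantics: toggling the flag moves the endpoint probability by this much).
DEFAULT_TREATMENT_EFFECTS = {"female": 0.0145, "medicare": 0.0327, "medicaid": 0.0308}

#: Default rank-correlation (Kendall tau) targets for the copula. Chosen so
#: the descriptive-statistics stage flags exactly these pairs (tau > 0.65) and
#: the collinearity stage sees hematocrit/hemoglobin (but not red blood cell
#: count) exceed the VIF threshold, mirroring the cohort the pipeline expects.
DEFAULT_COPULA_TAUS = (
    ("red_blood_cell", "hematocrit", 0.672),
    ("red_blood_cell", "hemoglobin", 0.672),
    ("hematocrit", "hemoglobin", 0.820),
    ("max_stay_length", "n_inpatient_admissions", 0.844),
)

PLANNED_GROUPERS = (
    "pregnancy_delivery",
    "breast_implantation",
    "artificial_prosthetic_limb",
    "organ_transplantation",
)

#: Coefficients of the base risk index (logit scale, standardized inputs).
#: BMI enters U-shaped (z^2 - 1): both high and low BMI raise risk.
RISK_COEF = {
    "age": 0.30,
    "bmi_u": 0.18,
    "charlson_score": 0.22,
    "n_ed_visits": 0.18,
    "relationship_status": -0.35,
    "note_latent": 0.30,
    "med_anticoagulant": 0.20,
    "dx_heart_disorder": 0.12,
}

_RISKY_TOKENS = (
    "pain swelling erythema drainage dyspnea confusion dizziness anemia "
    "infection fever wound dehiscence fall weakness anticoagulation dvt "
    "readmission hypoxia tachycardia edema nausea delirium hypotension"
).split()
_BENIGN_TOKENS = (
    "stable ambulating well healed afebrile routine followup improving "
    "tolerating independent intact baseline unremarkable normal controlled "
    "resolved therapy home discharge education compliant steady"
).split()
_FILLER_TOKENS = (
    "patient exam today continues reports denies plan assessment history "
    "review noted status seen clinic visit orthopedic knee hip shoulder "
    "surgery postop preop medication daily left right bilateral joint"
).split()
_NOTE_TYPES = ("progress", "nursing", "discharge_summary", "ed_note", "telephone")


@dataclass
class NotesConfig:
    """Knobs for the synthetic clinical-note corpus.

    Defaults emulate the note *availability* structure of the study cohort
    (≈76% of cases have notes, ≈23 notes per populated case) while keeping
    note lengths short enough for desk-scale runs; text length is a free
    scale parameter here, not a cohort-calibrated one.
    """

    p_has_notes: float = 29346 / 38581
    mean_notes_per_case: float = 23.0
    mean_tokens_per_note: float = 45.0
    signal_strength: float = 1.0
    duplicate_rate: float = 0.05
    stub_rate: float = 0.08
    special_run_rate: float = 0.10


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic cohort generator.

    ``base_prevalence`` is the target *overall* endpoint prevalence, planted
    sensitive effects included; the per-joint intercepts are calibrated at
    generation time so realized prevalence matches it in expectation.
    """

    n_cases: int = 38581
    joint_mix: dict[str, float] = field(default_factory=lambda: dict(JOINT_MIX))
    joint_endpoint_rate: dict[str, float] = field(
        default_factory=lambda: dict(JOINT_ENDPOINT_RATE))
    feature_moments: dict[str, tuple[float, float, float, float]] = field(
        default_factory=dict)  # overrides: name -> (mean, sd, min, max)
    copula_correlations: tuple[tuple[str, str, float], ...] = DEFAULT_COPULA_TAUS
    missingness_rates: dict[str, float] = field(default_factory=dict)  # overrides
    sensitive_prevalence: dict[str, float] = field(
        default_factory=lambda: {"female": 0.59, "medicare": 0.60, "medicaid": 0.10})
    #: Slope of Medicare on standardized age (logit scale). Nonzero by default
    #: so the propensity-matching audit faces genuine age confounding, mild
    #: enough that 1:1 matching without replacement can balance it.
    medicare_age_slope: float = 0.3
    treatment_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_EFFECTS))
    base_prevalence: float = catalog.TOTAL_ENDPOINT_RATE
    #: Multiplier on the risk-index logit spread: >1 makes the cohort easier
    #: to discriminate (stronger feature signal), prevalence is recalibrated.
    risk_logit_scale: float = 1.0
    notes: NotesConfig = field(default_factory=NotesConfig)
    #: Probability a positive case realizes each endpoint mechanism (redrawn
    #: until at least one applies; SNF unavailable when admitted from SNF).
    reason_probs: dict[str, float] = field(
        default_factory=lambda: {"inpatient_30d": 0.35, "ed_30d": 0.45,
                                 "snf_discharge": 0.45})
    admitted_from_snf_rate: float = 0.03
    #: Among negative admitted-from-SNF cases, share discharged back to SNF
    #: (exercises the endpoint rule's carve-out on default cohorts).
    snf_to_snf_rate: float = 0.5
    # Case-exclusion plants (default 0: the cohort is the analyzed cohort).
    fracture_rate: float = 0.0
    revision_rate: float = 0.0
    fatality_rate: float = 0.0
    planned_readmission_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if abs(sum(self.joint_mix.values()) - 1.0) > 1e-9:
            raise ValueError("joint_mix must sum to 1")
        rates = (
            list(self.missingness_rates.values())
            + list(self.sensitive_prevalence.values())
            + [self.base_prevalence, self.admitted_from_snf_rate,
               self.fracture_rate, self.revision_rate, self.fatality_rate,
               self.planned_readmission_rate]
        )
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("all rates and prevalences must lie in [0, 1]")
        if any(not np.isfinite(v) for v in self.treatment_effects.values()):
            raise ValueError("treatment_effects must be finite")


@dataclass
class CohortBundle:
    """Linked synthetic cohort tables plus generative ground truth."""

    cases: pd.DataFrame
    encounters: pd.DataFrame
    labs: pd.DataFrame
    meds: pd.DataFrame
    diagnoses: pd.DataFrame
    social: pd.DataFrame
    sensitive: pd.DataFrame
    truth: pd.DataFrame
    truth_features: pd.DataFrame
    notes: pd.DataFrame | None = None
    config: GeneratorConfig | None = None


# ---------------------------------------------------------------------------
# Marginal transforms
# ---------------------------------------------------------------------------

def _marginal_ppf(spec: FeatureSpec, z: np.ndarray,
                  moments: tuple[float, float, float, float]) -> np.ndarray:
    """Map standard-normal draws to the feature's marginal (monotone, so the
    copula's rank structure is preserved)."""
    mean, sd, vmin, vmax = moments
    if spec.marginal == "truncnorm":
        a, b = (vmin - mean) / sd, (vmax - mean) / sd
        u = stats.norm.cdf(z)
        return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)
    if spec.marginal == "lognorm":
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return np.clip(np.exp(mu + np.sqrt(sigma2) * z), vmin, vmax)
    if spec.marginal in ("nbinom", "charlson"):
        var = sd**2
        if var <= mean:  # fall back to Poisson when not overdispersed
            u = stats.norm.cdf(z)
            x = stats.poisson.ppf(u, mean)
        else:
            r = mean**2 / (var - mean)
            p = r / (r + mean)
            u = stats.norm.cdf(z)
            x = stats.nbinom.ppf(u, r, p)
        return np.clip(x, vmin, vmax)
    raise ValueError(f"unknown marginal kind {spec.marginal!r} for {spec.name}")


def _copula_matrix(config: GeneratorConfig) -> np.ndarray:
    names = list(catalog.CONTINUOUS_NAMES)
    idx = {n: i for i, n in enumerate(names)}
    r = np.eye(len(names))
    for f1, f2, tau in config.copula_correlations:
        rho = float(np.sin(np.pi * tau / 2.0))  # Greiner's relation
        i, j = idx[f1], idx[f2]
        r[i, j] = r[j, i] = rho
    eigmin = float(np.linalg.eigvalsh(r).min())
    if eigmin < -1e-10:
        raise ValueError(
            "copula correlation matrix is not positive semi-definite "
            f"(minimum eigenvalue {eigmin:.3e}); relax the requested "
            "rank-correlation targets")
    return r


# ---------------------------------------------------------------------------
# Outcome planting
# ---------------------------------------------------------------------------

def plant_outcomes(base_risk: np.ndarray, sensitive: pd.DataFrame,
                   effects: dict[str, float], seed) -> pd.DataFrame:
    """Draw endpoint labels with additive sensitive-attribute effects.

    The outcome is Bernoulli(clip(base_risk + Σ effect_a · flag_a, 0, 1)).
    For each sensitive attribute both counterfactual labels (flag forced to
    0 and to 1) are drawn with *common random numbers*, so the realized
    counterfactual contrast estimates the planted effect without extra
    Monte-Carlo noise from the Bernoulli draw.

    Returns a frame with columns ``risk``, ``y`` and, per attribute ``a``,
    ``y_cf_{a}0`` / ``y_cf_{a}1``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base_risk = np.asarray(base_risk, dtype=float)
    n = base_risk.shape[0]
    flags = {a: sensitive[a].to_numpy(dtype=float) for a in effects}
    bump = sum(effects[a] * flags[a] for a in effects)
    p = base_risk + bump
    n_clipped = int(np.sum((p < 0) | (p > 1)))
    if n_clipped > 0.01 * n:
        warnings.warn(
            f"{n_clipped}/{n} risks fell outside [0, 1] before clipping; "
            "the generator configuration is mis-calibrated", stacklevel=2)
    p = np.clip(p, 0.0, 1.0)
    u = rng.uniform(size=n)
    out = {"risk": p, "y": (u < p).astype(np.int8)}
    for a, eff in effects.items():
        others = bump - eff * flags[a]
        p0 = np.clip(base_risk + others, 0.0, 1.0)
        p1 = np.clip(base_risk + others + eff, 0.0, 1.0)
        out[f"y_cf_{a}0"] = (u < p0).astype(np.int8)
        out[f"y_cf_{a}1"] = (u < p1).astype(np.int8)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _draw_case_skeleton(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Case/patient ids, joint types and the date backbone."""
    n = config.n_cases
    # ~1.19 cases per patient as in the study cohort (38,581 cases for
    # 32,405 patients); patients have at most two cases here.
    n_patients = max(1, int(round(n / 1.1906)))
    n_second = n - n_patients
    patient_idx = np.arange(n_patients)
    second_owners = rng.choice(patient_idx, size=n_second, replace=False) \
        if n_second > 0 else np.array([], dtype=int)

    span_days = (SPAN_END - SPAN_START).days
    first_surgery = rng.integers(0, span_days - MIN_SIBLING_GAP_DAYS - 30,
                                 size=n_patients)
    rows = []
    for pi in patient_idx:
        rows.append((pi, int(first_surgery[pi]), 0))
    for pi in second_owners:
        lo = int(first_surgery[pi]) + MIN_SIBLING_GAP_DAYS
        surgery = int(rng.integers(lo, span_days + 1))
        rows.append((pi, surgery, 1))
    df = pd.DataFrame(rows, columns=["patient_idx", "surgery_offset", "case_seq"])
    df = df.sort_values(["patient_idx", "case_seq"], kind="stable").reset_index(drop=True)

    df["case_id"] = [f"C{i:06d}" for i in range(len(df))]
    df["patient_id"] = df["patient_idx"].map(lambda i: f"P{i:06d}")
    df["joint_type"] = rng.choice(
        JOINT_TYPES, size=len(df),
        p=[config.joint_mix[j] for j in JOINT_TYPES])
    df["surgery_date"] = SPAN_START + pd.to_timedelta(df["surgery_offset"], unit="D")
    creation_lead = rng.integers(14, 91, size=len(df))
    df["case_creation_date"] = df["surgery_date"] - pd.to_timedelta(creation_lead, unit="D")
    los = rng.integers(1, 5, size=len(df))
    df["discharge_date"] = df["surgery_date"] + pd.to_timedelta(los, unit="D")
    df["admitted_from_snf"] = (rng.uniform(size=len(df))
                               < config.admitted_from_snf_rate).astype(np.int8)
    df["pre_existing_fracture"] = (rng.uniform(size=len(df))
                                   < config.fracture_rate).astype(np.int8)
    df["revision_or_partial"] = (rng.uniform(size=len(df))
                                 < config.revision_rate).astype(np.int8)
    df["intraop_fatality"] = (rng.uniform(size=len(df))
                              < config.fatality_rate).astype(np.int8)
    return df


def _draw_features(config: GeneratorConfig, n: int,
                   rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent (pre-missingness) continuous + binary case-level features."""
    r = _copula_matrix(config)
    chol = np.linalg.cholesky(r + 1e-12 * np.eye(r.shape[0]))
    z = rng.standard_normal(size=(n, r.shape[0])) @ chol.T

    cont = {}
    for j, spec in enumerate(CONTINUOUS_FEATURES):
        moments = config.feature_moments.get(
            spec.name, (spec.mean, spec.sd, spec.vmin, spec.vmax))
        cont[spec.name] = _marginal_ppf(spec, z[:, j], moments)
    cont_df = pd.DataFrame(cont)

    binary = {}
    for spec in catalog.DIAGNOSIS_FEATURES + catalog.MEDICATION_FEATURES + \
            catalog.SOCIAL_FEATURES:
        binary[spec.name] = (rng.uniform(size=n) < spec.prevalence).astype(np.int8)
    # Chief-complaint flags are conditional on having at least one ED visit.
    has_ed = (cont_df["n_ed_visits"].to_numpy() >= 1)
    for spec in catalog.CHIEF_COMPLAINT_FEATURES:
        binary[spec.name] = ((rng.uniform(size=n) < spec.prevalence) & has_ed).astype(np.int8)
    return cont_df, pd.DataFrame(binary)


def _draw_sensitive(config: GeneratorConfig, age: np.ndarray,
                    rng: np.random.Generator) -> pd.DataFrame:
    prev = config.sensitive_prevalence
    n = age.shape[0]
    female = (rng.uniform(size=n) < prev["female"]).astype(np.int8)
    medicaid = (rng.uniform(size=n) < prev["medicaid"]).astype(np.int8)
    age_spec = catalog.FEATURE_INDEX["age"]
    z_age = (age - age_spec.mean) / age_spec.sd
    slope = config.medicare_age_slope
    if slope == 0.0:
        medicare = (rng.uniform(size=n) < prev["medicare"]).astype(np.int8)
    else:
        # Calibrate the intercept so the marginal matches the target share.
        lo, hi = -10.0, 10.0
        for _ in range(60):
            mid = (lo + hi) / 2.0
            if expit(mid + slope * z_age).mean() < prev["medicare"]:
                lo = mid
            else:
                hi = mid
        medicare = (rng.uniform(size=n) < expit((lo + hi) / 2 + slope * z_age)).astype(np.int8)
    return pd.DataFrame({"female": female, "medicare": medicare, "medicaid": medicaid})


def _base_risk(config: GeneratorConfig, cont: pd.DataFrame, binary: pd.DataFrame,
               joint_type: np.ndarray, note_latent: np.ndarray,
               sensitive: pd.DataFrame) -> np.ndarray:
    """Calibrated base endpoint probability (before sensitive-effect bumps).

    Per-joint intercepts are solved by bisection so each joint type hits its
    target endpoint rate *including* the planted effects, which makes the
    overall prevalence match ``base_prevalence`` in expectation.
    """
    def zf(name):
        spec = catalog.FEATURE_INDEX[name]
        return (cont[name].to_numpy() - spec.mean) / spec.sd

    eta = (RISK_COEF["age"] * zf("age")
           + RISK_COEF["bmi_u"] * (zf("bmi") ** 2 - 1.0)
           + RISK_COEF["charlson_score"] * zf("charlson_score")
           + RISK_COEF["n_ed_visits"] * zf("n_ed_visits")
           + RISK_COEF["relationship_status"] * binary["relationship_status"].to_numpy()
           + RISK_COEF["note_latent"] * note_latent
           + RISK_COEF["med_anticoagulant"] * binary["med_anticoagulant"].to_numpy()
           + RISK_COEF["dx_heart_disorder"] * binary["dx_heart_disorder"].to_numpy())
    eta = eta * config.risk_logit_scale

    effects = config.treatment_effects
    bump = sum(effects.get(a, 0.0) * sensitive[a].to_numpy(dtype=float)
               for a in sensitive.columns)
    # Rescale per-joint targets so the overall rate equals base_prevalence
    # even when the user overrides it away from the joint-table default.
    default_total = sum(config.joint_mix[j] * config.joint_endpoint_rate[j]
                        for j in JOINT_TYPES)
    scale = config.base_prevalence / default_total if default_total > 0 else 1.0
    base = np.empty_like(eta)
    for j in JOINT_TYPES:
        mask = joint_type == j
        if not mask.any():
            continue
        target = np.clip(config.joint_endpoint_rate[j] * scale, 1e-6, 1 - 1e-6)
        lo, hi = -12.0, 12.0
        for _ in range(60):
            mid = (lo + hi) / 2.0
            mean_p = np.clip(expit(eta[mask] + mid) + bump[mask], 0.0, 1.0).mean()
            if mean_p < target:
                lo = mid
            else:
                hi = mid
        base[mask] = expit(eta[mask] + (lo + hi) / 2.0)
    return base


def generate_cohort(config: GeneratorConfig | None = None, *,
                    include_notes: bool = True) -> CohortBundle:
    """Generate a seeded synthetic cohort bundle.

    Reproducible: identical config + seed yields an identical bundle.
    """
    config = config or GeneratorConfig()
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
    r_skel, r_feat, r_sens, r_out, r_mat, r_notes = rngs

    cases = _draw_case_skeleton(config, r_skel)
    n = len(cases)
    cont, binary = _draw_features(config, n, r_feat)

    # Anchor ages: each patient's birth date is set from one randomly chosen
    # case (so the case-level age marginal stays centred); sibling-case ages
    # are then derived from the shared birth date.
    creation = cases["case_creation_date"]
    anchor = np.ones(n, dtype=bool)
    multi_idx = cases.index[cases.duplicated("patient_id", keep=False)]
    if len(multi_idx):
        grouped = cases.loc[multi_idx].groupby("patient_id", sort=True).groups
        for pid_key in grouped:
            idxs = list(grouped[pid_key])
            keep = idxs[int(r_skel.integers(0, len(idxs)))]
            for i in idxs:
                anchor[i] = (i == keep)
    anchor_rows = np.flatnonzero(anchor)
    birth_dates = (creation.iloc[anchor_rows]
                   - pd.to_timedelta(cont["age"].to_numpy()[anchor_rows] * 365.25,
                                     unit="D"))
    birth = pd.Series(birth_dates.to_numpy(),
                      index=cases["patient_id"].to_numpy()[anchor_rows])
    birth_per_case = cases["patient_id"].map(birth)
    cont["age"] = ((creation - birth_per_case) / np.timedelta64(1, "D")) / 365.25

    sensitive_cases = _draw_sensitive(config, cont["age"].to_numpy(), r_sens)
    # Sensitive attributes are per patient: the first case's draw wins.
    # Harmonize BEFORE risk planting so every case's outcome reflects the
    # flags the analysis will see.
    sens = pd.concat([cases[["patient_id", "case_id"]], sensitive_cases], axis=1)
    first = sens.drop_duplicates("patient_id", keep="first")
    per_patient = first.set_index("patient_id")[["female", "medicare", "medicaid"]]
    for col in ("female", "medicare", "medicaid"):
        sensitive_cases[col] = cases["patient_id"].map(per_patient[col]).astype(np.int8)
    sensitive = per_patient.reset_index()
    sensitive["birth_date"] = sensitive["patient_id"].map(birth)

    note_latent = r_out.standard_normal(n)
    base = _base_risk(config, cont, binary, cases["joint_type"].to_numpy(),
                      note_latent, sensitive_cases)
    truth = plant_outcomes(base, sensitive_cases, config.treatment_effects, r_out)
    truth.insert(0, "case_id", cases["case_id"].to_numpy())
    truth["base_risk"] = base
    truth["note_latent"] = note_latent

    # Endpoint mechanism assignment.
    y = truth["y"].to_numpy()
    reasons = _assign_reasons(config, y, cases["admitted_from_snf"].to_numpy(), r_out)
    cases["discharge_disposition"] = np.where(reasons["snf_discharge"], "snf_rehab", "home")
    neg_from_snf = (y == 0) & (cases["admitted_from_snf"].to_numpy() == 1)
    snf_back = neg_from_snf & (r_out.uniform(size=n) < config.snf_to_snf_rate)
    cases.loc[snf_back, "discharge_disposition"] = "snf_rehab"
    planned = (r_out.uniform(size=n) < config.planned_readmission_rate) & (y == 0)

    encounters = _materialize_encounters(cases, cont, binary, reasons, planned, r_mat)
    labs = _materialize_labs(cases, cont, config, r_mat)
    diagnoses = _materialize_diagnoses(cases, cont, binary, r_mat)
    meds = _materialize_meds(cases, binary, r_mat)
    social = _materialize_social(cases, cont, binary, config, r_mat)

    truth_features = _truth_feature_matrix(cases, cont, binary, sensitive_cases, config)

    notes = None
    if include_notes:
        notes = generate_notes(cases, truth, r_notes, config.notes)

    cases = cases.drop(columns=["patient_idx", "surgery_offset", "case_seq"])
    return CohortBundle(cases=cases, encounters=encounters, labs=labs, meds=meds,
                        diagnoses=diagnoses, social=social, sensitive=sensitive,
                        truth=truth, truth_features=truth_features, notes=notes,
                        config=config)


def _assign_reasons(config: GeneratorConfig, y: np.ndarray, from_snf: np.ndarray,
                    rng: np.random.Generator) -> pd.DataFrame:
    n = y.shape[0]
    out = {k: np.zeros(n, dtype=bool) for k in
           ("inpatient_30d", "ed_30d", "snf_discharge")}
    probs = config.reason_probs
    pos = np.flatnonzero(y == 1)
    for i in pos:
        allowed = ["inpatient_30d", "ed_30d"]
        if not from_snf[i]:
            allowed.append("snf_discharge")
        picked = [k for k in allowed if rng.uniform() < probs[k]]
        if not picked:
            picked = [allowed[int(rng.integers(0, len(allowed)))]]
        for k in picked:
            out[k][i] = True
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Table materialization
# ---------------------------------------------------------------------------

def _materialize_encounters(cases, cont, binary, reasons, planned, rng):
    rows = []  # (patient_id, type, admit_offset_from_creation, los, cc, grouper, anchor)
    creation = cases["case_creation_date"]
    discharge = cases["discharge_date"]
    pid = cases["patient_id"].to_numpy()

    n = len(cases)
    k_ed = cont["n_ed_visits"].to_numpy().astype(int)
    k_ip = cont["n_inpatient_admissions"].to_numpy().astype(int)
    k_of = cont["n_office_visits"].to_numpy().astype(int)
    k_ns = cont["n_no_show_appts"].to_numpy().astype(int)
    k_ca = cont["n_cancelled_appts"].to_numpy().astype(int)
    k_su = cont["n_surgeries"].to_numpy().astype(int)
    max_stay = cont["max_stay_length"].to_numpy().astype(int)

    cc_flags = {
        "abdominal_pain": binary["cc_abdominal_pain"].to_numpy().astype(bool),
        "chest_pain": binary["cc_chest_pain"].to_numpy().astype(bool),
        "shortness_of_breath": binary["cc_shortness_of_breath"].to_numpy().astype(bool),
    }

    records: list[tuple] = []
    for i in range(n):
        c = creation.iloc[i]
        d = discharge.iloc[i]
        p = pid[i]
        # Pre-operative utilization (offsets are days *before* case creation).
        if k_ed[i] > 0:
            offs = rng.integers(1, catalog.DAYS_ED + 1, size=k_ed[i])
            ccs = ["none"] * k_ed[i]
            slot = 0
            for name, flag in cc_flags.items():
                if flag[i]:
                    if slot < k_ed[i]:
                        ccs[slot] = name
                    else:
                        # more complaint flags than ED visits: drop the flag
                        binary.loc[i, f"cc_{name}"] = 0
                    slot += 1
            for o, cc in zip(offs, ccs):
                records.append((p, "ED", c - pd.Timedelta(int(o), "D"), 0, cc, ""))
        if k_ip[i] > 0:
            offs = rng.integers(1, catalog.DAYS_INPATIENT + 1, size=k_ip[i])
            for jdx, o in enumerate(offs):
                los = max_stay[i] if jdx == 0 else int(rng.integers(0, max_stay[i] + 1))
                records.append((p, "inpatient", c - pd.Timedelta(int(o), "D"),
                                los, "none", ""))
        elif max_stay[i] > 0:
            # The stay defining max length sits in the 2-year window but
            # outside the 1-year admission-count window.
            o = int(rng.integers(catalog.DAYS_INPATIENT + 1, catalog.DAYS_MAX_STAY + 1))
            records.append((p, "inpatient", c - pd.Timedelta(o, "D"),
                            max_stay[i], "none", ""))
        for kind, k, win in (("office", k_of[i], catalog.DAYS_APPT),
                             ("no_show", k_ns[i], catalog.DAYS_APPT),
                             ("cancelled", k_ca[i], catalog.DAYS_APPT),
                             ("surgery", k_su[i], catalog.DAYS_SURGERY_HISTORY)):
            if k > 0:
                for o in rng.integers(1, win + 1, size=k):
                    records.append((p, kind, c - pd.Timedelta(int(o), "D"),
                                    0, "none", ""))
        # Post-discharge endpoint mechanisms (offsets days after discharge,
        # inclusive 0..30 window).
        if reasons["inpatient_30d"].iloc[i]:
            o = int(rng.integers(0, 31))
            records.append((p, "inpatient", d + pd.Timedelta(o, "D"),
                            int(rng.integers(1, 6)), "none", ""))
        if reasons["ed_30d"].iloc[i]:
            o = int(rng.integers(0, 31))
            records.append((p, "ED", d + pd.Timedelta(o, "D"), 0, "none", ""))
        if planned[i]:
            o = int(rng.integers(0, 31))
            g = PLANNED_GROUPERS[int(rng.integers(0, len(PLANNED_GROUPERS)))]
            records.append((p, "inpatient", d + pd.Timedelta(o, "D"),
                            int(rng.integers(1, 4)), "none", g))
        # Non-qualifying noise after the 30-day window.
        if rng.uniform() < 0.10:
            o = int(rng.integers(31, 61))
            kind = "ED" if rng.uniform() < 0.5 else "office"
            records.append((p, kind, d + pd.Timedelta(o, "D"), 0, "none", ""))

    enc = pd.DataFrame(records, columns=[
        "patient_id", "encounter_type", "admit_date", "length_of_stay",
        "chief_complaint", "planned_grouper"])
    enc.insert(0, "encounter_id", [f"E{i:07d}" for i in range(len(enc))])
    return enc


def _materialize_labs(cases, cont, config, rng):
    creation = cases["case_creation_date"].to_numpy()
    pid = cases["patient_id"].to_numpy()
    n = len(cases)
    frames = []
    lab_specs = [s for s in CONTINUOUS_FEATURES if s.family == "lab"]
    lab_specs.append(catalog.FEATURE_INDEX["bmi"])  # stored like a flowsheet lab
    for spec in lab_specs:
        miss = config.missingness_rates.get(spec.name, spec.missing_rate)
        observed = rng.uniform(size=n) >= miss
        cont.loc[~observed, spec.name] = np.nan
        idx = np.flatnonzero(observed)
        if idx.size == 0:
            continue
        main_off = rng.integers(0, 6, size=idx.size)
        frames.append(pd.DataFrame({
            "patient_id": pid[idx],
            "lab_name": spec.name,
            "value": cont[spec.name].to_numpy()[idx],
            "collect_date": creation[idx] - main_off * np.timedelta64(1, "D"),
        }))
        # Older in-window values (superseded by the most recent draw) and
        # decoys just outside the 2-year window exercise the builder's
        # recency and boundary logic.
        older = idx[rng.uniform(size=idx.size) < 0.10]
        if older.size:
            off = rng.integers(7, catalog.DAYS_LAB, size=older.size)
            frames.append(pd.DataFrame({
                "patient_id": pid[older],
                "lab_name": spec.name,
                "value": cont[spec.name].to_numpy()[older]
                * rng.uniform(0.9, 1.1, size=older.size),
                "collect_date": creation[older] - off * np.timedelta64(1, "D"),
            }))
        outside = idx[rng.uniform(size=idx.size) < 0.10]
        if outside.size:
            off = rng.integers(catalog.DAYS_LAB + 1, catalog.DAYS_LAB + 70,
                               size=outside.size)
            frames.append(pd.DataFrame({
                "patient_id": pid[outside],
                "lab_name": spec.name,
                "value": cont[spec.name].to_numpy()[outside]
                * rng.uniform(0.8, 1.2, size=outside.size),
                "collect_date": creation[outside] - off * np.timedelta64(1, "D"),
            }))
    labs = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["patient_id", "lab_name", "value", "collect_date"])
    return labs


def _decompose_charlson(score: int, rng: np.random.Generator) -> list[str]:
    """Random distinct-category decomposition of a Charlson score (≤ 21)."""
    by_weight: dict[int, list[str]] = {1: [], 2: [], 3: [], 6: []}
    for cat, w in CHARLSON_WEIGHTS.items():
        by_weight[w].append(cat)
    picked = []
    rem = int(score)
    for w in (6, 3, 2, 1):
        pool = by_weight[w]
        take = min(rem // w, len(pool))
        if take > 0:
            chosen = rng.choice(len(pool), size=take, replace=False)
            picked.extend(pool[int(c)] for c in chosen)
            rem -= take * w
    if rem != 0:  # cannot happen for scores in [0, 21]
        raise ValueError(f"cannot decompose Charlson score {score}")
    return picked


def _materialize_diagnoses(cases, cont, binary, rng):
    creation = cases["case_creation_date"].to_numpy()
    pid = cases["patient_id"].to_numpy()
    frames = []
    for spec in catalog.DIAGNOSIS_FEATURES:
        idx = np.flatnonzero(binary[spec.name].to_numpy().astype(bool))
        if idx.size == 0:
            continue
        offs = rng.integers(0, catalog.DAYS_DIAGNOSIS, size=idx.size)
        frames.append(pd.DataFrame({
            "patient_id": pid[idx], "category": spec.name, "charlson_weight": 0,
            "dx_date": creation[idx] - offs * np.timedelta64(1, "D")}))
        dup = idx[rng.uniform(size=idx.size) < 0.05]  # duplicate records
        if dup.size:
            offs = rng.integers(0, catalog.DAYS_DIAGNOSIS, size=dup.size)
            frames.append(pd.DataFrame({
                "patient_id": pid[dup], "category": spec.name, "charlson_weight": 0,
                "dx_date": creation[dup] - offs * np.timedelta64(1, "D")}))
    records = []
    scores = cont["charlson_score"].to_numpy().astype(int)
    for i in np.flatnonzero(scores > 0):
        for cat in _decompose_charlson(scores[i], rng):
            o = int(rng.integers(0, catalog.DAYS_DIAGNOSIS))
            records.append((pid[i], f"charlson:{cat}", CHARLSON_WEIGHTS[cat],
                            creation[i] - np.timedelta64(o, "D")))
    if records:
        frames.append(pd.DataFrame(records, columns=[
            "patient_id", "category", "charlson_weight", "dx_date"]))
    if not frames:
        return pd.DataFrame(columns=["patient_id", "category",
                                     "charlson_weight", "dx_date"])
    return pd.concat(frames, ignore_index=True)


def _materialize_meds(cases, binary, rng):
    creation = cases["case_creation_date"].to_numpy()
    pid = cases["patient_id"].to_numpy()
    n = len(cases)
    records = []
    for spec in catalog.MEDICATION_FEATURES:
        flags = binary[spec.name].to_numpy().astype(bool)
        idx = np.flatnonzero(flags)
        offs = rng.integers(0, catalog.DAYS_MEDICATION, size=idx.size)
        for i, o in zip(idx, offs):
            records.append((pid[i], spec.name, creation[i] - np.timedelta64(int(o), "D")))
        # Decoy old orders outside the 90-day window for a sample of the
        # cases that do NOT carry the class.
        off_idx = np.flatnonzero(~flags)
        decoy = off_idx[rng.uniform(size=off_idx.size) < 0.03]
        offs = rng.integers(catalog.DAYS_MEDICATION + 1, catalog.DAYS_MEDICATION + 200,
                            size=decoy.size)
        for i, o in zip(decoy, offs):
            records.append((pid[i], spec.name, creation[i] - np.timedelta64(int(o), "D")))
    return pd.DataFrame(records, columns=["patient_id", "med_class", "order_date"])


def _materialize_social(cases, cont, binary, config, rng):
    creation = cases["case_creation_date"].to_numpy()
    pid = cases["patient_id"].to_numpy()
    n = len(cases)
    frames = []
    flag_items = ("tobacco_use", "alcohol_use", "illegal_drug_use",
                  "relationship_status", "has_pcp")
    for item in flag_items:
        offs = rng.integers(0, 301, size=n)
        frames.append(pd.DataFrame({
            "patient_id": pid, "item": item,
            "value": binary[item].to_numpy().astype(float),
            "recorded_date": creation - offs * np.timedelta64(1, "D")}))
    # Flowsheet-style fall items carry their own missingness.
    for item in ("fall_risk", "fall_history"):
        spec = catalog.FEATURE_INDEX[item]
        miss = config.missingness_rates.get(item, spec.missing_rate)
        observed = rng.uniform(size=n) >= miss
        if item == "fall_risk":
            cont.loc[~observed, item] = np.nan
            vals = cont[item].to_numpy()
        else:
            raw = binary[item].to_numpy().astype(float).copy()
            raw[~observed] = np.nan
            binary[item] = raw  # becomes float with NaN for missing
            vals = raw
        idx = np.flatnonzero(observed)
        offs = rng.integers(0, 301, size=idx.size)
        frames.append(pd.DataFrame({
            "patient_id": pid[idx], "item": item, "value": vals[idx],
            "recorded_date": creation[idx] - offs * np.timedelta64(1, "D")}))
    return pd.concat(frames, ignore_index=True)


def _truth_feature_matrix(cases, cont, binary, sensitive_cases, config):
    """The case-level feature matrix the feature builder should recover."""
    out = pd.DataFrame({"case_id": cases["case_id"].to_numpy()})
    for name in catalog.CONTINUOUS_NAMES:
        out[name] = cont[name].to_numpy()
    for spec in (catalog.DIAGNOSIS_FEATURES + catalog.MEDICATION_FEATURES
                 + catalog.SOCIAL_FEATURES + catalog.CHIEF_COMPLAINT_FEATURES):
        out[spec.name] = binary[spec.name].to_numpy()
    for col in ("female", "medicare", "medicaid"):
        out[col] = sensitive_cases[col].to_numpy()
    return out


# ---------------------------------------------------------------------------
# Notes
# ---------------------------------------------------------------------------

def generate_notes(cases: pd.DataFrame, truth: pd.DataFrame,
                   seed, notes_config: NotesConfig | None = None) -> pd.DataFrame:
    """Synthesize per-case clinical notes carrying a noisy risk signal.

    Token composition encodes the case's true risk (risky vs. benign token
    mix), so a bag-of-words chunk scorer is learnable; with
    ``signal_strength=0`` the corpus is pure noise and a downstream scorer
    cannot beat chance. Planted artifacts: exact duplicate notes, sub-200
    character stubs, and runs of ``=``/``_``/``-`` for the preprocessing
    stage to remove.
    """
    cfg = notes_config or NotesConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    risk = truth["risk"].to_numpy()
    rz = (logit(np.clip(risk, 1e-6, 1 - 1e-6))
          - logit(np.clip(risk, 1e-6, 1 - 1e-6)).mean())
    sd = rz.std() or 1.0
    rz = rz / sd

    has_notes = rng.uniform(size=len(cases)) < cfg.p_has_notes
    records = []
    specials = ("=" * 8, "_" * 10, "-" * 12)
    for i in np.flatnonzero(has_notes):
        cid = cases["case_id"].iloc[i]
        creation = cases["case_creation_date"].iloc[i]
        n_notes = 1 + rng.poisson(max(cfg.mean_notes_per_case - 1.0, 0.0))
        p_risky = expit(-0.8 + cfg.signal_strength * (rz[i] + 0.5 * rng.standard_normal()))
        texts: list[str] = []
        for _ in range(n_notes):
            if texts and rng.uniform() < cfg.duplicate_rate:
                text = texts[int(rng.integers(0, len(texts)))]
            elif rng.uniform() < cfg.stub_rate:
                k = int(rng.integers(3, 8))
                text = " ".join(rng.choice(_FILLER_TOKENS, size=k))
            else:
                k = max(8, int(rng.poisson(cfg.mean_tokens_per_note)))
                roles = rng.uniform(size=k)
                signal = rng.uniform(size=k) < p_risky
                toks = np.where(
                    roles < 0.5,
                    rng.choice(_FILLER_TOKENS, size=k),
                    np.where(signal, rng.choice(_RISKY_TOKENS, size=k),
                             rng.choice(_BENIGN_TOKENS, size=k)))
                if rng.uniform() < cfg.special_run_rate:
                    pos = int(rng.integers(0, k))
                    toks = np.insert(toks, pos, specials[int(rng.integers(0, 3))])
                text = " ".join(toks)
            texts.append(text)
            dt = creation - pd.Timedelta(int(rng.integers(0, catalog.DAYS_NOTES + 1)), "D")
            records.append((cid, dt, _NOTE_TYPES[int(rng.integers(0, len(_NOTE_TYPES)))],
                            text))
    return pd.DataFrame(records, columns=["case_id", "datetime", "note_type", "text"])


# ---------------------------------------------------------------------------
# Bundle I/O (RFC-4180 CSV, ISO-8601 dates, UTF-8; notes as JSONL)
# ---------------------------------------------------------------------------

_TABLES = ("cases", "encounters", "labs", "meds", "diagnoses", "social",
           "sensitive", "truth", "truth_features")


def write_bundle(bundle: CohortBundle, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        getattr(bundle, name).to_csv(out / f"{name}.csv", index=False)
    if bundle.notes is not None:
        with open(out / "notes.jsonl", "w", encoding="utf-8") as fh:
            for rec in bundle.notes.itertuples(index=False):
                fh.write(json.dumps({
                    "case_id": rec.case_id,
                    "datetime": pd.Timestamp(rec.datetime).isoformat(),
                    "note_type": rec.note_type,
                    "text": rec.text,
                }) + "\n")
    return out


_DATE_COLS = {
    "cases": ["case_creation_date", "surgery_date", "discharge_date"],
    "encounters": ["admit_date"],
    "labs": ["collect_date"],
    "diagnoses": ["dx_date"],
    "meds": ["order_date"],
    "social": ["recorded_date"],
    "sensitive": ["birth_date"],
}


def read_bundle(in_dir: str | Path) -> CohortBundle:
    src = Path(in_dir)
    frames = {}
    for name in _TABLES:
        df = pd.read_csv(src / f"{name}.csv")
        for col in _DATE_COLS.get(name, []):
            if col in df.columns:
                df[col] = pd.to_datetime(df[col])
        frames[name] = df
    notes = None
    notes_path = src / "notes.jsonl"
    if notes_path.exists():
        recs = [json.loads(line) for line in
                notes_path.read_text(encoding="utf-8").splitlines() if line]
        notes = pd.DataFrame(recs)
        if len(notes):
            notes["datetime"] = pd.to_datetime(notes["datetime"])
    return CohortBundle(notes=notes, **frames)
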
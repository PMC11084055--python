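import numpy as np
import pandas as pd
import pytest

from tjarisk import GeneratorConfig, NotesConfig, generate_cohort


@pytest.fixture(scope="session")
def small_bundle():
    """Compact default-conditions cohort, notes disabled (fast round trips)."""
    cfg = GeneratorConfig(n_cases=1500, seed=3)
    return generate_cohort(cfg, include_notes=False)


@pytest.fixture(scope="session")
def medium_truth():
    """Truth feature matrix at n=10,000 for rank-correlation checks."""
    cfg = GeneratorConfig(n_cases=10_000, seed=21)
    bundle = generate_cohort(cfg, include_notes=False)
    return bundle.truth_features.set_index("case_id"), bundle.truth


@pytest.fixture(scope="session")
def noted_bundle():
    """Small cohort with notes enabled (short corpus for speed)."""
    cfg = GeneratorConfig(
        n_cases=1200, seed=9,
        notes=NotesConfig(mean_notes_per_case=6, mean_tokens_per_note=40))
    return generate_cohort(cfg, include_notes=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def toy_cases(rows):
    """Helper: build a cases frame from dicts with sensible defaults."""
    defaults = {
        "patient_id": "P0", "joint_type": "knee",
        "case_creation_date": pd.Timestamp("2018-01-01"),
        "surgery_date": pd.Timestamp("2018-02-01"),
        "discharge_date": pd.Timestamp("2018-02-03"),
        "discharge_disposition": "home", "admitted_from_snf": 0,
        "pre_existing_fracture": 0, "revision_or_partial": 0,
        "intraop_fatality": 0,
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["case_id"] = row.get("case_id", f"C{i}")
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)


def toy_encounters(rows):
    defaults = {"patient_id": "P0", "encounter_type": "ED",
                "admit_date": pd.Timestamp("2018-02-10"), "length_of_stay": 0,
                "chief_complaint": "none", "planned_grouper": ""}
    if not rows:
        return pd.DataFrame(columns=["encounter_id", *defaults]).astype(
            {"admit_date": "datetime64[ns]"})
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["encounter_id"] = row.get("encounter_id", f"E{i}")
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)
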
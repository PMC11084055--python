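"""Label the combined endpoint (30-day readmission / ED visit / SNF
discharge) and summarize the labeling reasons."""

from tjarisk import GeneratorConfig, generate_cohort, label_cohort

bundle = generate_cohort(GeneratorConfig(n_cases=5000, seed=2),
                         include_notes=False)
labels = label_cohort(bundle.cases, bundle.encounters)

n = labels["label"].notna().sum()
pos = labels["label"].astype("float").sum()
print(f"labeled cases: {n}, positives: {int(pos)} ({100 * pos / n:.1f}%)")
for reason in ("inpatient_30d", "ed_30d", "snf_discharge"):
    print(f"  {reason:<14}: {int(labels[reason].sum())}")
# A case can carry several reasons at once; the label is their union.
# SNF-to-SNF discharges (patient admitted from a SNF) never count.

agree = (labels.set_index("case_id")["label"].astype(float)
         == bundle.truth.set_index("case_id")["y"]).mean()
print(f"agreement with generator ground truth: {agree:.3f}")
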
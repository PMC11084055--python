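"""Generate a synthetic joint-replacement cohort and inspect its calibration.

The generator plants the cohort structure the risk pipeline assumes:
~16% combined-endpoint prevalence, continuous-feature moments matching the
published cohort table, high rank correlation among the blood-count labs,
and additive risk effects for female/Medicare/Medicaid patients.
"""

from scipy.stats import kendalltau

from tjarisk import GeneratorConfig, generate_cohort

bundle = generate_cohort(GeneratorConfig(n_cases=8000, seed=1),
                         include_notes=False)
truth = bundle.truth
features = bundle.truth_features

print(f"cases generated:        {len(bundle.cases)}")
print(f"endpoint prevalence:    {truth['y'].mean():.3f}   (target ~0.166)")
print(f"mean age (SD):          {features['age'].mean():.2f} "
      f"({features['age'].std():.2f})   (target 66.54 (10.09))")
print(f"female share:           {features['female'].mean():.3f} (target 0.59)")
print(f"Medicare share:         {features['medicare'].mean():.3f} (target 0.60)")

sub = features[["red_blood_cell", "hematocrit"]].dropna()
tau = kendalltau(sub["red_blood_cell"], sub["hematocrit"]).statistic
print(f"tau(RBC, hematocrit):   {tau:.3f}   (planted > 0.65)")

for attr in ("female", "medicare", "medicaid"):
    ate = (truth[f"y_cf_{attr}1"] - truth[f"y_cf_{attr}0"]).mean()
    print(f"true counterfactual ATE, {attr}: {ate:.4f}")
# The counterfactual ATEs are the ground-truth causal effects of each
# sensitive attribute; the bias audit (example 07) must recover them from
# observational matching alone.
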
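# Methods

This note documents the models, procedures and design choices behind
`tjarisk`, in the order the pipeline runs them. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Synthetic cohort generator

The generator (`tjarisk.synth`) is not a fixture factory: it is the
package's study population, and its defaults *are* the study conditions the
analysis assumes.

**Composition.** 38,581 surgical cases over 2015–2021 for ~32,400 patients
(≈1.19 cases per patient, at most two per patient here), split
knee/hip/shoulder at 56.8/33.7/9.5% with per-joint endpoint rates
18.4/14.9/12.5% (overall 16.6%). Sibling cases of the same patient are at
least 1,200 days apart, which makes every lookback window (max 2 years, plus
a small decoy margin) and the 30-day outcome window provably disjoint
between a patient's cases; feature extraction then recovers the generator's
case-level draws exactly, a property the round-trip tests assert to 1e-9.

**Continuous features.** 27 features are drawn through a Gaussian copula:
latent MVN with unit diagonal, rank-correlation targets converted by
Greiner's relation ρ = sin(πτ/2), then mapped through per-feature marginals
(truncated normal for near-symmetric labs and scores, moment-matched
lognormal for skewed labs, negative binomial for utilization counts, a
clipped negative binomial for the Charlson score). Marginal means/SDs/
min/max follow the reference cohort summaries the generator is calibrated to. Planted τ targets:
0.672 for red-blood-cell count against hematocrit and hemoglobin, 0.82 for
hematocrit–hemoglobin, 0.844 (latent) for maximum stay length against
inpatient admissions — chosen so (a) every planted pair exceeds the 0.65
flagging threshold with sampling margin at n ≥ 10,000, and (b) the VIF
stage sees hematocrit and hemoglobin above 5 but red-blood-cell count below
it, reproducing the qualitative collinearity structure of the real cohort
(reference VIFs ≈18.7/15.4/4.5). An infeasible (non-PSD) correlation request
is rejected with a diagnostic.

**Missingness** is injected completely at random per feature. The six
designated sparse features (urine protein, total protein, prothrombin time,
partial thromboplastin time, fall risk, fall history) default to 72–80%
missing, so the >70% filter removes exactly this set; routine pre-operative
panels (CBC, chemistry) get 10–20%, A1C 45%, BMI 3%. MNAR mechanisms are
deliberately out of scope — the selection stage tests the 70% rule, not
missingness modelling — so passing tests say nothing about informative
missingness in real data.

**Risk index and outcomes.** The base endpoint probability is logistic in
standardized age, a U-shaped BMI term (z² − 1; both low and high BMI raise
risk), Charlson score, prior ED visits, relationship status (protective),
an anticoagulant-order flag, a heart-disorder flag, and a latent note
signal. Per-joint intercepts are calibrated by bisection so each joint hits
its target endpoint rate *including* the sensitive-attribute bumps, which
pins the overall prevalence at 16.6% in expectation. Sensitive effects are
additive on the probability scale (matching treatment-effect semantics, not
odds ratios): female +0.0145, Medicare +0.0327, Medicaid +0.0308. Outcomes
and all six per-attribute counterfactual outcomes are drawn with common
random numbers, so the realized counterfactual contrast is an unbiased,
low-variance estimate of the planted effect; a configuration that clips
more than 1% of risks outside [0,1] warns.

Sensitive attributes are per-patient. Female and Medicaid are independent
of the covariates (the joint distribution of payor flags is configurable;
independence is the default). Medicare depends on age (logit slope 0.3 on
standardized age, intercept calibrated to the 60% marginal): strong enough
that the naive Medicare–outcome difference is visibly confounded, mild
enough that 1:1 matching without replacement can balance it (post-match
SMD ≈ 0.02 at full size). Medicaid's 10% marginal is not among the reference
quantities; 10% is a plausible payor share for elective arthroplasty and
is fixed once in the defaults.

**Materialization.** Features are drawn first, then unrolled into dated
relational tables: lab rows just before case creation (plus older in-window
rows and out-of-window decoys to exercise recency and boundary logic),
encounter rows for each utilization count within its window, the admission
carrying the maximum stay placed inside the 2-year window but outside the
1-year count window when the count is zero, diagnosis rows including a
random distinct-category decomposition of the drawn Charlson score, and
post-discharge encounters realizing each positive case's endpoint
mechanisms. Case-exclusion flags (fractures, revisions, intra-operative
fatalities) and planned readmissions default to rate 0 — the default cohort
is the *analyzed* cohort — and are switched on in tests.

**Notes.** ~76% of cases have notes (matching 29,346/38,581), ~23 notes per
populated case. Token composition mixes risky/benign clinical vocabulary
with the mixing probability tied to the case's true risk, so a bag-of-words
scorer is learnable and a zero-signal configuration is unlearnable by
construction. Duplicates, sub-200-character stubs and runs of `=`/`_`/`-`
are planted for the preprocessing stage. Note *lengths* default to tens of
tokens rather than the tens of thousands of characters real cases carry —
a deliberate scale-down so default corpora stay small; chunking behaviour
at scale is exercised via configuration.

## Endpoint labeling

"Within 30 days" is inclusive on both ends: admit − discharge ∈ [0, 30]
days (the day-0 inclusion is a config toggle, on by default). Any ED
encounter in the window counts as rule (b). Rule (c) fires on a SNF/rehab
discharge disposition unless the patient was admitted from a SNF. Planned
readmissions are matched by encounter grouper against a configurable list
(pregnancy/delivery, breast implantation, artificial/prosthetic limbs,
organ transplantation); they never count as endpoint mechanisms and exclude
the case when configured. Labeling is a pure function of the case row and
the patient's encounters; a missing discharge date is reported per case,
never silently skipped.

## Feature extraction

All windows anchor at the case creation date; shifting every date by a
constant leaves the matrix unchanged (tested). "Most recent" ties break to
the later collection timestamp, then last row in file order, keeping
extraction deterministic. Binary diagnosis/medication features read 0 when
no record exists (absence of a record is the signal); social-history flags
come from the most recent record at or before creation; the flowsheet-style
fall items additionally respect a 1-year window and are missing when
unrecorded. The Charlson score sums classic weights (1–6) over *distinct*
comorbidity categories. Kendall tau uses the tie-corrected τ-b (count
features are tie-heavy); Cramér's V is computed without bias correction;
constant columns report the association as undefined rather than 0.

## Note scoring

Preprocessing removes exact-duplicate texts per case (fuzzy deduplication is
out of scope), drops notes under 200 characters, strips runs of
`=`/`_`/`-`, collapses whitespace, and concatenates most-recent-first.
Chunking units are whitespace tokens (the transformer tokenizer is
abstracted away behind the `ChunkScorer` contract); chunks are 512 units
with the final short chunk kept. The default scorer is a hashed
bag-of-words (2^16 features, L2-normalized) logistic model trained on
chunk-level labels inherited from the case label. `C` is tuned on
{1, 1.5, …, 100} (199 candidates) by F1 of `P_final ≥ 0.5`; ties go to the
smallest `C`; whether to threshold at 0.5 or a tuned cut is exposed as
config. Cases with no surviving notes carry a missing NLP score and flow
through imputation like any feature.

## Selection cascade

Stage order is fixed: missingness → outliers → VIF → imputation →
Box-Tidwell → Box-Cox → adaptive lasso, and the `SelectionReport` ledger
replays to the identical output matrix.

- *Missingness*: strictly greater than 70% missing drops the column.
- *Outliers*: OLS of the outcome on continuous features; flag when Cook's
  distance > 4/n **and** |internally studentized residual| > 3 (strict
  inequalities; disjunction available). The auxiliary fit uses continuous
  features with ≤5% missingness so sparse labs cannot shrink it to a
  sliver of the cohort. Removing more than 5% of cases warns. Note that
  with a binary outcome the studentized residuals are bounded near
  1/√(p(1−p)) ≈ 2.7, so the default cohort yields zero removals; the stage
  is exercised on continuous designs in tests.
- *VIF*: 1/(1−R²) per feature, one removal pass, recomputed after removal.
  The pipeline uses complete-case rows when there are at least
  max(1000, 30p) of them — below that the ~p/n inflation of R² distorts
  VIFs near the cutoff — and otherwise takes the diagonal of the inverse
  pairwise-complete correlation matrix (eigenvalue-floored).
- *Imputation*: categorical missings become an explicit "unknown" indicator
  plus zero fill; continuous columns are imputed by seeded random-forest
  regressions on the fully observed columns; BMI gets an `imputed_bmi`
  indicator feature.
- *Box-Tidwell*: per-feature logistic fits augmented with x·ln(x), shift
  by 1 − min(x) when nonpositive values occur; p ≤ 0.05 flags
  non-linearity; separation or non-convergence marks the feature untested
  with a warning. Type-I error ≈ 5% and power > 80% against a quadratic
  logit at n = 2,000 are verified by simulation.
- *Box-Cox*: λ by maximum likelihood on a grid (−3 to 3, step 0.01),
  transform (x^λ − 1)/λ (ln x at λ = 0), applied to the flagged features.
- *Adaptive lasso*: standardized design; stage-1 ridge logistic with the
  penalty chosen by 5-fold cross-validated deviance; weights
  ω_j = 1/|β_j^ini|^γ, capped at 10^6 and normalized to geometric mean 1
  (only relative weights matter — the overall scale folds into the
  cross-validated stage-2 penalty; without normalization a heavily shrunk
  initializer makes every weight enormous and no finite penalty grid
  compensates). Stage 2 is an L1 logistic fit on the weight-rescaled
  columns, penalty again by cross-validated deviance; γ is compared across
  the grid {0.5, …, 2} by cross-validated F1 at each γ's chosen penalty.
  Exact zeros drop. With γ → 0 the procedure reduces to plain lasso
  (tested); support recovery on a 5-of-50 sparse truth at n = 2,000
  succeeds in ≥90% of replicates at an oracle penalty.

## Classifier

TPE (authored in `tjarisk.tpe`: random start-up, top-quantile/rest split,
per-parameter Parzen densities with a uniform prior component, candidates
ranked by the density ratio) searches the stated space maximizing
3-fold cross-validated F1 at the 0.5 cut; the budget defaults to 100 trials
(25 in the pipeline default for desk-scale runs). The split is a stratified
80/20 at case level; as in the source design, no patient-level grouping is
applied, which is a known leakage caveat when a patient's two cases land on
opposite sides. Baselines (LightGBM, XGBoost, logistic regression on
standardized inputs) fill the four-row comparison table. AUROC is the rank
statistic, AUPRC the step-integrated average precision, CIs are 95%
percentile bootstrap over test-set resamples (default 1,000).

SHAP values come from an exact path-dependent tree-SHAP implementation
(`tjarisk.explain`), validated three ways: bit-identical agreement between
the numba kernel and the pure-Python reference, additivity to the model
output within 1e-6 (observed ~1e-15), and equality with brute-force
Shapley enumeration over the cover-weighted conditional expectation on
small trees. Global importance is mean |SHAP| on a subsample (default 200
cases); each case also gets its top-3 positive contributors.

## Fairness audit

Mann-Whitney U (two-sided, tie-corrected) compares predicted scores between
the levels of each sensitive attribute. Propensity scores come from a
logistic regression of the attribute on standardized covariates (the
selected features minus the attribute); matching is greedy 1:1 nearest
neighbour on the *logit* propensity, without replacement and without a
caliper, with the smaller arm matched into the larger (required when
treated units outnumber controls, as for Medicare at 60%). Greedy matching
is order-dependent, so the processing order is randomized under the run
seed. Balance is gated at |SMD| < 0.2 (difference in means over the pooled
SD); the ATE is the matched-pair mean outcome difference with a percentile
bootstrap over pairs (score-scale effects are available by flag; the
outcome scale is the default reading of the reference effects).

## Equalized-odds thresholds

Per-group ROC convex hulls are built from empirical ROC points
(score ≥ t decision rule). The feasible equalized-odds region is the area
under every group's hull; its upper boundary is the pointwise minimum of
the hulls, and the operating point maximizes balanced accuracy
(TPR + 1 − FPR)/2 over a grid that contains every hull vertex plus a fine
mesh of 2,001 points (hull *crossings* between vertices are captured only
up to mesh resolution, a deliberate approximation; the single-group case is
exact and oracle-tested). Each group expresses the point as (t₀, t₁, w) on
its bracketing hull edge and collapses it deterministically to
t* = w·t₀ + (1−w)·t₁ — the randomization of the original formulation
removed. Thresholds are fitted on a 25% calibration fraction held out of
the training split (fitting them on test data would overstate parity).
Groups are intersectional (female × Medicare × Medicaid, up to 8 cells) by
default with marginal per-attribute gap reporting; groups under 30 members
or with one outcome class inherit the global threshold with a warning.
Adjusted scores R_adj = x/(x+1) are reported as continuous gaps before and
after; no pass/fail parity cut is hard-coded.

## Pipeline and determinism

Every stage reads from and writes to the run directory, so stages are
individually runnable (the `tjarisk` CLI mirrors them) and no stage mutates
another's outputs; a manifest records a SHA-256 per artifact. All
randomness descends from the single run seed through named spawned
generators; reruns are bit-identical (tested). The bundle serializes as
RFC-4180 CSV with ISO-8601 dates plus JSONL notes.

## Problem sizes

Default component sizes are chosen for single-CPU desk-scale runs: the test
suite exercises cohorts of 900–16,000 cases (38,581 for the calibration and
ATE-recovery acceptance checks), 12 replicates at n = 12,000 for the ATE
bias check, 500 simulation replicates for the Box-Tidwell type-I rate, and
20 replicates for lasso support recovery. `scripts/acceptance.py` runs the
full n = 38,581 path end to end.

## Known limitations

- MCAR missingness, exact-duplicate note detection, and additive
  probability-scale effects are simplifications; real cohorts violate all
  three in interesting ways.
- The case-level split can leak patient information across folds for
  two-case patients.
- The multi-group operating point is mesh-approximate between hull
  vertices; with very small groups the hull itself is noisy.
- Collapsing the randomized threshold pair to its weighted average attains
  the constrained optimum only approximately; the residual TPR/FPR gaps it
  leaves (≈0.01 at n = 20,000 in the planted-shift benchmark) are the price
  of determinism.
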
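"""End-to-end pipeline: generate → label → featurize → notes → select →
train → audit → adjust → report.

Each stage reads its inputs from the run directory and writes its artifacts
back to it, so stages can be run individually (the CLI mirrors them) and no
stage mutates another stage's outputs. A manifest records the configuration,
package versions, and a content hash of every artifact; reruns with the same
configuration and seed produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, catalog
from .endpoints import ExclusionConfig, apply_case_exclusions, label_cohort
from .explain import shap_importance
from .fairness import audit_attribute
from .features import build_features, descriptive_stats
from .model import evaluate_with_ci, fit_and_score, split_cases, tune_random_forest
from .notes import fit_note_scores
from .selection import AdaptiveLassoConfig, run_selection
from .synth import GeneratorConfig, generate_cohort, read_bundle, write_bundle
from .thresholds import adjust_scores, fairness_gaps, fit_group_thresholds

log = logging.getLogger("tjarisk.pipeline")

STAGES = ("generate", "label", "featurize", "notes", "select", "train",
          "audit", "adjust", "report")


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    exclusion: ExclusionConfig = field(default_factory=ExclusionConfig)
    lasso: AdaptiveLassoConfig | None = None
    use_notes: bool = True
    with_baselines: bool = True
    tune_trials: int = 25
    tune_folds: int = 3
    n_boot: int = 500
    test_size: float = 0.2
    #: Fraction of the training split held out to fit group thresholds.
    calibration_fraction: float = 0.25
    shap_sample: int = 200
    make_plots: bool = False
    skip_stages: tuple[str, ...] = ()

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        gen = GeneratorConfig(**raw.pop("generator", {}))
        exc = ExclusionConfig(**raw.pop("exclusion", {}))
        lasso = AdaptiveLassoConfig(**raw["lasso"]) if raw.get("lasso") else None
        raw.pop("lasso", None)
        return cls(generator=gen, exclusion=exc, lasso=lasso, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _out(config: RunConfig) -> Path:
    p = Path(config.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_generate(config: RunConfig) -> None:
    gen = dataclasses.replace(config.generator, seed=config.seed)
    bundle = generate_cohort(gen, include_notes=config.use_notes)
    write_bundle(bundle, _out(config) / "bundle")


def stage_label(config: RunConfig) -> None:
    out = _out(config)
    bundle = read_bundle(out / "bundle")
    retained, ledger = apply_case_exclusions(bundle.cases)
    labels = label_cohort(retained, bundle.encounters, config.exclusion)
    labels.to_csv(out / "labels.csv", index=False)
    exclusion = {"case_flag_exclusions": ledger,
                 "planned_readmission_exclusions":
                     int(labels["excluded"].sum()),
                 "n_labeled": int(labels["label"].notna().sum())}
    (out / "exclusion_ledger.json").write_text(json.dumps(exclusion, indent=2))


def stage_featurize(config: RunConfig) -> None:
    out = _out(config)
    bundle = read_bundle(out / "bundle")
    labels = pd.read_csv(out / "labels.csv")
    keep = labels.loc[labels["label"].notna(), "case_id"]
    bundle.cases = bundle.cases.loc[bundle.cases["case_id"].isin(set(keep))]
    fm = build_features(bundle)
    fm.data.to_csv(out / "features.csv")
    fm.meta.to_csv(out / "features_meta.csv")
    stats = descriptive_stats(fm)
    stats["continuous"].to_csv(out / "descriptive_stats.csv")
    stats["high_tau_pairs"].to_csv(out / "high_tau_pairs.csv", index=False)


def stage_notes(config: RunConfig) -> None:
    out = _out(config)
    if not config.use_notes:
        return
    bundle = read_bundle(out / "bundle")
    if bundle.notes is None or bundle.notes.empty:
        return
    labels = _read_labels(out)
    features = pd.read_csv(out / "features.csv", index_col="case_id")
    train_ids, *_ = split_cases(features, labels.loc[features.index],
                                test_size=config.test_size, seed=config.seed)
    scores, best_c, report = fit_note_scores(
        bundle.notes, labels, list(train_ids.index), seed=config.seed)
    scores.to_csv(out / "nlp_scores.csv", index=False)
    report.to_csv(out / "tune_c_report.csv", index=False)
    (out / "tune_c.json").write_text(json.dumps({"best_c": best_c}))


def _read_labels(out: Path) -> pd.Series:
    labels = pd.read_csv(out / "labels.csv")
    labels = labels.loc[labels["label"].notna()]
    return labels.set_index("case_id")["label"].astype(int)


def _assemble_matrix(out: Path, config: RunConfig) -> pd.DataFrame:
    df = pd.read_csv(out / "features.csv", index_col="case_id")
    nlp = out / "nlp_scores.csv"
    if config.use_notes and nlp.exists():
        scores = pd.read_csv(nlp).set_index("case_id")["p_final"]
        df["nlp_risk_score"] = scores.reindex(df.index)
    return df


def stage_select(config: RunConfig) -> None:
    out = _out(config)
    df = _assemble_matrix(out, config)
    y = _read_labels(out).loc[df.index]
    cont = [c for c in df.columns
            if c in catalog.FEATURE_INDEX and catalog.FEATURE_INDEX[c].is_continuous]
    cat = [c for c in df.columns if c not in cont]
    selected, report = run_selection(
        df, y, continuous_cols=cont, categorical_cols=cat, seed=config.seed,
        lasso_config=config.lasso or AdaptiveLassoConfig(seed=config.seed))
    selected.to_csv(out / "selected_features.csv")
    vif = report.stage("vif")["table"]
    vif.to_csv(out / "vif_table.csv")
    summary = {
        "missingness_dropped": report.stage("missingness")["dropped"],
        "n_outliers_removed": len(report.stage("outliers")["removed_case_ids"]),
        "vif_dropped": report.stage("vif")["dropped"],
        "nonlinear_features": list(
            report.stage("box_cox")["transforms"].keys()),
        "box_cox_lambdas": {k: v[1] for k, v in
                            report.stage("box_cox")["transforms"].items()},
        "gamma": report.stage("adaptive_lasso")["gamma"],
        "n_selected": len(report.final_features),
        "selected": report.final_features,
    }
    (out / "selection_report.json").write_text(json.dumps(summary, indent=2))


def _selected_matrix(out: Path, config: RunConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Model matrix: the selection stage's feature list applied to the *full*
    labeled cohort (outlier cases are excluded from selection fitting only;
    the classifier trains on every case)."""
    df = _assemble_matrix(out, config)
    y = _read_labels(out).loc[df.index]
    summary = json.loads((out / "selection_report.json").read_text())
    sel = pd.read_csv(out / "selected_features.csv", index_col="case_id")
    feats = summary["selected"]
    base = [f for f in feats if f in df.columns]
    x = df[base].copy()
    # Reapply the cascade's derived columns (imputation fills, indicators,
    # transforms) by aligning with the selected matrix where available and
    # median-filling the outlier cases that the cascade removed.
    for f in feats:
        if f not in x.columns:
            x[f] = sel[f].reindex(df.index)
    for f in feats:
        aligned = sel[f].reindex(df.index)
        x[f] = aligned.where(aligned.notna(), x[f])
        if x[f].isna().any():
            x[f] = x[f].fillna(sel[f].median())
    return x[feats], y


def stage_train(config: RunConfig) -> None:
    out = _out(config)
    x, y = _selected_matrix(out, config)
    xtr, xte, ytr, yte = split_cases(x, y, test_size=config.test_size,
                                     seed=config.seed)
    params, trials = tune_random_forest(xtr, ytr, n_trials=config.tune_trials,
                                        seed=config.seed,
                                        n_folds=config.tune_folds)
    rf, scores, comparison = fit_and_score(params, xtr, ytr, xte, yte,
                                           seed=config.seed,
                                           with_baselines=config.with_baselines,
                                           n_boot=config.n_boot)
    scores.to_csv(out / "scores.csv", index=False)
    comparison.to_csv(out / "model_comparison.csv", index=False)
    (out / "best_params.json").write_text(json.dumps(params, indent=2))
    sample = x.sample(n=min(config.shap_sample, len(x)),
                      random_state=config.seed)
    global_tbl, topk = shap_importance(rf, sample)
    global_tbl.to_csv(out / "shap_global.csv", index=False)
    topk.to_csv(out / "shap_topk.csv", index=False)
    rep = evaluate_with_ci(scores["score"], scores["label"],
                           n_boot=config.n_boot, seed=config.seed,
                           keep_curves=True)
    (out / "eval_report.json").write_text(json.dumps({
        "auroc": rep.auroc, "auroc_ci": list(rep.auroc_ci),
        "auprc": rep.auprc, "auprc_ci": list(rep.auprc_ci),
        "n_boot": rep.n_boot}, indent=2))
    rep.roc_curve.to_csv(out / "roc_curve.csv", index=False)
    rep.pr_curve.to_csv(out / "pr_curve.csv", index=False)
    if config.make_plots:
        _plot_curves(rep, out)
    # Persist the calibration split and per-case scores for the later stages.
    xfit, xcal, yfit, ycal = split_cases(xtr, ytr,
                                         test_size=config.calibration_fraction,
                                         seed=config.seed + 1)
    cal_scores = pd.DataFrame({"case_id": xcal.index,
                               "score": rf.predict_proba(xcal)[:, 1],
                               "label": np.asarray(ycal, int)})
    cal_scores.to_csv(out / "calibration_scores.csv", index=False)


def _plot_curves(rep, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].plot(rep.roc_curve["fpr"], rep.roc_curve["tpr"])
    axes[0].plot([0, 1], [0, 1], "k--", lw=0.7)
    axes[0].set(xlabel="FPR", ylabel="TPR",
                title=f"ROC (AUROC {rep.auroc:.3f})")
    axes[1].plot(rep.pr_curve["recall"], rep.pr_curve["precision"])
    axes[1].set(xlabel="Recall", ylabel="Precision",
                title=f"PR (AUPRC {rep.auprc:.3f})")
    fig.tight_layout()
    fig.savefig(out / "curves.png", dpi=120)
    plt.close(fig)


def stage_audit(config: RunConfig) -> None:
    out = _out(config)
    x, y = _selected_matrix(out, config)
    bundle = read_bundle(out / "bundle")
    sens = (bundle.cases[["case_id", "patient_id"]]
            .merge(bundle.sensitive, on="patient_id")
            .set_index("case_id")
            .loc[x.index, ["female", "medicare", "medicaid"]])
    scores = pd.read_csv(out / "scores.csv").set_index("case_id")["score"]
    report = {}
    for attr in ("female", "medicare", "medicaid"):
        covs = x.drop(columns=[attr], errors="ignore")
        test_sens = sens.loc[sens.index.intersection(scores.index), attr]
        res = audit_attribute(covs, sens[attr].rename(attr), y,
                              scores=None, seed=config.seed,
                              n_boot=config.n_boot)
        psm = res["psm"]
        from .fairness import mannwhitney_by_group
        u, p = mannwhitney_by_group(scores.loc[test_sens.index], test_sens)
        report[attr] = {
            "mannwhitney_u": u, "mannwhitney_p": p,
            "ate": psm.ate, "ate_ci": list(psm.ate_ci),
            "n_pairs": len(psm.pairs),
            "max_smd_before": float(psm.smd_before.abs().max()),
            "max_smd_after": float(psm.smd_after.abs().max()),
            "balanced": psm.balanced,
        }
        smd = pd.DataFrame({"before": psm.smd_before, "after": psm.smd_after})
        smd.to_csv(out / f"smd_{attr}.csv")
    (out / "psm_report.json").write_text(json.dumps(report, indent=2))


def stage_adjust(config: RunConfig) -> None:
    out = _out(config)
    bundle = read_bundle(out / "bundle")
    sens_all = (bundle.cases[["case_id", "patient_id"]]
                .merge(bundle.sensitive, on="patient_id").set_index("case_id"))
    cal = pd.read_csv(out / "calibration_scores.csv").set_index("case_id")
    test = pd.read_csv(out / "scores.csv").set_index("case_id")
    from .thresholds import intersectional_groups
    g_cal = intersectional_groups(sens_all.loc[cal.index])
    g_test = intersectional_groups(sens_all.loc[test.index])
    ts = fit_group_thresholds(cal["score"], cal["label"], g_cal)
    ts.table.to_csv(out / "thresholds.csv", index=False)
    adj = adjust_scores(test["score"], g_test, ts)
    adj.insert(0, "case_id", test.index)
    adj.to_csv(out / "adjusted_scores.csv", index=False)
    rows = []
    from .thresholds import balanced_accuracy_threshold
    t_shared, _ = balanced_accuracy_threshold(cal["score"], cal["label"])
    for attr in ("female", "medicare", "medicaid"):
        marg = sens_all.loc[test.index, attr].astype(str)
        before_tbl, before = fairness_gaps(
            (test["score"] >= t_shared).astype(int), test["label"], marg)
        after_tbl, after = fairness_gaps(
            (adj["r_adj"] >= 0.5).astype(int), test["label"].to_numpy(), marg)
        rows.append((attr, before["tpr_gap"], after["tpr_gap"],
                     before["fpr_gap"], after["fpr_gap"]))
    pd.DataFrame(rows, columns=["attribute", "tpr_gap_before", "tpr_gap_after",
                                "fpr_gap_before", "fpr_gap_after"]) \
        .to_csv(out / "fairness_gaps.csv", index=False)


def stage_report(config: RunConfig) -> None:
    out = _out(config)
    artifacts = sorted(p for p in out.rglob("*")
                       if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config),
                                        default=str)),
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


STAGE_FUNCS = {
    "generate": stage_generate, "label": stage_label,
    "featurize": stage_featurize, "notes": stage_notes,
    "select": stage_select, "train": stage_train,
    "audit": stage_audit, "adjust": stage_adjust, "report": stage_report,
}


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage in order; returns the run directory.

    A stage failure aborts the run with the stage name and cause; artifacts
    of completed stages are retained.
    """
    out = _out(config)
    for name in STAGES:
        if name in config.skip_stages:
            log.info("stage %s skipped", name)
            continue
        t0 = time.time()
        try:
            STAGE_FUNCS[name](config)
        except Exception as exc:
            stage_report(config)  # manifest marks the partial run
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info("stage %s done in %.1fs", name, time.time() - t0)
    return out
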
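"""Classifier tuning, evaluation metrics, and SHAP explanations."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from tjarisk.explain import TreeShapExplainer, shap_importance
from tjarisk.model import (
    TUNING_SPACE,
    auroc_pair_count,
    evaluate_with_ci,
    fit_and_score,
    split_cases,
    tune_random_forest,
)
from tjarisk.tpe import CatParam, IntParam, tpe_maximize


def _signal_data(rng, n=900, p=6):
    x = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"f{i}" for i in range(p)],
                     index=[f"C{i}" for i in range(n)])
    eta = 1.5 * x["f0"] + 1.0 * x["f1"] - 1.2
    y = pd.Series((rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int),
                  index=x.index)
    return x, y


class TestTPE:
    def test_deterministic_and_single_trial(self):
        space = {"a": IntParam(1, 20), "c": CatParam(("x", "y"))}
        obj = lambda p: -(p["a"] - 7) ** 2 + (5 if p["c"] == "x" else 0)
        best1, hist1 = tpe_maximize(obj, space, n_trials=30, seed=5)
        best2, hist2 = tpe_maximize(obj, space, n_trials=30, seed=5)
        assert best1 == best2
        assert [t.params for t in hist1] == [t.params for t in hist2]
        single, hist = tpe_maximize(obj, space, n_trials=1, seed=5)
        assert single == hist[0].params
        with pytest.raises(ValueError):
            tpe_maximize(obj, space, n_trials=0)

    def test_search_improves_over_random_startup(self):
        space = {"a": IntParam(0, 200), "b": IntParam(0, 200)}
        obj = lambda p: -abs(p["a"] - 137) - abs(p["b"] - 23)
        best, hist = tpe_maximize(obj, space, n_trials=60, seed=1)
        startup_best = max(t.value for t in hist[:10])
        assert max(t.value for t in hist) >= startup_best
        assert obj(best) > -80  # far better than a typical random draw (~-130)


class TestTuning:
    def test_rf_tuning_deterministic_and_beats_untuned(self, rng):
        x, y = _signal_data(rng, n=500)
        kwargs = dict(n_trials=8, seed=2, n_folds=3,
                      space={**TUNING_SPACE,
                             "n_estimators": IntParam(20, 60)})
        best1, trials1 = tune_random_forest(x, y, **kwargs)
        best2, _ = tune_random_forest(x, y, **kwargs)
        assert best1 == best2
        assert len(trials1) == 8
        from tjarisk.model import _cv_f1
        from sklearn.model_selection import StratifiedKFold
        cv = StratifiedKFold(3, shuffle=True, random_state=2)
        tuned = _cv_f1(best1, x.to_numpy(), y.to_numpy(), cv, 2)
        default = _cv_f1({}, x.to_numpy(), y.to_numpy(), cv, 2)
        assert tuned >= default - 1e-9

    def test_single_class_rejected(self, rng):
        x, _ = _signal_data(rng, n=100)
        with pytest.raises(ValueError):
            tune_random_forest(x, pd.Series(1, index=x.index), n_trials=1)


class TestFitAndScore:
    def test_comparison_table_has_four_models(self, rng):
        x, y = _signal_data(rng, n=700)
        xtr, xte, ytr, yte = split_cases(x, y, seed=0)
        rf, scores, table = fit_and_score({"n_estimators": 60}, xtr, ytr,
                                          xte, yte, seed=0, n_boot=50)
        assert set(table["model"]) == {"random_forest", "lgbm", "xgboost",
                                       "logistic_regression"}
        assert scores["score"].between(0, 1).all()
        assert ((table["auroc_lo"] <= table["auroc"])
                & (table["auroc"] <= table["auroc_hi"])).all()

    def test_feature_mismatch_is_reported(self, rng):
        x, y = _signal_data(rng, n=200)
        xtr, xte, ytr, yte = split_cases(x, y, seed=0)
        with pytest.raises(ValueError, match="mismatch"):
            fit_and_score({}, xtr, ytr, xte.drop(columns=["f0"]), yte)

    def test_permuted_labels_score_at_chance(self, rng):
        x, y = _signal_data(rng, n=10_000)
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        xtr, xte, ytr, yte = split_cases(x, y_perm, seed=1)
        _, scores, _ = fit_and_score({"n_estimators": 80}, xtr, ytr, xte, yte,
                                     seed=1, with_baselines=False, n_boot=10)
        rep = evaluate_with_ci(scores["score"], scores["label"], n_boot=10)
        assert abs(rep.auroc - 0.5) < 0.04

    def test_strong_signal_cohort_scores_high(self):
        from tjarisk import GeneratorConfig, generate_cohort
        from tjarisk.features import build_features
        bundle = generate_cohort(
            GeneratorConfig(n_cases=4000, seed=6, risk_logit_scale=3.0),
            include_notes=False)
        y = bundle.truth.set_index("case_id")["y"].astype(int)
        x = (build_features(bundle).data
             [["age", "bmi", "charlson_score", "n_ed_visits",
               "relationship_status", "med_anticoagulant", "dx_heart_disorder"]])
        xtr, xte, ytr, yte = split_cases(x, y.loc[x.index], seed=6)
        _, scores, _ = fit_and_score({"n_estimators": 150, "max_depth": 8},
                                     xtr, ytr, xte, yte, seed=6,
                                     with_baselines=False, n_boot=10)
        rep = evaluate_with_ci(scores["score"], scores["label"], n_boot=10)
        assert rep.auroc > 0.70


class TestEvaluation:
    def test_perfect_and_baseline_limits(self, rng):
        y = np.array([0] * 50 + [1] * 50)
        s = y.astype(float)
        rep = evaluate_with_ci(s, y, n_boot=20)
        assert rep.auroc == 1.0 and rep.auprc == 1.0
        # uninformative scores: AUPRC ~ prevalence
        y2 = (rng.uniform(size=4000) < 0.2).astype(int)
        s2 = rng.uniform(size=4000)
        rep2 = evaluate_with_ci(s2, y2, n_boot=20)
        assert abs(rep2.auprc - 0.2) < 0.04
        assert abs(rep2.auroc - 0.5) < 0.04

    def test_auroc_equals_pair_counting_oracle(self, rng):
        for _ in range(10):
            n = 12
            s = np.round(rng.uniform(size=n), 1)  # coarse: force ties
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            rep = evaluate_with_ci(s, y, n_boot=5)
            assert rep.auroc == pytest.approx(auroc_pair_count(s, y))

    def test_auroc_invariant_under_monotone_transform(self, rng):
        s = rng.uniform(size=300)
        y = (rng.uniform(size=300) < s).astype(int)
        a = evaluate_with_ci(s, y, n_boot=5).auroc
        b = evaluate_with_ci(s / (s + 1), y, n_boot=5).auroc
        assert a == pytest.approx(b)

    def test_ci_width_shrinks_with_sample_size(self, rng):
        def width(n, seed):
            s = rng.uniform(size=n)
            y = (rng.uniform(size=n) < np.clip(s, 0.05, 0.95)).astype(int)
            rep = evaluate_with_ci(s, y, n_boot=200, seed=seed)
            return rep.auroc_ci[1] - rep.auroc_ci[0]

        assert width(4000, 1) < width(300, 1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_with_ci(np.ones(10), np.ones(10, dtype=int))


class TestShap:
    def test_additivity_to_model_output(self, rng):
        x, y = _signal_data(rng, n=400)
        rf = RandomForestClassifier(n_estimators=25, max_depth=6,
                                    random_state=0).fit(x, y)
        ex = TreeShapExplainer(rf)
        sub = x.iloc[:40]
        phi = ex.shap_values(sub)
        pred = rf.predict_proba(sub)[:, 1]
        assert np.abs(phi.sum(axis=1) + ex.expected_value - pred).max() < 1e-6

    def test_single_feature_tree_shap_is_score_minus_base(self, rng):
        x = pd.DataFrame({"only": rng.normal(size=300)})
        y = (x["only"] > 0.3).astype(int)
        dt = DecisionTreeClassifier(max_depth=3, random_state=0).fit(x, y)
        ex = TreeShapExplainer(dt)
        phi = ex.shap_values(x.iloc[:20])
        pred = dt.predict_proba(x.iloc[:20])[:, 1]
        assert np.allclose(phi[:, 0], pred - ex.expected_value)

    def test_irrelevant_feature_ranks_at_the_bottom(self, rng):
        # every feature except f9 carries planted signal; f9 has zero effect
        # and no correlation with the others, so it must land at the bottom
        n, p = 1500, 10
        x = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"f{i}" for i in range(p)])
        coefs = np.linspace(1.6, 0.4, p - 1)
        eta = sum(c * x[f"f{i}"] for i, c in enumerate(coefs))
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        rf = RandomForestClassifier(n_estimators=60, max_depth=6,
                                    random_state=0).fit(x, y)
        table, topk = shap_importance(rf, x.iloc[:250])
        ranks = {f: i for i, f in enumerate(table["feature"])}
        assert ranks["f9"] >= p - 2
        assert set(topk.columns) == {"case_id", "rank", "feature", "shap"}
        assert topk["rank"].max() <= 3
        assert (topk["shap"] > 0).all()

    def test_accelerated_kernel_matches_reference_implementation(self, rng):
        x, y = _signal_data(rng, n=300)
        rf = RandomForestClassifier(n_estimators=10, max_depth=7,
                                    random_state=1).fit(x, y)
        fast = TreeShapExplainer(rf).shap_values(x.iloc[:10])
        slow = TreeShapExplainer(rf, use_numba=False).shap_values(x.iloc[:10])
        assert np.abs(fast - slow).max() < 1e-12
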
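"""Equalized-odds threshold optimization and the bounded score adjustment."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from tjarisk.thresholds import (
    GroupThresholdSet,
    adjust_scores,
    balanced_accuracy_threshold,
    fairness_gaps,
    fit_group_thresholds,
    intersectional_groups,
)


def _biased_cohort(rng, n=6000, shift=0.10):
    g = rng.choice(["a", "b"], size=n)
    y = (rng.uniform(size=n) < 0.3).astype(int)
    s = np.clip(rng.normal(0.3 + 0.25 * y, 0.15), 0, 1)
    s = np.clip(s + np.where(g == "b", shift, 0.0), 0, 1)
    return s, y, g


def _reference_randomized_optimum(scores, labels, groups, n_grid=2001):
    """Independent oracle for the published randomized optimizer's operating
    point: for each FPR on a grid, each group's best achievable TPR is found
    by mixing the two empirical ROC points that bracket that FPR (computed
    directly from sorted scores, without the package's hull code); the
    shared feasible TPR is the per-group minimum and the objective is
    balanced accuracy."""
    xs = np.linspace(0, 1, n_grid)
    tprs = []
    for key in np.unique(groups):
        m = groups == key
        s, y = scores[m], labels[m]
        pos, neg = s[y == 1], s[y == 0]
        cuts = np.unique(np.concatenate([s, [np.inf]]))[::-1]
        fpr = np.array([(neg >= c).mean() for c in cuts])
        tpr = np.array([(pos >= c).mean() for c in cuts])
        # upper concave envelope via cumulative maximum of slopes scan:
        # brute force — for each grid x take the max over all convex
        # combinations of two ROC points
        best = np.zeros_like(xs)
        order = np.argsort(fpr)
        fpr, tpr = fpr[order], tpr[order]
        for i in range(len(fpr)):
            for j in range(i, len(fpr)):
                lo, hi = fpr[i], fpr[j]
                mask = (xs >= lo) & (xs <= hi)
                if hi > lo:
                    w = (xs[mask] - lo) / (hi - lo)
                    val = tpr[i] + w * (tpr[j] - tpr[i])
                else:
                    val = np.full(mask.sum(), max(tpr[i], tpr[j]))
                best[mask] = np.maximum(best[mask], val)
        tprs.append(best)
    feasible = np.min(tprs, axis=0)
    obj = (feasible + 1 - xs) / 2
    k = int(np.argmax(obj))
    return float(xs[k]), float(feasible[k]), float(obj[k])


class TestFit:
    def test_single_group_matches_exhaustive_cutpoint_scan(self, rng):
        s = np.round(rng.uniform(size=400), 2)
        y = (rng.uniform(size=400) < np.clip(s, 0.05, 0.95)).astype(int)
        t_star, obj = balanced_accuracy_threshold(s, y)
        cand = np.unique(np.concatenate([s, [0.0, 1.0, 1.1]]))
        best = max(((s[y == 1] >= c).mean() + (s[y == 0] < c).mean()) / 2
                   for c in cand)
        assert obj == pytest.approx(best)
        got = ((s[y == 1] >= t_star).mean() + (s[y == 0] < t_star).mean()) / 2
        assert got == pytest.approx(best)
        # the group fit collapses to the same operating point
        ts = fit_group_thresholds(s, y, np.repeat("only", s.size))
        assert ts.objective == pytest.approx(best)

    def test_identical_groups_get_identical_thresholds(self, rng):
        s = rng.uniform(size=4000)
        y = (rng.uniform(size=4000) < np.clip(s, 0.05, 0.95)).astype(int)
        g = np.array(["a", "b"])[np.arange(4000) % 2]
        ts = fit_group_thresholds(s, y, g)
        stars = ts.table.set_index("group")["t_star"]
        assert abs(stars["a"] - stars["b"]) < 0.05

    def test_operating_point_matches_reference_randomized_oracle(self, rng):
        s, y, g = _biased_cohort(rng, n=2500)
        ts = fit_group_thresholds(s, y, g)
        x_ref, tpr_ref, obj_ref = _reference_randomized_optimum(s, y, g)
        assert ts.objective == pytest.approx(obj_ref, abs=0.01)
        assert ts.operating_point[0] == pytest.approx(x_ref, abs=0.03)

    def test_deterministic(self, rng):
        s, y, g = _biased_cohort(rng)
        t1 = fit_group_thresholds(s, y, g)
        t2 = fit_group_thresholds(s, y, g)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_small_or_single_class_group_falls_back(self, rng):
        s = rng.uniform(size=220)
        y = (rng.uniform(size=220) < s).astype(int)
        g = np.array(["big"] * 200 + ["tiny"] * 20)
        with pytest.warns(UserWarning, match="falling back"):
            ts = fit_group_thresholds(s, y, g)
        row = ts.table.set_index("group")
        assert bool(row.loc["tiny", "fallback"])
        assert row.loc["tiny", "t_star"] == pytest.approx(ts.global_threshold)

    def test_thresholds_bracket_t_star(self, rng):
        s, y, g = _biased_cohort(rng)
        ts = fit_group_thresholds(s, y, g)
        t = ts.table
        assert ((t["t_star"] >= np.minimum(t["t0"], t["t1"]) - 1e-12)
                & (t["t_star"] <= np.maximum(t["t0"], t["t1"]) + 1e-12)).all()
        assert (t["t_star"] > 0).all()
        assert t["w"].between(0, 1).all()


class TestAdjustment:
    def _ts(self, mapping):
        table = pd.DataFrame([(k, v, v, 1.0, v, False) for k, v in mapping.items()],
                             columns=["group", "t0", "t1", "w", "t_star",
                                      "fallback"])
        return GroupThresholdSet(table=table, operating_point=(0, 0),
                                 objective=0.0, global_threshold=0.5)

    def test_fixed_points_and_arithmetic(self):
        ts = self._ts({"g": 0.1})
        adj = adjust_scores(np.array([0.1, 0.0, 0.3]), np.repeat("g", 3), ts)
        assert adj["r_adj"].tolist() == pytest.approx([0.5, 0.0, 0.75])

    def test_range_and_decision_equivalence(self, rng):
        s, y, g = _biased_cohort(rng, n=1500)
        ts = fit_group_thresholds(s, y, g)
        adj = adjust_scores(s, g, ts)
        assert ((adj["r_adj"] >= 0) & (adj["r_adj"] < 1)).all()
        hard = adj["raw"] >= adj["threshold"]
        assert ((adj["r_adj"] >= 0.5) == hard).all()

    def test_within_group_auroc_is_exactly_preserved(self, rng):
        s, y, g = _biased_cohort(rng, n=3000)
        ts = fit_group_thresholds(s, y, g)
        adj = adjust_scores(s, g, ts)
        for key in ("a", "b"):
            m = g == key
            assert roc_auc_score(y[m], s[m]) == pytest.approx(
                roc_auc_score(y[m], adj.loc[m, "r_adj"]), abs=1e-12)

    def test_same_raw_score_orders_inversely_with_threshold(self):
        ts = self._ts({"lo": 0.2, "hi": 0.4})
        adj = adjust_scores(np.array([0.3, 0.3]), np.array(["lo", "hi"]), ts)
        assert adj.loc[0, "r_adj"] > adj.loc[1, "r_adj"]

    def test_nonpositive_threshold_rejected(self):
        ts = self._ts({"g": 0.0})
        with pytest.raises(ValueError, match="non-positive"):
            adjust_scores(np.array([0.5]), np.array(["g"]), ts)


class TestGaps:
    def test_trivial_cases(self):
        y = np.array([1, 1, 0, 0, 1, 1, 0, 0])
        g = np.array(list("abab" * 2))
        table, gaps = fairness_gaps(y, y, g)  # perfect classifier
        assert (table["tpr"] == 1).all() and (table["fpr"] == 0).all()
        assert gaps == {"tpr_gap": 0.0, "fpr_gap": 0.0}

    def test_group_without_positives_reports_nan(self):
        y = np.array([0, 0, 1, 0])
        d = np.array([0, 1, 1, 0])
        g = np.array(["a", "a", "b", "b"])
        table, gaps = fairness_gaps(d, y, g)
        assert np.isnan(table.set_index("group").loc["a", "tpr"])

    def test_per_group_thresholds_shrink_gaps_on_planted_bias(self, rng):
        s, y, g = _biased_cohort(rng, n=8000)
        t_shared, _ = balanced_accuracy_threshold(s, y)
        _, before = fairness_gaps((s >= t_shared).astype(int), y, g)
        ts = fit_group_thresholds(s, y, g)
        adj = adjust_scores(s, g, ts)
        _, after = fairness_gaps((adj["r_adj"] >= 0.5).astype(int), y, g)
        assert after["tpr_gap"] < before["tpr_gap"]
        assert after["fpr_gap"] < before["fpr_gap"]


def test_intersectional_group_keys():
    sens = pd.DataFrame({"female": [1, 0], "medicare": [0, 1],
                         "medicaid": [0, 0]})
    keys = intersectional_groups(sens)
    assert keys.tolist() == ["1|0|0", "0|1|0"]
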
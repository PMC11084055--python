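"""Deterministic extended equalized-odds threshold optimization.

Post-processing for group fairness: for each sensitive group an ROC convex
hull is built from the predicted scores, and a single operating point
(FPR, TPR) is chosen in the intersection of the group-feasible regions by
maximizing balanced accuracy. Because the chosen point generally falls on a
hull *edge* rather than a vertex, each group expresses it as an
interpolation between two adjacent ROC thresholds (t0, t1) with weight w —
the randomized interpolation of the original formulation. Here the
randomization is removed: the pair collapses to one deterministic threshold
per group,

    t* = w·t0 + (1−w)·t1 ,

and instead of a hard decision each case receives a bounded adjusted score

    R_adj = x / (x + 1),   x = raw score / t*  (its group's threshold),

which lies in [0, 1), equals 0.5 exactly when the raw score sits at the
group threshold, and is strictly increasing in the raw score — so the
decision rule R_adj >= 0.5 coincides with raw >= t* and within-group ranking
(hence within-group AUROC) is unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

#: Groups smaller than this inherit the global threshold (ROC degeneracy).
MIN_GROUP_SIZE = 30


@dataclass
class GroupThresholdSet:
    """Per-group threshold pairs and collapsed thresholds."""

    table: pd.DataFrame          # group, t0, t1, w, t_star, fallback
    operating_point: tuple[float, float]   # (FPR, TPR) target
    objective: float             # balanced accuracy at the operating point
    global_threshold: float
    roc_hulls: dict = field(default_factory=dict, repr=False)

    def threshold_for(self, group) -> float:
        row = self.table.loc[self.table["group"] == group]
        if row.empty:
            return self.global_threshold
        return float(row["t_star"].iloc[0])


def _roc_hull(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Upper convex hull of the empirical ROC curve, with thresholds.

    Points are (FPR, TPR, threshold) where the classifier is
    ``score >= threshold``; the hull always contains (0, 0) and (1, 1).
    """
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    hi = max(1.0, float(np.max(scores)))
    thr = np.where(np.isinf(thr), hi + 1e-6, thr)
    pts = sorted(zip(fpr, tpr, thr))
    hull: list[tuple[float, float, float]] = []
    for p in pts:
        while len(hull) >= 2:
            (x1, y1, _), (x2, y2, _) = hull[-2], hull[-1]
            if (x2 - x1) * (p[1] - y1) - (p[0] - x1) * (y2 - y1) >= 0:
                hull.pop()
            else:
                break
        hull.append(p)
    return pd.DataFrame(hull, columns=["fpr", "tpr", "threshold"])


def _hull_tpr_at(hull: pd.DataFrame, x: np.ndarray) -> np.ndarray:
    return np.interp(x, hull["fpr"].to_numpy(), hull["tpr"].to_numpy())


def _interpolate_threshold(hull: pd.DataFrame, x: float) -> tuple[float, float, float]:
    """(t0, t1, w): adjacent hull thresholds bracketing FPR = x and the
    weight w on t0 solving w·fpr0 + (1−w)·fpr1 = x."""
    f = hull["fpr"].to_numpy()
    t = hull["threshold"].to_numpy()
    j = int(np.searchsorted(f, x, side="right"))
    if j == 0:
        return float(t[0]), float(t[0]), 1.0
    if j >= f.size:
        return float(t[-1]), float(t[-1]), 1.0
    f0, f1 = f[j - 1], f[j]
    if f1 == f0:
        return float(t[j - 1]), float(t[j]), 1.0
    w = float((f1 - x) / (f1 - f0))
    return float(t[j - 1]), float(t[j]), w


def balanced_accuracy_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Single-population balanced-accuracy-optimal threshold via the hull.

    Returns (threshold, balanced accuracy). The optimum of a linear
    objective over the ROC feasible region is attained at a hull vertex, so
    scanning vertices is exact.
    """
    hull = _roc_hull(np.asarray(scores, float), np.asarray(labels, int))
    obj = (hull["tpr"] + 1.0 - hull["fpr"]) / 2.0
    j = int(np.argmax(obj.to_numpy()))
    return float(hull["threshold"].iloc[j]), float(obj.iloc[j])


def fit_group_thresholds(scores, labels, groups, *,
                         min_group_size: int = MIN_GROUP_SIZE,
                         grid_points: int = 2001) -> GroupThresholdSet:
    """Fit per-group thresholds under the equalized-odds constraint.

    The common operating point maximizes balanced accuracy over the
    pointwise minimum of the group ROC hulls (the intersection of feasible
    regions); ties break to the smallest FPR. Groups with a single outcome
    class or fewer than ``min_group_size`` members fall back to the global
    balanced-accuracy threshold with a warning. Fully deterministic.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    g = np.asarray(groups)
    if s.size == 0:
        raise ValueError("empty inputs")
    t_global, _ = balanced_accuracy_threshold(s, y)

    hulls, fallback = {}, {}
    for key in pd.unique(g):
        mask = g == key
        if mask.sum() == 0:
            raise ValueError(f"empty group {key!r}")
        if mask.sum() < min_group_size or len(np.unique(y[mask])) < 2:
            warnings.warn(f"group {key!r} is too small or single-class; "
                          "falling back to the global threshold", stacklevel=2)
            fallback[key] = True
            continue
        hulls[key] = _roc_hull(s[mask], y[mask])
        fallback[key] = False

    rows = []
    if hulls:
        xs = np.unique(np.concatenate(
            [h["fpr"].to_numpy() for h in hulls.values()]
            + [np.linspace(0.0, 1.0, grid_points)]))
        min_tpr = np.min(np.vstack([_hull_tpr_at(h, xs) for h in hulls.values()]),
                         axis=0)
        obj = (min_tpr + 1.0 - xs) / 2.0
        j = int(np.argmax(obj))          # argmax returns the first (smallest FPR)
        x_star, tpr_star, best = float(xs[j]), float(min_tpr[j]), float(obj[j])
        for key, hull in hulls.items():
            t0, t1, w = _interpolate_threshold(hull, x_star)
            t_star = max(w * t0 + (1.0 - w) * t1, 1e-9)
            rows.append((key, t0, t1, w, t_star, False))
    else:
        x_star, tpr_star, best = np.nan, np.nan, np.nan
    for key, fb in fallback.items():
        if fb:
            rows.append((key, t_global, t_global, 1.0, max(t_global, 1e-9), True))
    table = pd.DataFrame(rows, columns=["group", "t0", "t1", "w", "t_star",
                                        "fallback"])
    return GroupThresholdSet(table=table, operating_point=(x_star, tpr_star),
                             objective=best, global_threshold=t_global,
                             roc_hulls=hulls)


def adjust_scores(scores, groups, thresholds: GroupThresholdSet) -> pd.DataFrame:
    """Bounded per-group score adjustment R_adj = x/(x+1), x = raw/t*.

    R_adj is in [0, 1), hits 0.5 exactly at the group threshold, and is
    strictly increasing in the raw score, so the rule R_adj >= 0.5 equals
    raw >= t*. Cases with the same raw score in groups with different
    thresholds receive different adjusted scores, ordered inversely with t*.
    """
    s = np.asarray(scores, dtype=float)
    g = np.asarray(groups)
    t = np.array([thresholds.threshold_for(k) for k in g])
    if np.any(t <= 0):
        raise ValueError("non-positive group threshold")
    x = s / t
    return pd.DataFrame({"raw": s, "group": g, "threshold": t,
                         "ratio": x, "r_adj": x / (x + 1.0)})


def fairness_gaps(decisions, labels, groups) -> tuple[pd.DataFrame, dict]:
    """Per-group TPR/FPR and the maximum pairwise absolute gaps.

    A group without positives (negatives) has undefined TPR (FPR), reported
    as NaN and excluded from the gap maxima.
    """
    d = np.asarray(decisions, dtype=int)
    y = np.asarray(labels, dtype=int)
    g = np.asarray(groups)
    rows = []
    for key in pd.unique(g):
        m = g == key
        pos, neg = (y[m] == 1), (y[m] == 0)
        tpr = float(d[m][pos].mean()) if pos.any() else np.nan
        fpr = float(d[m][neg].mean()) if neg.any() else np.nan
        rows.append((key, int(m.sum()), tpr, fpr))
    table = pd.DataFrame(rows, columns=["group", "n", "tpr", "fpr"])
    tprs = table["tpr"].dropna()
    fprs = table["fpr"].dropna()
    gaps = {
        "tpr_gap": float(tprs.max() - tprs.min()) if len(tprs) > 1 else 0.0,
        "fpr_gap": float(fprs.max() - fprs.min()) if len(fprs) > 1 else 0.0,
    }
    return table, gaps


def intersectional_groups(sensitive: pd.DataFrame,
                          attributes: tuple[str, ...] = ("female", "medicare",
                                                         "medicaid")) -> pd.Series:
    """Cartesian group key over the sensitive attributes (up to 2^k groups)."""
    return sensitive[list(attributes)].astype(int).astype(str).agg("|".join, axis=1)
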
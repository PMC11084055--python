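"""Bias detection: score-distribution tests and propensity-score matching.

For each sensitive attribute (female, Medicare, Medicaid) the audit first
tests whether predicted risk differs between the groups (two-sided
Mann-Whitney U), then quantifies the attribute's effect on the combined
endpoint by 1:1 nearest-neighbour propensity-score matching without
replacement: a logistic regression of the attribute on the covariates gives
the propensity, units are matched on the logit propensity, balance is
checked via standardized mean differences (SMD < 0.2), and the average
treatment effect is the matched-pair mean outcome difference with a seeded
bootstrap CI over pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit
from sklearn.linear_model import LogisticRegression

SMD_THRESHOLD = 0.2


@dataclass
class PSMResult:
    """Outcome of one propensity-matching analysis."""

    treatment: str
    pairs: pd.DataFrame              # treated_id, control_id, treated/control logit
    propensity_coef: pd.Series
    smd_before: pd.Series
    smd_after: pd.Series
    ate: float
    ate_ci: tuple[float, float]
    n_treated: int
    n_control: int
    logit_propensity: pd.Series      # per unit, for distribution plots
    balanced: bool


def mannwhitney_by_group(scores, group_flag) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of scores between the two subgroups.

    Returns (U statistic for the flagged group, p-value). Ties are handled
    by the normal approximation with tie correction; two identical constant
    groups yield p = 1.
    """
    s = np.asarray(scores, dtype=float)
    g = np.asarray(group_flag, dtype=bool)
    a, b = s[g], s[~g]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(s == s[0]):  # all tied: no information, U at its midpoint
        return float(a.size * b.size / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def standardized_mean_difference(x_t: np.ndarray, x_c: np.ndarray) -> float:
    """Difference in means over the pooled standard deviation."""
    num = x_t.mean() - x_c.mean()
    denom = np.sqrt((x_t.var(ddof=1) + x_c.var(ddof=1)) / 2.0)
    if denom == 0:
        return 0.0 if num == 0 else np.inf
    return float(num / denom)


def _greedy_match(focal: np.ndarray, pool: np.ndarray,
                  order: np.ndarray) -> np.ndarray:
    """1-D greedy nearest-neighbour matching without replacement.

    ``focal``/``pool`` are logit propensities; returns for each focal index
    (in input order) the matched pool index. Uses a sorted doubly-linked
    skip structure, O((n+m) log m).
    """
    sort_idx = np.argsort(pool, kind="stable")
    sorted_pool = pool[sort_idx]
    m = sorted_pool.size
    # Union-find skip pointers: next unused position at or right of i
    # (sentinel m = none), and at or left of i (stored shifted by 1,
    # sentinel 0 = none).
    nxt = list(range(m + 1))
    prv = list(range(m + 2))

    def find_r(i):
        root = i
        while nxt[root] != root:
            root = nxt[root]
        while nxt[i] != root:
            nxt[i], i = root, nxt[i]
        return root

    def find_l(i):  # i is shifted by +1
        root = i
        while prv[root] != root:
            root = prv[root]
        while prv[i] != root:
            prv[i], i = root, prv[i]
        return root

    out = np.full(focal.size, -1, dtype=int)
    insert = np.searchsorted(sorted_pool, focal)
    for f in order:
        v = focal[f]
        r = find_r(min(insert[f], m))
        l = find_l(insert[f]) - 1  # unshifted; -1 means none
        if r >= m and l < 0:
            break  # pool exhausted
        if l < 0 or (r < m and abs(sorted_pool[r] - v) < abs(v - sorted_pool[l])):
            pick = r
        else:
            pick = l
        nxt[pick] = pick + 1
        prv[pick + 1] = pick
        out[f] = sort_idx[pick]
    return out


def propensity_match(x: pd.DataFrame, treatment: pd.Series, *, seed: int = 0,
                     treatment_name: str = "treatment",
                     smd_threshold: float = SMD_THRESHOLD) -> PSMResult:
    """Estimate the propensity model and build 1:1 matched pairs.

    The covariates must exclude the treatment flag and the outcome. Matching
    is greedy nearest-neighbour on the logit propensity, without replacement;
    the smaller arm is matched into the larger, and the processing order is
    randomized under the seed (greedy matching is order-dependent). A
    post-match SMD above the threshold for any covariate triggers a warning.
    """
    if treatment_name in x.columns:
        raise ValueError("covariates must exclude the treatment flag")
    t = np.asarray(treatment, dtype=int)
    if t.min() == t.max():
        raise ValueError("treatment must have both levels")
    rng = np.random.default_rng(seed)
    xv = x.to_numpy(dtype=float)
    mu, sd = xv.mean(axis=0), xv.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (xv - mu) / sd
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(xs, t)
    p = np.clip(clf.predict_proba(xs)[:, 1], 1e-12, 1 - 1e-12)
    lp = logit(p)
    if lp[t == 1].min() > lp[t == 0].max() or lp[t == 0].min() > lp[t == 1].max():
        raise ValueError("no overlap between the propensity distributions; "
                         "matching is infeasible")

    treated_idx = np.flatnonzero(t == 1)
    control_idx = np.flatnonzero(t == 0)
    swap = treated_idx.size > control_idx.size
    focal_idx, pool_idx = (control_idx, treated_idx) if swap \
        else (treated_idx, control_idx)
    order = rng.permutation(focal_idx.size)
    match_pos = _greedy_match(lp[focal_idx], lp[pool_idx], order)
    ok = match_pos >= 0
    focal_sel = focal_idx[ok]
    pool_sel = pool_idx[match_pos[ok]]
    t_ids, c_ids = (pool_sel, focal_sel) if swap else (focal_sel, pool_sel)

    index = np.asarray(x.index)
    pairs = pd.DataFrame({
        "treated_id": index[t_ids], "control_id": index[c_ids],
        "treated_logit": lp[t_ids], "control_logit": lp[c_ids]})

    smd_before = pd.Series({c: standardized_mean_difference(
        xv[t == 1, j], xv[t == 0, j]) for j, c in enumerate(x.columns)})
    smd_after = pd.Series({c: standardized_mean_difference(
        xv[t_ids, j], xv[c_ids, j]) for j, c in enumerate(x.columns)})
    balanced = bool((smd_after.abs() < smd_threshold).all())
    if not balanced:
        worst = smd_after.abs().idxmax()
        warnings.warn(f"post-match SMD above {smd_threshold} for {worst!r} "
                      f"({smd_after[worst]:.3f})", stacklevel=2)
    return PSMResult(
        treatment=treatment_name, pairs=pairs,
        propensity_coef=pd.Series(clf.coef_.ravel(), index=x.columns),
        smd_before=smd_before, smd_after=smd_after,
        ate=np.nan, ate_ci=(np.nan, np.nan),
        n_treated=int(treated_idx.size), n_control=int(control_idx.size),
        logit_propensity=pd.Series(lp, index=x.index), balanced=balanced)


def average_treatment_effect(result: PSMResult, outcome: pd.Series, *,
                             n_boot: int = 1000, seed: int = 0) -> PSMResult:
    """Matched-pair mean outcome difference (treated − control) with a
    seeded percentile-bootstrap CI over pairs; stored back on the result."""
    if len(result.pairs) == 0:
        raise ValueError("no matched pairs")
    d = (outcome.loc[result.pairs["treated_id"]].to_numpy(dtype=float)
         - outcome.loc[result.pairs["control_id"]].to_numpy(dtype=float))
    ate = float(d.mean())
    rng = np.random.default_rng(seed)
    boots = [d[rng.integers(0, d.size, d.size)].mean() for _ in range(n_boot)]
    result.ate = ate
    result.ate_ci = tuple(np.percentile(boots, [2.5, 97.5]))
    return result


def audit_attribute(features: pd.DataFrame, sensitive: pd.Series,
                    outcome: pd.Series, scores: pd.Series | None = None, *,
                    seed: int = 0, n_boot: int = 1000,
                    effect_on: str = "outcome") -> dict:
    """Full audit for one sensitive attribute: Mann-Whitney on predicted
    scores (when given) plus PSM and the ATE on the outcome (or on predicted
    scores with ``effect_on='score'``)."""
    out: dict = {"attribute": sensitive.name}
    if scores is not None:
        u, p = mannwhitney_by_group(scores.loc[features.index], sensitive)
        out["mannwhitney_u"], out["mannwhitney_p"] = u, p
    res = propensity_match(features, sensitive, seed=seed,
                           treatment_name=str(sensitive.name))
    target = outcome if effect_on == "outcome" else scores
    res = average_treatment_effect(res, target, n_boot=n_boot, seed=seed)
    out["psm"] = res
    return out
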
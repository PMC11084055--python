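"""Feature-selection cascade: each stage against closed-form or simulation
oracles, plus ledger replay."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from tjarisk.selection import (
    AdaptiveLassoConfig,
    adaptive_lasso,
    adaptive_weights,
    box_cox,
    box_cox_transform,
    box_tidwell,
    compute_vif,
    compute_vif_pairwise,
    drop_high_missingness,
    flag_outlier_cases,
    impute_missing,
    run_selection,
)


class TestMissingness:
    def test_strict_threshold_boundary(self):
        n = 100
        df = pd.DataFrame({
            "drop_me": [np.nan] * 71 + [1.0] * 29,     # 71% missing
            "keep_me": [np.nan] * 70 + [1.0] * 30,     # exactly 70%
            "full": np.ones(n),
        })
        out, report = drop_high_missingness(df)
        assert list(out.columns) == ["keep_me", "full"]
        assert report.loc["drop_me", "dropped"]
        assert report.loc["drop_me", "missing_frac"] == pytest.approx(0.71)

    def test_fully_observed_matrix_is_identity(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        out, _ = drop_high_missingness(df)
        pd.testing.assert_frame_equal(out, df)


class TestOutliers:
    def _clean(self, rng, n=1000):
        x = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        y = pd.Series(1.0 + 2 * x["x1"] - x["x2"] + rng.normal(0, 1, n))
        return x, y

    def test_clean_linear_data_flags_almost_nothing(self):
        # Gaussian errors put ~0.27% of residuals beyond 3 SDs, so the
        # conjunction rule flags a handful of cases at most; the flagged
        # share stays far below the 1% ballpark seen on real cohorts.
        counts = []
        for s in range(5):
            rng = np.random.default_rng(s)
            x, y = self._clean(rng)
            ids, _ = flag_outlier_cases(x, y)
            counts.append(len(ids))
        assert max(counts) <= 8
        assert np.mean(counts) < 5

    def test_planted_gross_outlier_is_flagged_and_matches_closed_form(self, rng):
        x, y = self._clean(rng, n=400)
        x.loc[0, "x1"] = 6.0          # high leverage
        y.loc[0] = 60.0               # gross y outlier
        ids, report = flag_outlier_cases(x, y)
        assert 0 in ids
        # closed-form single-point check: D_i = r_i^2/p * h_ii/(1-h_ii)
        design = np.column_stack([np.ones(len(x)), x.to_numpy()])
        hat = design @ np.linalg.inv(design.T @ design) @ design.T
        h = np.diag(hat)
        resid = y.to_numpy() - hat @ y.to_numpy()
        p = design.shape[1]
        mse = (resid**2).sum() / (len(x) - p)
        r_int = resid / np.sqrt(mse * (1 - h))
        cooks = r_int**2 * h / ((1 - h) * p)
        assert report.loc[0, "cooks_distance"] == pytest.approx(cooks[0])
        assert report.loc[0, "std_residual"] == pytest.approx(r_int[0])

    def test_threshold_is_strictly_greater_than(self, rng):
        x, y = self._clean(rng, n=300)
        x.loc[0, "x1"] = 5.0
        y.loc[0] = 40.0
        _, report = flag_outlier_cases(x, y)
        r0 = abs(report.loc[0, "std_residual"])
        # with the cutoff raised to the exact residual, "larger than" fails
        ids, _ = flag_outlier_cases(x, y, resid_cutoff=r0)
        assert 0 not in ids
        ids, _ = flag_outlier_cases(x, y, resid_cutoff=r0 - 1e-9)
        assert 0 in ids

    def test_singular_design_names_collinear_columns(self, rng):
        x = pd.DataFrame({"a": rng.normal(size=50)})
        x["b"] = 2 * x["a"]
        with pytest.raises(ValueError, match="collinear"):
            flag_outlier_cases(x, pd.Series(rng.normal(size=50)))

    def test_excess_removal_triggers_warning(self, rng):
        x, y = self._clean(rng, n=200)
        with pytest.warns(UserWarning, match="outlier stage removed"):
            flag_outlier_cases(x, y, cooks_multiplier=1e9, resid_cutoff=0.0,
                               rule="or", max_fraction=0.01)


class TestVIF:
    def test_orthogonal_columns_have_unit_vif(self):
        # columns orthogonal to each other *and* to the intercept
        raw = np.random.default_rng(1).normal(size=(60, 5))
        raw[:, 0] = 1.0
        q, _ = np.linalg.qr(raw)
        df = pd.DataFrame(q[:, 1:], columns=list("abcd"))
        _, table = compute_vif(df)
        assert np.allclose(table["vif"], 1.0, atol=1e-6)

    def test_closed_form_for_exact_correlation(self, rng):
        # construct exact sample correlation 0.6: VIF = 1/(1-0.36) = 1.5625
        z = rng.normal(size=(500, 2))
        z -= z.mean(axis=0)
        q, _ = np.linalg.qr(z)
        u, v = q[:, 0], q[:, 1]
        x2 = 0.6 * u + 0.8 * v
        df = pd.DataFrame({"x1": u, "x2": x2})
        _, table = compute_vif(df)
        assert table["vif"].to_numpy() == pytest.approx([1.5625, 1.5625])

    def test_duplicated_column_is_infinite_and_removed(self, rng):
        a = rng.normal(size=80)
        df = pd.DataFrame({"a": a, "dup": a, "b": rng.normal(size=80)})
        pruned, table = compute_vif(df)
        assert np.isinf(table.loc["a", "vif"]) and np.isinf(table.loc["dup", "vif"])
        assert list(pruned.columns) == ["b"]

    def test_vif_never_below_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 6)),
                          columns=[f"f{i}" for i in range(6)])
        _, table = compute_vif(df)
        assert (table["vif"] >= 1.0 - 1e-9).all()

    def test_pairwise_variant_agrees_on_complete_data(self, rng):
        df = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
        df["d"] = 0.8 * df["a"] + 0.6 * df["b"] + 0.1 * df["d"]
        _, full = compute_vif(df)
        _, pw = compute_vif_pairwise(df)
        assert np.allclose(full["vif"], pw["vif"], rtol=1e-6)


class TestImputation:
    def test_complete_matrix_is_identity(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        out, info = impute_missing(df, seed=0)
        pd.testing.assert_frame_equal(out, df)
        assert info["imputed_values"] == {}

    def test_categorical_missing_becomes_unknown_level(self, rng):
        df = pd.DataFrame({"flag": [1.0, 0.0, np.nan, np.nan, 1.0],
                           "x": rng.normal(size=5)})
        out, info = impute_missing(df, seed=0, categorical_cols=["flag"])
        assert "flag_unknown" in out.columns
        assert out["flag_unknown"].tolist() == [0, 0, 1, 1, 0]
        assert out["flag"].isna().sum() == 0

    def test_rf_imputation_beats_mean_imputation_on_planted_signal(self, rng):
        n = 800
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        target = 2 * a - b + rng.normal(0, 0.3, n)
        df = pd.DataFrame({"a": a, "b": b, "t": target})
        mask = rng.uniform(size=n) < 0.3
        truth = df.loc[mask, "t"].copy()
        df.loc[mask, "t"] = np.nan
        out, info = impute_missing(df, seed=0)
        rmse_rf = np.sqrt(((out.loc[mask, "t"] - truth) ** 2).mean())
        rmse_mean = np.sqrt(((truth - df["t"].mean()) ** 2).mean())
        assert rmse_rf < rmse_mean
        assert "t" in info["imputed_values"]

    def test_all_missing_column_is_an_error(self):
        df = pd.DataFrame({"x": [np.nan, np.nan], "y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="no observed values"):
            impute_missing(df, seed=0)

    def test_bmi_indicator_column(self, rng):
        df = pd.DataFrame({"bmi": [30.0, np.nan, 28.0, np.nan],
                           "x": rng.normal(size=4)})
        out, info = impute_missing(df, seed=0)
        assert out["imputed_bmi"].tolist() == [0, 1, 0, 1]


class TestBoxTidwellAndBoxCox:
    def test_zero_containing_feature_is_shifted_not_fatal(self, rng):
        n = 500
        x = pd.DataFrame({"counts": rng.poisson(1.0, n).astype(float)})
        y = pd.Series((rng.uniform(size=n) < 0.3).astype(int))
        table = box_tidwell(x, y)
        assert table["tested"].all()
        assert table.loc[0, "shift"] == 1.0

    def test_box_cox_formula_identities(self):
        x = np.array([1.0, 2.0, 3.0])
        assert box_cox_transform(x, 1.0) == pytest.approx(x - 1)
        assert box_cox_transform(x, 0.0) == pytest.approx(np.log(x))
        with pytest.raises(ValueError):
            box_cox_transform(np.array([0.0, 1.0]), 0.5)

    def test_box_cox_mle_recovers_log_for_lognormal(self, rng):
        x = np.exp(rng.normal(0, 0.6, size=5000))
        _, lam = box_cox(x)
        assert abs(lam) < 0.1


class TestAdaptiveLasso:
    def test_weight_formula(self):
        assert adaptive_weights(np.array([1.0]), 0.75)[0] == pytest.approx(1.0)
        assert adaptive_weights(np.array([16.0]), 0.75)[0] == pytest.approx(0.125)
        # near-zero initial coefficient hits the cap
        assert adaptive_weights(np.array([1e-12]), 2.0)[0] == pytest.approx(1e6)

    def test_gamma_to_zero_reduces_to_plain_lasso(self, rng):
        n, p = 600, 12
        x = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"f{i}" for i in range(p)])
        eta = 1.2 * x["f0"] - 0.9 * x["f1"] + 0.7 * x["f2"]
        y = pd.Series((rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int))
        cfg = AdaptiveLassoConfig(gamma=1e-9, seed=0)
        selected, coefs, diag = adaptive_lasso(x, y, cfg)
        # plain lasso with the same standardization, folds and grid
        xs = (x - x.mean()) / x.std(ddof=0)
        cv = StratifiedKFold(5, shuffle=True, random_state=0)
        plain = LogisticRegressionCV(Cs=list(cfg.lasso_cs), cv=cv, penalty="l1",
                                     solver="liblinear", scoring="neg_log_loss",
                                     max_iter=2000, random_state=0)
        plain.fit(xs.to_numpy(), y.to_numpy())
        plain_sel = list(x.columns[plain.coef_.ravel() != 0])
        assert selected == plain_sel

    def test_all_zero_solution_raises_actionable_error(self, rng):
        n = 200
        x = pd.DataFrame(rng.normal(size=(n, 5)),
                         columns=[f"f{i}" for i in range(5)])
        y = pd.Series(rng.integers(0, 2, n))
        cfg = AdaptiveLassoConfig(gamma=0.75, lasso_cs=(1e-6,), seed=0)
        with pytest.raises(ValueError, match="penalty grid"):
            adaptive_lasso(x, y, cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            AdaptiveLassoConfig(gamma_grid=(0.0, 1.0))
        with pytest.raises(ValueError):
            AdaptiveLassoConfig(weight_cap=np.inf)


class TestCascade:
    def _matrix(self, rng, n=500):
        x = pd.DataFrame({
            "age": rng.normal(65, 10, n),
            "count": rng.poisson(1.0, n).astype(float),
            "lab": rng.normal(1.0, 0.2, n),
            "sparse_lab": np.where(rng.uniform(size=n) < 0.8, np.nan,
                                   rng.normal(size=n)),
            "flag": rng.integers(0, 2, n).astype(float),
        }, index=[f"C{i}" for i in range(n)])
        x["lab_dup"] = x["lab"] * 2.0 + 1e-9 * rng.normal(size=n)
        x.loc[rng.uniform(size=n) < 0.2, "lab"] = np.nan
        eta = 0.04 * (x["age"] - 65) + 0.5 * x["count"] - 1.8
        y = pd.Series((rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int),
                      index=x.index)
        return x, y

    def test_pipeline_order_and_replay_reproduces_output(self, rng):
        x, y = self._matrix(rng)
        cfg = AdaptiveLassoConfig(gamma=0.75, seed=0)
        out, report = run_selection(
            x, y, continuous_cols=["age", "count", "lab", "sparse_lab",
                                   "lab_dup"],
            categorical_cols=["flag"], seed=0, lasso_config=cfg)
        assert [s["stage"] for s in report.stages] == [
            "missingness", "outliers", "vif", "imputation", "box_tidwell",
            "box_cox", "adaptive_lasso"]
        assert "sparse_lab" in report.stage("missingness")["dropped"]
        replayed = report.replay(x)
        pd.testing.assert_frame_equal(replayed[out.columns], out)
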
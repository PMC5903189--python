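"""Sum-contrast regression, outlier refit, contrast CIs and classification."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given
from hypothesis import strategies as hst

from forestcarbon import factors as fm
from forestcarbon.simulate import SimulationConfig, simulate_subplot_outcomes


def ols_oracle(y, X):
    """Independent normal-equations OLS: (XᵀX)⁻¹Xᵀy with t inference."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    s2 = resid @ resid / (n - p)
    se = np.sqrt(np.diag(xtx_inv) * s2)
    tvals = beta / se
    pvals = 2 * st.t.sf(np.abs(tvals), n - p)
    tss = ((y - y.mean()) ** 2).sum()
    r2 = 1 - (resid @ resid) / tss
    adj = 1 - (1 - r2) * (n - 1) / (n - p)
    return beta, se, pvals, r2, adj, xtx_inv, s2


class TestCategorize:
    sv = fm.DEFAULT_CATEGORY_SPECS["stem_volume"]
    dbh = fm.DEFAULT_CATEGORY_SPECS["dbh"]
    tn = fm.DEFAULT_CATEGORY_SPECS["tree_count"]

    @pytest.mark.parametrize(
        "value, expected",
        [(150.0, "sv_mid"), (91.0, "sv_mid"), (199.0, "sv_mid"),
         (90.99, "sv_low"), (199.01, "sv_high")],
    )
    def test_stem_volume_inclusive_middle(self, value, expected):
        assert fm.categorize(value, self.sv) == expected

    def test_dbh_top_level(self):
        assert fm.categorize(43.5, self.dbh) == "dbh_high"
        assert fm.categorize(43.4, self.dbh) == "dbh_mid"

    def test_tree_count_split_at_twenty(self):
        assert fm.categorize(19, self.tn) == "tn_lt20"
        assert fm.categorize(20, self.tn) == "tn_ge20"

    def test_missing_value_excluded(self):
        assert fm.categorize(float("nan"), self.sv) is None
        df = pd.DataFrame(
            {
                "stem_volume_m3_ha": [100.0, np.nan],
                "mean_dbh_cm": [30.0, 30.0],
                "tree_count": [10, 10],
                "altitude_m": [400.0, 400.0],
                "region": ["C", "C"],
                "ownership": ["community", "other"],
            }
        )
        with pytest.warns(UserWarning, match="missing"):
            levels = fm.build_levels(df)
        assert len(levels) == 1

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            fm.CategorySpec("x", (2.0, 1.0), ("a", "b", "c"))
        with pytest.raises(ValueError):
            fm.CategorySpec("x", (1.0,), ("a", "b", "c"))


def _toy_levels(n=12, rng=None):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame(
        {
            "f1": np.tile(["a", "b", "c"], n // 3),
            "f2": np.repeat(["x", "y"], n // 2),
        }
    )


class TestSumContrastDesign:
    def test_columns_and_coding(self):
        levels = _toy_levels()
        X, meta = fm.sum_contrast_design(levels, {"f1": ["a", "b", "c"], "f2": ["x", "y"]})
        assert list(X.columns) == ["Intercept", "f1[a]", "f1[b]", "f2[x]"]
        row_c = X.loc[levels["f1"] == "c"]
        assert (row_c["f1[a]"] == -1).all() and (row_c["f1[b]"] == -1).all()

    def test_effects_sum_to_zero_after_fit(self, rng):
        levels = _toy_levels(24)
        X, meta = fm.sum_contrast_design(levels)
        y = rng.normal(50, 5, len(X))
        fit = fm.fit_ols(y, X, meta)
        for factor in meta:
            assert abs(fm.level_effects(fit, factor).sum()) < 1e-10

    def test_balanced_two_level_intercept_is_grand_level_mean(self, rng):
        # 12-row toy: compare with a one-hot (cell-means) OLS oracle
        levels = pd.DataFrame({"f": np.repeat(["u", "v"], 6)})
        y = rng.normal(10, 2, 12)
        X, meta = fm.sum_contrast_design(levels, {"f": ["u", "v"]})
        fit = fm.fit_ols(y, X, meta)
        onehot = np.column_stack([(levels["f"] == "u"), (levels["f"] == "v")]).astype(float)
        mu = np.linalg.lstsq(onehot, y, rcond=None)[0]
        assert fit.params["Intercept"] == pytest.approx(mu.mean(), rel=1e-10)
        assert fit.params["f[u]"] == pytest.approx((mu[0] - mu[1]) / 2, rel=1e-10)

    def test_single_level_factor_dropped(self):
        levels = pd.DataFrame({"f1": ["a", "a", "a"], "f2": ["x", "y", "x"]})
        with pytest.warns(UserWarning, match="one level"):
            X, meta = fm.sum_contrast_design(levels)
        assert "f1" not in meta

    def test_adjusted_means_invariant_under_level_reordering(self, rng):
        levels = _toy_levels(30, rng)
        y = pd.Series(rng.normal(60, 8, len(levels)))
        for orders in ({"f1": ["a", "b", "c"]}, {"f1": ["c", "a", "b"]}):
            X, meta = fm.sum_contrast_design(levels, orders)
            fit = fm.fit_ols(y, X, meta)
            cis = fm.contrast_cis(fit, "f1", levels, y).set_index("level")
            if orders["f1"][0] == "a":
                base = cis
            else:
                for lev in "abc":
                    assert cis.loc[lev, "adjusted_mean"] == pytest.approx(
                        base.loc[lev, "adjusted_mean"], rel=1e-10
                    )
                    assert cis.loc[lev, "ci_low"] == pytest.approx(
                        base.loc[lev, "ci_low"], rel=1e-10
                    )


class TestFitOls:
    def test_perfect_fit(self):
        X = pd.DataFrame({"Intercept": np.ones(10), "x": np.arange(10.0)})
        y = 3.0 + 2.0 * X["x"]
        fit = fm.fit_ols(y, X)
        assert fit.rsquared_adj == pytest.approx(1.0)
        assert np.allclose(fit.resid, 0.0, atol=1e-10)

    def test_matches_normal_equations_on_random_toys(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 51))
            p = int(rng.integers(2, min(6, n - 2)))
            X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
            X.insert(0, "Intercept", 1.0)
            y = rng.normal(size=n)
            fit = fm.fit_ols(y, X)
            beta, se, pvals, r2, adj, *_ = ols_oracle(y, X)
            assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)
            assert np.allclose(fit.bse.to_numpy(), se, atol=1e-8)
            assert np.allclose(fit.pvalues.to_numpy(), pvals, atol=1e-8)
            assert fit.rsquared_adj == pytest.approx(adj, abs=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        X = pd.DataFrame({"Intercept": np.ones(20), "a": rng.normal(size=20)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="rank deficient"):
            fm.fit_ols(rng.normal(size=20), X)

    def test_more_columns_than_rows_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(3, 4)))
        with pytest.raises(ValueError, match="observations"):
            fm.fit_ols(np.zeros(3), X)


class TestQQResiduals:
    def test_gaussian_residuals_follow_diagonal(self):
        rng = np.random.default_rng(42)
        theo, ordered = fm.qq_residuals(rng.normal(0, 1, 10_000))
        central = (theo > np.quantile(theo, 0.01)) & (theo < np.quantile(theo, 0.99))
        assert np.max(np.abs(theo[central] - ordered[central])) < 0.1

    def test_symmetric_set_symmetric_about_origin(self):
        r = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        theo, ordered = fm.qq_residuals(r)
        assert np.allclose(ordered, -ordered[::-1])
        assert np.allclose(theo, -theo[::-1])

    def test_constant_residuals_no_error(self):
        theo, ordered = fm.qq_residuals(np.full(10, 2.5))
        assert np.allclose(ordered, 0.0)


class TestOutlierRefit:
    def test_no_outliers_is_a_no_op(self, rng):
        X = pd.DataFrame({"Intercept": np.ones(50), "x": rng.normal(size=50)})
        y = pd.Series(5 + rng.normal(0, 1, 50))
        res = fm.outlier_refit(y, X, threshold=40.0)
        assert res.n_removed == 0
        assert res.final_fit.params.equals(res.first_fit.params)

    def test_planted_outliers_removed_exactly(self):
        """10 planted +60 shifts at n = 300 with moderate noise: all and only
        the planted records exceed the +40 residual rule."""
        cfg = SimulationConfig(
            n_subplot_records=300, n_outliers=10, carbon_noise_sd=8.0
        )
        df, truth = simulate_subplot_outcomes(cfg, 42)
        levels = fm.build_levels(df)
        X, meta = fm.sum_contrast_design(levels)
        res = fm.outlier_refit(df["carbon_tC_ha"], X, threshold=40.0, factor_levels=meta)
        removed_ids = sorted(df.loc[res.removed_index, "subplot_id"])
        assert removed_ids == truth["outlier_subplot_ids"]
        assert res.final_fit.nobs == 290

    def test_one_sided_rule_keeps_low_outliers(self, rng):
        X = pd.DataFrame({"Intercept": np.ones(100)})
        y = pd.Series(np.zeros(100))
        y.iloc[0] = 80.0
        y.iloc[1] = -80.0
        one = fm.outlier_refit(y, X, threshold=40.0)
        two = fm.outlier_refit(y, X, threshold=40.0, two_sided=True)
        assert one.n_removed == 1
        assert two.n_removed == 2

    def test_emptied_level_aborts(self):
        # both members of level b lie far above an intercept-only fit, so
        # removing them would leave the level unrepresented
        levels = pd.DataFrame({"f": ["a"] * 10 + ["b"] * 2})
        X = pd.DataFrame({"Intercept": np.ones(12)})
        y = pd.Series([10.0] * 10 + [200.0, 210.0])
        with pytest.raises(ValueError, match="empties"):
            fm.outlier_refit(y, X, threshold=40.0, levels=levels)

    def test_invalid_threshold(self):
        X = pd.DataFrame({"Intercept": np.ones(5)})
        with pytest.raises(ValueError):
            fm.outlier_refit(pd.Series(np.zeros(5)), X, threshold=0.0)


class TestContrastCIs:
    def test_balanced_single_factor_adjusted_equals_crude(self, rng):
        levels = pd.DataFrame({"f": np.repeat(["a", "b", "c"], 10)})
        y = pd.Series(rng.normal(50, 5, 30))
        X, meta = fm.sum_contrast_design(levels, {"f": ["a", "b", "c"]})
        fit = fm.fit_ols(y, X, meta)
        cis = fm.contrast_cis(fit, "f", levels, y)
        for _, row in cis.iterrows():
            assert row["adjusted_mean"] == pytest.approx(row["crude_mean"], rel=1e-10)
            assert row["ci_low"] <= row["adjusted_mean"] <= row["ci_high"]

    def test_ci_matches_linear_combination_oracle(self, rng):
        levels = _toy_levels(30, rng)
        y = rng.normal(60, 8, 30)
        X, meta = fm.sum_contrast_design(levels)
        fit = fm.fit_ols(y, X, meta)
        beta, se, pvals, r2, adj, xtx_inv, s2 = ols_oracle(y, X)
        cols = list(X.columns)
        order = meta["f1"]
        for i, lev in enumerate(order):
            c = np.zeros(len(cols))
            c[cols.index("Intercept")] = 1.0
            if lev == order[-1]:
                for other in order[:-1]:
                    c[cols.index(f"f1[{other}]")] = -1.0
            else:
                c[cols.index(f"f1[{lev}]")] = 1.0
            est = c @ beta
            half = st.t.ppf(0.975, len(y) - len(cols)) * np.sqrt(c @ xtx_inv @ c * s2)
            row = fm.contrast_cis(fit, "f1", levels, y).iloc[i]
            assert row["adjusted_mean"] == pytest.approx(est, abs=1e-10)
            assert row["ci_low"] == pytest.approx(est - half, abs=1e-10)
            assert row["ci_high"] == pytest.approx(est + half, abs=1e-10)

    def test_level_effects_recover_reference(self, outcome_dataset):
        df, truth = outcome_dataset
        analysis = fm.fit_factor_model(df)
        for factor in analysis.contrasts:
            eff = fm.level_effects(analysis.final_fit, factor)
            assert abs(eff.sum()) < 1e-10


class TestClassifyCI:
    @pytest.mark.parametrize(
        "lo, hi, mean, expected",
        [
            (80, 90, 75, "above"),
            (70, 80, 75, "around"),
            (60, 70, 75, "below"),
            (75, 80, 75, "around"),  # endpoint equal to the mean
            (70, 75, 75, "around"),
        ],
    )
    def test_trichotomy(self, lo, hi, mean, expected):
        assert fm.classify_ci(lo, hi, mean) == expected

    @given(
        hst.floats(min_value=-100, max_value=100),
        hst.floats(min_value=0, max_value=50),
        hst.floats(min_value=-100, max_value=100),
    )
    def test_exhaustive_and_exclusive(self, lo, width, mean):
        out = fm.classify_ci(lo, lo + width, mean)
        assert out in {"above", "around", "below"}
        # exclusivity: exactly one rule fires
        fires = [lo > mean, lo + width < mean]
        assert sum(fires) <= 1


def test_fit_factor_model_end_to_end(outcome_dataset):
    df, truth = outcome_dataset
    analysis = fm.fit_factor_model(df)
    assert analysis.final_fit.nobs == len(df) - analysis.n_removed
    assert analysis.final_fit.rsquared_adj <= analysis.final_fit.rsquared
    assert abs(analysis.final_fit.resid.sum()) < 1e-6
    # the coefficient table mirrors the fitted factors
    tbl = analysis.coefficients
    assert set(tbl["variable"]) == {"Intercept", *analysis.final_fit.factor_levels}
    # contrasts exist for every factor and carry a classification
    for factor, cis in analysis.contrasts.items():
        assert set(cis["classification"]) <= {"above", "around", "below"}
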
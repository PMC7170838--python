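"""Lasso screening, AICc, exhaustive sweep search, univariate scan, ANOVA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import orawave as ow
from orawave import selection as S
from orawave.errors import DegenerateFitError, SaturationError


def _gaussian_design(n, k, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, k)),
                        columns=[f"x{i}" for i in range(k)]), rng


class TestAICc:
    def test_hand_arithmetic_value(self):
        # n ln(2 pi rss / n) + n + 2p + 2p(p+1)/(n-p-1) at n=20, rss=10, p=4
        assert S.aicc(20, 10.0, 2) == pytest.approx(53.56126438365467, abs=1e-9)

    def test_extra_slope_with_same_rss_increases_aicc(self):
        assert S.aicc(50, 20.0, 3) > S.aicc(50, 20.0, 2)

    def test_correction_vanishes_for_large_n(self):
        n = 10_000_000
        aic = n * math.log(2 * math.pi * 5.0 / n) + n + 2 * 4
        assert S.aicc(n, 5.0, 2) == pytest.approx(aic, abs=1e-4)

    def test_zero_rss_rejected(self):
        with pytest.raises(DegenerateFitError):
            S.aicc(20, 0.0, 2)

    def test_saturated_model_rejected(self):
        with pytest.raises(SaturationError):
            S.aicc(6, 1.0, 3)   # n - p - 1 = 0


class TestOLSFit:
    def test_matches_statsmodels(self):
        statsmodels_api = pytest.importorskip("statsmodels.api")
        X, rng = _gaussian_design(80, 4, seed=3)
        y = pd.Series(1.0 + 2 * X["x0"].to_numpy() - X["x2"].to_numpy()
                      + rng.normal(size=80))
        fit = S.ols_fit(X, y, ["x0", "x2"])
        sm_fit = statsmodels_api.OLS(
            y, statsmodels_api.add_constant(X[["x0", "x2"]])).fit()
        assert fit.coefficients["x0"] == pytest.approx(sm_fit.params["x0"],
                                                       rel=1e-9)
        assert fit.std_errors["x2"] == pytest.approx(sm_fit.bse["x2"], rel=1e-9)
        assert fit.p_values["x0"] == pytest.approx(sm_fit.pvalues["x0"],
                                                   rel=1e-6, abs=1e-12)
        assert fit.rss == pytest.approx(sm_fit.ssr, rel=1e-12)
        assert fit.loglik == pytest.approx(sm_fit.llf, rel=1e-9)


class TestLassoScreen:
    def test_planted_strong_predictors_survive(self):
        for seed in range(10):
            X, rng = _gaussian_design(200, 30, seed=seed)
            y = pd.Series(4 * X["x0"].to_numpy() - 3 * X["x7"].to_numpy()
                          + 5 * X["x19"].to_numpy() + rng.normal(size=200))
            got = set(S.lasso_screen(X, y, k=10))
            assert {"x0", "x7", "x19"} <= got, seed

    def test_exactly_k_returned(self):
        X, rng = _gaussian_design(100, 41, seed=1)
        y = pd.Series(rng.normal(size=100) + X["x1"].to_numpy())
        assert len(S.lasso_screen(X, y, k=20)) == 20

    def test_k_equals_columns_returns_all(self):
        X, rng = _gaussian_design(50, 6, seed=2)
        y = pd.Series(rng.normal(size=50))
        assert set(S.lasso_screen(X, y, k=6)) == set(X.columns)

    def test_k_too_large_rejected(self):
        X, rng = _gaussian_design(50, 6, seed=2)
        with pytest.raises(ValueError):
            S.lasso_screen(X, pd.Series(rng.normal(size=50)), k=7)

    def test_constant_column_dropped(self, caplog):
        X, rng = _gaussian_design(60, 5, seed=4)
        X["flat"] = 1.0
        y = pd.Series(rng.normal(size=60))
        got = S.lasso_screen(X, y, k=5)
        assert "flat" not in got


class TestExhaustiveSearch:
    def test_three_candidates_equal_naive_refits(self):
        X, rng = _gaussian_design(40, 3, seed=5)
        y = pd.Series(2 * X["x0"].to_numpy() + rng.normal(size=40))
        res = S.exhaustive_aicc_search(X, y, list(X.columns), top_k=8)
        assert res.n_models_evaluated == 8
        naive = {}
        for m in range(4):
            for sub in itertools.combinations(X.columns, m):
                A = np.column_stack([np.ones(40)] + [X[c] for c in sub])
                coef, *_ = np.linalg.lstsq(A, y.to_numpy(), rcond=None)
                rss = float(np.sum((y.to_numpy() - A @ coef) ** 2))
                naive[frozenset(sub)] = S.aicc(40, rss, len(sub))
        for row in res.aicc_table.itertuples():
            assert row.aicc == pytest.approx(naive[frozenset(row.subset)],
                                             abs=1e-8)
        assert res.best.aicc == pytest.approx(min(naive.values()), abs=1e-8)

    def test_sweep_equals_naive_at_p8(self):
        X, rng = _gaussian_design(90, 8, seed=6)
        y = pd.Series(X["x1"].to_numpy() - X["x4"].to_numpy()
                      + 0.5 * rng.normal(size=90))
        res = S.exhaustive_aicc_search(X, y, list(X.columns), top_k=256)
        table = {frozenset(r.subset): r.rss for r in res.aicc_table.itertuples()}
        for m in range(9):
            for sub in itertools.combinations(X.columns, m):
                A = np.column_stack([np.ones(90)] + [X[c] for c in sub])
                coef, *_ = np.linalg.lstsq(A, y.to_numpy(), rcond=None)
                rss = float(np.sum((y.to_numpy() - A @ coef) ** 2))
                assert rss == pytest.approx(table[frozenset(sub)], abs=1e-8)

    def test_planted_pair_recovered(self):
        X, rng = _gaussian_design(100, 12, seed=7)
        y = pd.Series(2 * X["x1"].to_numpy() - 3 * X["x2"].to_numpy()
                      + 0.3 * rng.normal(size=100))
        res = S.exhaustive_aicc_search(X, y, list(X.columns))
        assert {"x1", "x2"} <= set(res.best.subset)

    def test_empty_candidates_intercept_only(self):
        X, rng = _gaussian_design(30, 2, seed=8)
        y = pd.Series(rng.normal(size=30) + 5.0)
        res = S.exhaustive_aicc_search(X, y, [])
        assert res.n_models_evaluated == 1
        assert res.best.subset == ()
        assert res.best.coefficients["intercept"] == pytest.approx(y.mean())

    def test_best_aicc_is_table_minimum(self):
        X, rng = _gaussian_design(60, 6, seed=9)
        y = pd.Series(X["x0"].to_numpy() + rng.normal(size=60))
        res = S.exhaustive_aicc_search(X, y, list(X.columns), top_k=64)
        assert res.best.aicc == pytest.approx(res.aicc_table["aicc"].min(),
                                              abs=1e-8)

    def test_too_many_candidates_rejected(self):
        X, rng = _gaussian_design(40, 2, seed=0)
        with pytest.raises(ValueError):
            S.exhaustive_aicc_search(X, pd.Series(rng.normal(size=40)),
                                     [f"x{i}" for i in range(25)])


class TestUnivariateScan:
    def test_exact_relation(self):
        X = pd.DataFrame({"x": np.linspace(-2, 3, 30)})
        y = pd.Series(5.0 * X["x"].to_numpy())
        row = S.univariate_scan(X, y + 1e-9 * np.random.default_rng(0)
                                .normal(size=30)).iloc[0]
        assert row["coefficient"] == pytest.approx(5.0, rel=1e-6)
        assert row["p_value"] < 1e-12

    def test_row_per_column(self, small_cohort):
        averaged, _ = ow.average_replicates(
            ow.filter_by_quality(small_cohort.records))
        feats = {r.eye_id: ow.compute_features(r.trace) for r in averaged}
        design = ow.assemble_design_matrix(feats, small_cohort.covariates)
        table = S.univariate_scan(design.X, design.y)
        assert len(table) == design.X.shape[1]

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(10)
        pvals = []
        for _ in range(1000):
            x = rng.normal(size=40)
            y = rng.normal(size=40)
            table = S.univariate_scan(pd.DataFrame({"x": x}), pd.Series(y))
            pvals.append(table["p_value"].iloc[0])
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert 0.03 <= frac <= 0.07

    def test_constant_column_flagged(self):
        X = pd.DataFrame({"flat": np.ones(20)})
        y = pd.Series(np.random.default_rng(0).normal(size=20))
        table = S.univariate_scan(X, y)
        assert table.iloc[0]["flag"] == "constant"
        assert np.isnan(table.iloc[0]["coefficient"])


class TestNestedAnova:
    def test_strong_added_effect_has_power(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(100):
            X = pd.DataFrame(rng.normal(size=(80, 2)), columns=["a", "b"])
            y = pd.Series(X["a"].to_numpy() + 1.5 * X["b"].to_numpy()
                          + rng.normal(size=80))
            p = S.anova_nested(S.ols_fit(X, y, ["a"]),
                               S.ols_fit(X, y, ["a", "b"]))
            hits += p < 0.001
        assert hits >= 95

    def test_non_nested_rejected(self):
        X, rng = _gaussian_design(40, 3, seed=13)
        y = pd.Series(rng.normal(size=40))
        fit_a = S.ols_fit(X, y, ["x0"])
        fit_b = S.ols_fit(X, y, ["x1", "x2"])
        with pytest.raises(ValueError):
            S.anova_nested(fit_a, fit_b)

    def test_equal_subsets_rejected(self):
        X, rng = _gaussian_design(40, 2, seed=14)
        y = pd.Series(rng.normal(size=40))
        fit = S.ols_fit(X, y, ["x0"])
        with pytest.raises(ValueError):
            S.anova_nested(fit, fit)

    def test_matches_statsmodels_anova(self):
        statsmodels_api = pytest.importorskip("statsmodels.api")
        from statsmodels.stats.anova import anova_lm
        X, rng = _gaussian_design(60, 3, seed=15)
        y = pd.Series(X["x0"].to_numpy() + 0.4 * X["x1"].to_numpy()
                      + rng.normal(size=60))
        p = S.anova_nested(S.ols_fit(X, y, ["x0"]),
                           S.ols_fit(X, y, ["x0", "x1"]))
        small = statsmodels_api.OLS(
            y, statsmodels_api.add_constant(X[["x0"]])).fit()
        large = statsmodels_api.OLS(
            y, statsmodels_api.add_constant(X[["x0", "x1"]])).fit()
        expected = anova_lm(small, large)["Pr(>F)"].iloc[1]
        assert p == pytest.approx(expected, rel=1e-9)
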
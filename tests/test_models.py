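"""OLS fitting, LOOCV evaluation, LRT, VIF and the combination search."""

import itertools

import numpy as np
import pandas as pd
import pytest

from irsplice.errors import CollinearityError, NestingError
from irsplice.models import (
    augment_model,
    combination_search,
    fit_ols,
    loocv_evaluate,
    lrt,
    unexplained_variance,
    vif,
)


def frame(n=12, k=3, seed=0, index=None):
    rng = np.random.default_rng(seed)
    index = index or [f"T{i}" for i in range(n)]
    return pd.DataFrame(rng.normal(size=(n, k)), index=index,
                        columns=[f"x{j}" for j in range(k)])


class TestFitOls:
    def test_perfect_fit(self):
        X = pd.DataFrame({"x": np.arange(8.0)})
        y = 2.0 * X["x"] + 1.0
        fit = fit_ols(X, y)
        assert fit.coefficients["x"] == pytest.approx(2.0)
        assert fit.coefficients["intercept"] == pytest.approx(1.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_orthogonal_slope_zero(self):
        X = pd.DataFrame({"x": [-1.0, 0.0, 1.0, -1.0, 0.0, 1.0]})
        y = pd.Series([1.0, -2.0, 1.0, 1.0, -2.0, 1.0])  # orthogonal to x, centered
        fit = fit_ols(X, y)
        assert fit.coefficients["x"] == pytest.approx(0.0, abs=1e-12)

    def test_three_point_by_hand(self):
        fit = fit_ols(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), pd.Series([1.0, 2.0, 4.0]))
        assert fit.coefficients["x"] == pytest.approx(1.5)
        assert fit.coefficients["intercept"] == pytest.approx(-2.0 / 3.0)

    def test_loglik_is_gaussian_ml(self):
        X = frame(n=15, k=2, seed=4)
        y = pd.Series(np.random.default_rng(5).normal(size=15), index=X.index)
        fit = fit_ols(X, y)
        sigma2 = fit.rss / fit.n
        expected = -fit.n / 2.0 * (np.log(2 * np.pi * sigma2) + 1.0)
        assert fit.loglik == pytest.approx(expected, rel=1e-12)

    def test_collinear_design_named(self):
        X = frame(n=10, k=1, seed=1)
        X["dup"] = 2.0 * X["x0"]
        y = pd.Series(np.arange(10.0), index=X.index)
        with pytest.raises(CollinearityError, match="dup"):
            fit_ols(X, y)


class TestLoocv:
    def test_noiseless_linear_recovery(self):
        X = frame(n=10, k=2, seed=2)
        y = 1.5 * X["x0"] - 2.0 * X["x1"] + 0.5
        fit = loocv_evaluate(["x0", "x1"], X, y)
        assert np.allclose(fit.predictions, y)
        assert fit.loocv_rs == pytest.approx(1.0)
        assert fit.unexplained_variance == pytest.approx(0.0, abs=1e-12)

    def test_identity_unexplained_variance(self):
        X = frame(n=14, k=2, seed=3)
        y = X["x0"] + pd.Series(np.random.default_rng(9).normal(size=14), index=X.index)
        fit = loocv_evaluate(["x0", "x1"], X, y)
        assert fit.unexplained_variance == pytest.approx(1 - fit.loocv_rs**2, abs=1e-15)

    def test_null_loocv_rs_small_sample_pessimism(self):
        """Null LOOCV Rs is slightly negative at small n and shrinks toward 0.

        Leaving observation i out moves the fit away from it, so held-out
        predictions anti-correlate with an unrelated response; the bias is a
        small-sample property of cross-validation, not an artifact.
        """
        rng = np.random.default_rng(12)
        rss = []
        for rep in range(200):
            X = frame(n=12, k=2, seed=rep)
            y = pd.Series(rng.normal(size=12), index=X.index)
            rss.append(loocv_evaluate(["x0", "x1"], X, y).loocv_rs)
        # pessimistic, never optimistic: selection on LOOCV Rs is conservative
        assert -0.45 < np.mean(rss) < -0.05
        assert np.std(rss) > 0.2  # wide null spread at n=12

    def test_affine_rescaling_invariance(self):
        X = frame(n=11, k=2, seed=6)
        y = X["x0"] * 2 + pd.Series(np.random.default_rng(7).normal(size=11),
                                    index=X.index)
        base = loocv_evaluate(["x0", "x1"], X, y)
        X2 = X.copy()
        X2["x0"] = 100.0 * X2["x0"] - 3.0
        X2["x1"] = -0.01 * X2["x1"] + 5.0
        scaled = loocv_evaluate(["x0", "x1"], X2, y)
        assert np.allclose(base.predictions, scaled.predictions)

    def test_unexplained_variance_helper(self):
        assert unexplained_variance(0.80) == pytest.approx(0.36)
        assert unexplained_variance(0.88) == pytest.approx(1 - 0.88**2)


class TestLrt:
    def test_self_comparison(self):
        X = frame(n=10, k=1, seed=8)
        y = pd.Series(np.arange(10.0), index=X.index)
        fit = fit_ols(X, y)
        cmp = lrt(fit, fit)
        assert cmp.lrt_stat == 0.0
        assert cmp.p_value == 1.0

    def test_nesting_enforced(self):
        X = frame(n=10, k=2, seed=8)
        y = pd.Series(np.arange(10.0), index=X.index)
        f0 = fit_ols(X[["x0"]], y)
        f1 = fit_ols(X[["x1"]], y)
        with pytest.raises(NestingError):
            lrt(f0, f1)

    def test_null_p_roughly_uniform(self):
        """Adding a pure-noise column gives a uniform LRT p under the null."""
        rng = np.random.default_rng(21)
        ps = []
        for rep in range(300):
            X = frame(n=20, k=2, seed=10_000 + rep)
            y = X["x0"] + pd.Series(rng.normal(size=20), index=X.index)
            ps.append(lrt(fit_ols(X[["x0"]], y), fit_ols(X, y)).p_value)
        ps = np.array(ps)
        # chi2(1) LRT at n=20 is only asymptotic; allow generous band
        assert 0.30 < (ps < 0.5).mean() < 0.70
        assert abs(np.mean(ps) - 0.5) < 0.08

    def test_statistic_non_negative(self):
        rng = np.random.default_rng(31)
        for rep in range(50):
            X = frame(n=12, k=3, seed=rep)
            y = pd.Series(rng.normal(size=12), index=X.index)
            cmp = lrt(fit_ols(X[["x0"]], y), fit_ols(X, y))
            assert cmp.lrt_stat >= 0
            assert cmp.df == 2


class TestVif:
    def test_orthogonal_is_one(self):
        X = pd.DataFrame({"a": [-1, -1, 1, 1.0], "b": [-1, 1, -1, 1.0],
                          "c": [1, -1, -1, 1.0]})
        X = pd.concat([X, X], ignore_index=True)  # n=8 > k+1
        v = vif(X)
        assert v.to_numpy() == pytest.approx([1.0, 1.0, 1.0])

    def test_exact_collinearity_flagged_inf(self):
        X = frame(n=10, k=1, seed=2)
        X["double"] = 2.0 * X["x0"]
        v = vif(X)
        assert np.isinf(v).all()

    def test_auxiliary_regression_oracle(self):
        """VIF_j equals 1/(1-R^2_j) from an independent polyfit-based R^2."""
        X = frame(n=30, k=3, seed=13)
        X["x2"] = X["x2"] + 0.8 * X["x0"]
        v = vif(X)
        for j, name in enumerate(X.columns):
            others = X.drop(columns=[name]).to_numpy()
            target = X[name].to_numpy()
            exog = np.column_stack([np.ones(len(X)), others])
            beta = np.linalg.solve(exog.T @ exog, exog.T @ target)
            resid = target - exog @ beta
            r2 = 1 - (resid**2).sum() / ((target - target.mean()) ** 2).sum()
            assert v[name] == pytest.approx(1 / (1 - r2), rel=1e-10)


class TestCombinationSearch:
    def test_model_count_k10(self):
        X = frame(n=12, k=10, seed=14)
        y = pd.Series(np.random.default_rng(15).normal(size=12), index=X.index)
        res = combination_search(X.columns, X, y)
        assert len(res) == 45 + 120
        assert (res["n_variables"].value_counts()[2], res["n_variables"].value_counts()[3]) == (45, 120)

    def test_k2_single_model(self):
        X = frame(n=10, k=2, seed=16)
        y = pd.Series(np.arange(10.0), index=X.index)
        res = combination_search(X.columns, X, y)
        assert len(res) == 1

    def test_noiseless_pair_ranks_first(self):
        X = frame(n=15, k=6, seed=17)
        y = 3.0 * X["x1"] - 1.0 * X["x4"] + 2.0
        res = combination_search(X.columns, X, y)
        assert res.iloc[0]["variables"] == "x1;x4"
        assert res.iloc[0]["loocv_rs"] == pytest.approx(1.0)

    def test_deterministic_ranking(self):
        X = frame(n=12, k=5, seed=18)
        y = pd.Series(np.random.default_rng(19).normal(size=12), index=X.index)
        r1 = combination_search(X.columns, X, y)
        r2 = combination_search(list(reversed(X.columns)), X, y)
        pd.testing.assert_frame_equal(r1, r2)

    def test_too_few_candidates(self):
        X = frame(n=10, k=1, seed=20)
        with pytest.raises(ValueError):
            combination_search(["x0"], X, pd.Series(np.arange(10.0), index=X.index))


class TestAugment:
    def test_planted_extra_improves(self):
        X = frame(n=16, k=3, seed=22)
        y = X["x0"] + X["x1"] + 0.8 * X["x2"] + pd.Series(
            np.random.default_rng(23).normal(0, 0.1, 16), index=X.index
        )
        cmp, fit = augment_model(["x0", "x1"], "x2", X, y)
        base = loocv_evaluate(["x0", "x1"], X, y)
        assert fit.loocv_rs >= base.loocv_rs
        assert cmp.p_value < 0.05
        assert fit.max_vif < 4

    def test_extra_already_present(self):
        X = frame(n=10, k=2, seed=24)
        with pytest.raises(ValueError):
            augment_model(["x0"], "x0", X, pd.Series(np.arange(10.0), index=X.index))

    def test_null_extra_p_near_uniform(self):
        rng = np.random.default_rng(25)
        ps = []
        for rep in range(200):
            X = frame(n=14, k=2, seed=30_000 + rep)
            y = X["x0"] + pd.Series(rng.normal(size=14), index=X.index)
            cmp, _ = augment_model(["x0"], "x1", X, y)
            ps.append(cmp.p_value)
        assert abs(np.mean(ps) - 0.5) < 0.1
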
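"""Unit and property tests for pinball-loss quantile regression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from saltol.quantreg import (
    DesignMatrix,
    PinballQuantileRegressor,
    RankDeficientDesignError,
    center_covariates,
    fit_ols,
    fit_quantile_regression,
    pinball_loss,
    rankscore_ci,
    vif,
)


def pairline_oracle(x, y, p):
    """Minimum pinball objective over all lines through two data points.

    An optimal quantile-regression line for a one-covariate model with
    intercept interpolates two observations, so exhaustive enumeration of
    point pairs is an exact (if slow) oracle for the LP solution.
    """
    n = len(x)
    best = np.inf
    for i in range(n):
        for j in range(i + 1, n):
            if np.isclose(x[i], x[j]):
                continue
            slope = (y[j] - y[i]) / (x[j] - x[i])
            icpt = y[i] - slope * x[i]
            best = min(best, float(np.sum(pinball_loss(y - icpt - slope * x, p))))
    return best


class TestPinballLoss:
    @pytest.mark.parametrize(
        "u,p,expected",
        [(2.0, 0.5, 1.0), (1.0, 0.9, 0.9), (-1.0, 0.1, 0.9), (0.0, 0.3, 0.0)],
    )
    def test_values(self, u, p, expected):
        assert pinball_loss(u, p) == pytest.approx(expected)

    @given(u=st.floats(-1e6, 1e6), p=st.floats(0.01, 0.99))
    @settings(max_examples=100, derandomize=True)
    def test_nonnegative_zero_iff_zero(self, u, p):
        v = float(pinball_loss(u, p))
        assert v >= 0.0
        assert (v == 0.0) == (u == 0.0)

    def test_rejects_degenerate_level(self):
        with pytest.raises(ValueError):
            pinball_loss(1.0, 1.0)


class TestQuantileFit:
    def test_intercept_only_median(self):
        f = fit_quantile_regression(np.ones((3, 1)), [1.0, 2.0, 9.0], 0.5,
                                    names=["intercept"])
        assert f.coefficients[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_exact_line_interpolation(self, p, rng):
        x = rng.normal(size=20)
        y = 2.0 + 3.0 * x
        f = fit_quantile_regression(np.column_stack([np.ones(20), x]), y, p)
        assert f.coefficients == pytest.approx([2.0, 3.0], abs=1e-8)
        assert f.objective == pytest.approx(0.0, abs=1e-9)

    def test_objective_recomputes_from_coefficients(self, rng):
        x = rng.normal(size=30)
        y = 1.0 + x + rng.normal(size=30)
        X = np.column_stack([np.ones(30), x])
        f = fit_quantile_regression(X, y, 0.3)
        obj = float(np.sum(pinball_loss(y - X @ f.coefficients, 0.3)))
        assert f.objective == pytest.approx(obj, rel=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pairline_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        p = float(rng.uniform(0.1, 0.9))
        f = fit_quantile_regression(np.column_stack([np.ones(n), x]), y, p)
        assert f.objective == pytest.approx(pairline_oracle(x, y, p), abs=1e-9)

    @pytest.mark.parametrize("p", [0.25, 0.5, 0.75])
    def test_residual_sign_balance(self, p, rng):
        n = 100
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = rng.normal(size=n)
        f = fit_quantile_regression(X, y, p)
        r = y - X @ f.coefficients
        assert np.sum(r < -1e-9) <= n * p + 1e-9
        assert np.sum(r > 1e-9) <= n * (1 - p) + 1e-9

    def test_scale_equivariance(self, rng):
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        f1 = fit_quantile_regression(X, y, 0.7)
        f2 = fit_quantile_regression(X, 3.5 * y, 0.7)
        assert f2.coefficients == pytest.approx(3.5 * f1.coefficients, rel=1e-7)

    def test_sign_flip_equivariance(self, rng):
        n = 41
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        f1 = fit_quantile_regression(X, y, 0.2)
        f2 = fit_quantile_regression(X, -y, 0.8)
        assert f2.objective == pytest.approx(f1.objective, rel=1e-8)
        assert f2.coefficients == pytest.approx(-f1.coefficients, rel=1e-6)

    def test_beats_ols_on_pinball(self, rng):
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ [1.0, 2.0, -1.0] + rng.standard_t(3, size=n)
        f = fit_quantile_regression(X, y, 0.4)
        ols = fit_ols(X, y)
        obj_ols = float(np.sum(pinball_loss(y - X @ ols.coefficients, 0.4)))
        assert f.objective <= obj_ols + 1e-10

    def test_agrees_with_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ [1.0, 2.0, -1.0] + rng.normal(size=n)
        f = fit_quantile_regression(X, y, 0.3)
        smf = sm.QuantReg(y, X).fit(q=0.3)
        assert f.coefficients == pytest.approx(smf.params, abs=5e-4)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([np.ones(30), x, 2.0 * x])
        with pytest.raises(RankDeficientDesignError, match="x2|x1"):
            fit_quantile_regression(X, rng.normal(size=30), 0.5,
                                    names=["intercept", "x1", "x2"])


@pytest.fixture(scope="module")
def dataset():
    rng = np.random.default_rng(5)
    n = 80
    x = rng.normal(size=n)
    y = 1.0 + 2.0 * x + rng.normal(size=n)
    return np.column_stack([np.ones(n), x]), y


class TestRankScoreCI:

    @pytest.mark.parametrize("variant", ["nid", "iid"])
    def test_point_estimate_inside_interval(self, dataset, variant):
        X, y = dataset
        f = rankscore_ci(X, y, 0.5, variant=variant)
        assert np.all(f.ci_lower <= f.coefficients + 1e-12)
        assert np.all(f.coefficients <= f.ci_upper + 1e-12)

    def test_interval_nesting_in_alpha(self, dataset):
        X, y = dataset
        f05 = rankscore_ci(X, y, 0.5, alpha=0.05)
        f10 = rankscore_ci(X, y, 0.5, alpha=0.10)
        assert np.all(f05.ci_lower <= f10.ci_lower + 1e-9)
        assert np.all(f05.ci_upper >= f10.ci_upper - 1e-9)

    def test_significance_flag_matches_interval(self, dataset):
        X, y = dataset
        f = rankscore_ci(X, y, 0.5)
        expected = (f.ci_lower > 0) | (f.ci_upper < 0)
        assert np.array_equal(f.significant, expected)
        # the planted slope of 2 is strongly significant at n=80
        assert f.significant[1]

    def test_true_slope_covered_most_of_the_time(self):
        """Median-regression rank-score CIs on iid gaussian data should
        cover the planted slope at roughly the nominal rate (coarse check
        here; the calibrated coverage simulation lives in acceptance)."""
        hits = 0
        reps = 25
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=60)
            y = 0.5 + 1.5 * x + rng.normal(size=60)
            f = rankscore_ci(np.column_stack([np.ones(60), x]), y, 0.5)
            hits += f.ci_lower[1] <= 1.5 <= f.ci_upper[1]
        assert hits >= reps - 4


class TestOLS:
    def test_exact_linear_interpolation(self, rng):
        X = np.column_stack([np.ones(25), rng.normal(size=(25, 2))])
        y = X @ [1.0, -2.0, 0.5]
        f = fit_ols(X, y)
        assert f.coefficients == pytest.approx([1.0, -2.0, 0.5], abs=1e-10)

    def test_matches_normal_equations(self, rng):
        n = 50
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        y = rng.normal(size=n)
        f = fit_ols(X, y)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert f.coefficients == pytest.approx(beta, abs=1e-10)


class TestVIF:
    def test_orthogonal_covariates_unit_vif(self):
        n = 64
        t = np.arange(n)
        Z = np.column_stack([np.cos(2 * np.pi * t / n), np.sin(2 * np.pi * t / n)])
        out = vif(DesignMatrix.from_covariates(Z, ["c", "s"]))
        assert out["c"] == pytest.approx(1.0, abs=1e-8)
        assert out["s"] == pytest.approx(1.0, abs=1e-8)

    def test_near_collinearity_blows_up(self, rng):
        x1 = rng.normal(size=100)
        x2 = x1 + 1e-4 * rng.normal(size=100)
        out = vif(np.column_stack([x1, x2]), names=["a", "b"])
        assert out["a"] > 10 and out["b"] > 10

    def test_perfect_collinearity_reports_inf(self, rng):
        x1 = rng.normal(size=50)
        out = vif(np.column_stack([x1, 2 * x1, rng.normal(size=50)]),
                  names=["a", "b", "c"])
        assert np.isinf(out["a"]) and np.isinf(out["b"])
        assert np.isfinite(out["c"])

    def test_definitional_oracle(self, rng):
        Z = rng.normal(size=(80, 3)) @ np.array(
            [[1.0, 0.4, 0.0], [0.0, 1.0, 0.3], [0.0, 0.0, 1.0]]
        )
        out = vif(Z, names=["a", "b", "c"])
        for j, name in enumerate(["a", "b", "c"]):
            others = np.delete(Z, j, axis=1)
            f = fit_ols(DesignMatrix.from_covariates(others), Z[:, j])
            pred = np.column_stack([np.ones(len(Z)), others]) @ f.coefficients
            r2 = 1 - np.sum((Z[:, j] - pred) ** 2) / np.sum(
                (Z[:, j] - Z[:, j].mean()) ** 2
            )
            assert out[name] == pytest.approx(1.0 / (1.0 - r2), rel=1e-8)


class TestCentering:
    def test_column_means_zero_and_offsets(self, rng):
        Z = rng.normal(loc=5.0, size=(40, 3))
        d = center_covariates(DesignMatrix.from_covariates(Z, ["a", "b", "c"]))
        assert np.abs(d.X[:, 1:].mean(axis=0)).max() < 1e-12
        assert d.offsets["a"] == pytest.approx(Z[:, 0].mean())

    def test_constant_column_warns(self):
        Z = np.column_stack([np.full(10, 3.0), np.arange(10.0)])
        with pytest.warns(RuntimeWarning, match="constant"):
            d = center_covariates(DesignMatrix.from_covariates(Z, ["const", "x"]))
        assert np.allclose(d.X[:, 1], 0.0)

    def test_slopes_invariant_intercept_shifted(self, rng):
        Z = rng.normal(loc=10.0, size=(60, 2))
        y = 1.0 + Z @ [2.0, -1.0] + rng.normal(size=60)
        raw = DesignMatrix.from_covariates(Z, ["a", "b"])
        cen = center_covariates(raw)
        f_raw = fit_quantile_regression(raw, y, 0.5)
        f_cen = fit_quantile_regression(cen, y, 0.5)
        assert f_cen.coefficients[1:] == pytest.approx(f_raw.coefficients[1:], abs=1e-6)
        shift = f_raw.coefficients[1:] @ Z.mean(axis=0)
        assert f_cen.coefficients[0] == pytest.approx(
            f_raw.coefficients[0] + shift, abs=1e-6
        )


class TestEstimator:
    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        est = PinballQuantileRegressor(quantile=0.8, ci=None)
        est2 = clone(est)
        assert est2.get_params() == est.get_params()

    def test_fit_predict_roundtrip(self, rng):
        x = rng.normal(size=(50, 1))
        y = (1.0 + 2.0 * x[:, 0])
        est = PinballQuantileRegressor(quantile=0.5, ci=None).fit(x, y)
        assert est.intercept_ == pytest.approx(1.0, abs=1e-8)
        assert est.coef_[0] == pytest.approx(2.0, abs=1e-8)
        assert est.predict(x) == pytest.approx(y, abs=1e-7)
        assert est.score(x, y) == pytest.approx(0.0, abs=1e-8)
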
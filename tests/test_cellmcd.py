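import math

import numpy as np
import pytest

from zrank import (
    CellMCDParams,
    ZMatrix,
    cell_predict,
    cellmcd_rank,
    fit_cellmcd,
    flag_entries,
    mahalanobis_sq,
)
from zrank.cellmcd import CellMCDFit, FitSizeError

from .conftest import zmatrix_from


class TestCellPredict:
    @pytest.mark.parametrize("rho", [-0.8, -0.3, 0.0, 0.5, 0.9])
    @pytest.mark.parametrize("x2", [-2.0, 0.7, 3.1])
    def test_bivariate_closed_form(self, rho, x2):
        sigma = np.array([[1.0, rho], [rho, 1.0]])
        pred, sd = cell_predict([0.0, 0.0], sigma, [np.nan, x2], observed=[1], target=0)
        assert pred == pytest.approx(rho * x2, abs=1e-10)
        assert sd == pytest.approx(math.sqrt(1.0 - rho * rho), abs=1e-10)

    def test_identity_covariance_ignores_observed_values(self, rng):
        sigma = np.eye(3)
        mu = np.array([1.0, -2.0, 0.5])
        for _ in range(5):
            row = rng.normal(size=3)
            pred, sd = cell_predict(mu, sigma, row, observed=[1, 2], target=0)
            assert pred == pytest.approx(mu[0], abs=1e-12)
            assert sd == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        # regression coefficients of coordinate 0 on {1,2,3} solved directly
        A = rng.normal(size=(4, 4))
        sigma = A @ A.T + 4 * np.eye(4)
        mu = rng.normal(size=4)
        row = rng.normal(size=4)
        obs = np.array([1, 2, 3])
        beta = np.linalg.solve(sigma[np.ix_(obs, obs)], sigma[obs, 0])
        pred_oracle = mu[0] + beta @ (row[obs] - mu[obs])
        var_oracle = sigma[0, 0] - beta @ sigma[obs, 0]
        pred, sd = cell_predict(mu, sigma, row, observed=obs, target=0)
        assert pred == pytest.approx(pred_oracle, rel=1e-12)
        assert sd == pytest.approx(math.sqrt(var_oracle), rel=1e-12)

    def test_empty_observed_set_falls_back_to_marginal(self):
        sigma = np.array([[4.0, 1.0], [1.0, 2.0]])
        pred, sd = cell_predict([3.0, 0.0], sigma, [0.0, 0.0], observed=[], target=0)
        assert (pred, sd) == (3.0, 2.0)

    def test_target_inside_observed_rejected(self):
        with pytest.raises(ValueError):
            cell_predict([0, 0], np.eye(2), [1, 1], observed=[0], target=0)


class TestFit:
    def test_parameter_recovery_on_clean_draw(self, clean_bivariate):
        Z, mu, sigma = clean_bivariate
        fit = fit_cellmcd(Z)
        assert fit.converged
        assert np.abs(fit.center - mu).max() < 0.05
        assert np.abs(fit.covariance - sigma).max() < 0.08

    def test_clean_data_flags_almost_nothing(self, clean_bivariate):
        Z, _, _ = clean_bivariate
        fit = fit_cellmcd(Z)
        assert 1.0 - fit.flags.mean() <= 0.02

    def test_planted_gross_cell_is_flagged(self, clean_bivariate):
        Z, _, _ = clean_bivariate
        X = Z.values.copy()
        X[0, 0] = 20.0
        fit = fit_cellmcd(zmatrix_from(X))
        assert fit.flags[0, 0] == 0
        assert abs(fit.residuals[0, 0]) > fit.params.cutoff

    def test_objective_trace_monotone(self, clean_bivariate, rng):
        Z, _, _ = clean_bivariate
        X = Z.values.copy()
        hit = rng.choice(X.size, size=int(0.02 * X.size), replace=False)
        X.flat[hit] = rng.choice([-15.0, 15.0], size=hit.size)
        fit = fit_cellmcd(zmatrix_from(X))
        assert np.all(np.diff(fit.objective_trace) <= 1e-8)

    def test_column_budget_respected(self, rng):
        X = rng.standard_normal((200, 3))
        X[:80, 1] = 30.0 + rng.standard_normal(80)  # 40% gross cells in one column
        fit = fit_cellmcd(zmatrix_from(X))
        m = X.shape[0]
        budget = math.ceil(fit.params.alpha * m)
        assert fit.flags.sum(axis=0).min() >= budget

    def test_clean_limit_equals_sample_mle_when_flagging_disabled(self, clean_bivariate):
        Z, _, _ = clean_bivariate
        fit = fit_cellmcd(Z, CellMCDParams(penalty_q=1e12))
        np.testing.assert_allclose(fit.center, Z.values.mean(axis=0), atol=1e-6)
        np.testing.assert_allclose(fit.covariance, np.cov(Z.values.T, ddof=0), atol=1e-6)

    def test_translation_equivariance(self, clean_bivariate):
        Z, _, _ = clean_bivariate
        base = fit_cellmcd(Z)
        shift = np.array([3.0, -2.0])
        moved = fit_cellmcd(zmatrix_from(Z.values + shift))
        np.testing.assert_allclose(moved.center, base.center + shift, atol=1e-8)
        np.testing.assert_allclose(moved.covariance, base.covariance, atol=1e-8)
        np.testing.assert_array_equal(moved.flags, base.flags)
        np.testing.assert_allclose(moved.residuals, base.residuals, atol=1e-8)

    def test_breakdown_under_one_percent_gross_cells(self, clean_bivariate, rng):
        Z, _, _ = clean_bivariate
        base = fit_cellmcd(Z)
        X = Z.values.copy()
        hit = rng.choice(X.size, size=int(0.01 * X.size), replace=False)
        X.flat[hit] = 20.0
        contaminated = fit_cellmcd(zmatrix_from(X))
        assert np.abs(contaminated.center - base.center).max() < 0.05
        assert np.abs(contaminated.covariance - base.covariance).max() < 0.05

    def test_deterministic(self, clean_bivariate):
        Z, _, _ = clean_bivariate
        a, b = fit_cellmcd(Z), fit_cellmcd(Z)
        np.testing.assert_array_equal(a.center, b.center)
        np.testing.assert_array_equal(a.covariance, b.covariance)
        np.testing.assert_array_equal(a.flags, b.flags)

    def test_too_few_rows_rejected(self, rng):
        Z = zmatrix_from(rng.standard_normal((9, 2)))
        with pytest.raises(FitSizeError, match="5\\*d"):
            fit_cellmcd(Z)

    def test_non_convergence_warns_and_returns_iterate(self, clean_bivariate):
        Z, _, _ = clean_bivariate
        with pytest.warns(RuntimeWarning, match="did not converge"):
            fit = fit_cellmcd(Z, CellMCDParams(max_iter=1, tol=1e-300))
        assert not fit.converged
        assert fit.center.shape == (2,)


def _fit_with_residuals(residuals, values=None):
    residuals = np.asarray(residuals, dtype=float)
    m, d = residuals.shape
    values = np.zeros_like(residuals) if values is None else np.asarray(values, float)
    return CellMCDFit(
        genes=tuple(f"g{i + 1}" for i in range(m)),
        phenotypes=tuple(f"p{j + 1}" for j in range(d)),
        values=values,
        center=np.zeros(d),
        covariance=np.eye(d),
        flags=np.ones((m, d), dtype=np.int8),
        predictions=values - residuals,
        cond_sd=np.ones((m, d)),
        residuals=residuals,
        objective_trace=np.array([0.0]),
        n_iter=1,
        converged=True,
    )


class TestFlagEntries:
    def test_all_zero_residuals_give_empty_table(self):
        table = flag_entries(_fit_with_residuals(np.zeros((3, 2))))
        assert len(table) == 0

    def test_threshold_and_descending_order(self):
        table = flag_entries(_fit_with_residuals([[3.0, 0.0], [-2.6, 1.0]]), cutoff=2.5758)
        assert list(table["residual"]) == [3.0, -2.6]
        assert list(table["gene"]) == ["g1", "g2"]

    def test_hidden_outlier_indicator(self):
        fit = _fit_with_residuals([[4.0, 0.0]], values=[[1.0, 0.0]])
        table = flag_entries(fit, cutoff=2.5758)
        assert len(table) == 1
        assert table.loc[0, "hidden"] == 1  # |z| = 1.0 < 2.5758 yet residual 4.0
        fit2 = _fit_with_residuals([[4.0, 0.0]], values=[[6.0, 0.0]])
        assert flag_entries(fit2, cutoff=2.5758).loc[0, "hidden"] == 0


class TestRowOutliers:
    def test_distance_identity_covariance(self):
        h = mahalanobis_sq([[3.0, 4.0]], np.zeros(2), np.eye(2))[0]
        assert h == pytest.approx(25.0, rel=1e-12)
        # chi-square(2) survival has the closed form exp(-h/2)
        assert math.exp(-12.5) == pytest.approx(3.727e-6, rel=1e-3)

    def test_distance_correlated_hand_inverted(self):
        sigma = np.array([[1.0, 0.5], [0.5, 1.0]])
        h = mahalanobis_sq([[1.0, 1.0]], np.zeros(2), sigma)[0]
        assert h == pytest.approx(4.0 / 3.0, rel=1e-12)

    def test_rank_result_contract(self, clean_bivariate):
        Z, _, _ = clean_bivariate
        res = cellmcd_rank(Z)
        assert res.method == "cellmcd"
        assert sorted(res.rank) == list(range(1, Z.m + 1))
        np.testing.assert_allclose(res.criterion, np.sqrt(res.distance / Z.d), rtol=1e-12)
        assert np.all(res.pvalue > 0) and np.all(res.pvalue <= 1)
        # chi-square(2) closed form on the reported distances
        expected = np.exp(-res.distance / 2.0)
        np.testing.assert_allclose(res.pvalue, expected, rtol=1e-10)
        # the row closest to the center has distance near 0 and p near 1
        closest = np.argmin(res.distance)
        assert res.pvalue[closest] > 0.99

    def test_row_at_center_has_zero_distance(self, clean_bivariate):
        Z, _, _ = clean_bivariate
        fit = fit_cellmcd(Z)
        X = Z.values.copy()
        X[0] = fit.center
        res = cellmcd_rank(zmatrix_from(X), fit=fit)
        assert res.distance[0] == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue[0] == pytest.approx(1.0)
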
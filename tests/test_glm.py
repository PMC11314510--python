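import numpy as np
import pandas as pd
import pytest

from bryorisk.glm import (
    ContingencyTest,
    SeparationError,
    binned_residuals,
    chisq_association,
    fit_logistic,
    vif,
    wald_ci,
)


def grid_mle_logistic(y, x, span=5.0):
    """Brute-force likelihood maximisation on a refining grid.

    Independent oracle for two-coefficient fits: exhaustive coarse grid then
    two refinements down to 1e-3 resolution (the log-likelihood is concave,
    so refinement around the coarse optimum is exact at that resolution).
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)

    def nll(b0, b1):
        eta = b0 + b1 * x
        return -np.sum(y * eta - np.log1p(np.exp(eta)))

    best = (0.0, 0.0)
    for step in (0.1, 0.01, 0.001):
        b0s = np.arange(best[0] - span, best[0] + span + step, step)
        b1s = np.arange(best[1] - span, best[1] + span + step, step)
        vals = np.array([[nll(b0, b1) for b1 in b1s] for b0 in b0s])
        i, j = np.unravel_index(vals.argmin(), vals.shape)
        best = (b0s[i], b1s[j])
        span = 2 * step
    return best


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = [1] * 5 + [0] * 15  # 25% positives
        fit = fit_logistic(y, None)
        assert fit.coefficients[0] == pytest.approx(np.log(0.25 / 0.75), abs=1e-6)

    def test_binary_predictor_slope_is_log_odds_ratio(self):
        # 2x2 counts [[20,10],[10,20]] -> slope log(4)
        y = [1] * 20 + [0] * 10 + [1] * 10 + [0] * 20
        x = [1.0] * 30 + [0.0] * 30
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.coef("x") == pytest.approx(np.log(4.0), abs=1e-6)

    def test_matches_grid_search_oracle_on_toy(self):
        y = np.array([0, 0, 1, 0, 1, 1, 0, 1], float)
        x = np.array([-1.2, -0.7, -0.1, 0.2, 0.5, 0.9, -0.3, 1.4])
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        b0, b1 = grid_mle_logistic(y, x)
        assert abs(fit.coefficients[0] - b0) < 2e-3
        assert abs(fit.coefficients[1] - b1) < 2e-3

    def test_aic_identity(self, default_cohort):
        m, _ = default_cohort
        y = m.data["threat_status"].astype(float)
        x = (m.data["Plant sex"] == "monoicous").astype(float)
        fit = fit_logistic(y, pd.DataFrame({"sex": x}))
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2 * 2)
        assert np.all((fit.fitted_probabilities > 0) & (fit.fitted_probabilities < 1))
        assert len(fit.fitted_probabilities) == fit.n

    def test_zscaling_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 4, 300)
        y = (rng.random(300) < 1 / (1 + np.exp(-(-1 + 0.2 * (x - 10))))).astype(float)
        raw = fit_logistic(y, pd.DataFrame({"x": x}))
        sd = x.std(ddof=1)
        z = fit_logistic(y, pd.DataFrame({"x": (x - x.mean()) / sd}))
        assert z.coefficients[1] == pytest.approx(raw.coefficients[1] * sd, rel=1e-6)
        np.testing.assert_allclose(
            z.fitted_probabilities, raw.fitted_probabilities, atol=1e-9
        )

    def test_complete_separation_raises(self):
        y = [0, 0, 0, 0, 1, 1, 1, 1]
        x = [0.0, 0.1, 0.2, 0.3, 2.0, 2.1, 2.2, 2.3]
        with pytest.raises(SeparationError):
            fit_logistic(y, pd.DataFrame({"x": x}))

    def test_missing_predictors_dropped_and_counted(self):
        y = [0, 1, 0, 1, 0, 1, 1, 0]
        x = [1.0, 2.0, np.nan, 0.5, 1.5, 2.5, 0.2, 1.1]
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.n == 7
        assert fit.n_dropped == 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic([1, 1, 1, 1], None)


class TestWaldCI:
    def test_half_width_arithmetic(self):
        fit = fit_logistic([1] * 5 + [0] * 15, None)
        fit.standard_errors = np.array([0.29])
        assert wald_ci(fit, 0.95)[0] == pytest.approx(0.568, abs=5e-3)

    def test_zero_se_zero_width(self):
        fit = fit_logistic([1] * 5 + [0] * 15, None)
        fit.standard_errors = np.array([0.0])
        assert wald_ci(fit, 0.95)[0] == 0.0

    def test_monotone_nesting(self):
        fit = fit_logistic([1] * 5 + [0] * 15, None)
        assert wald_ci(fit, 0.999)[0] > wald_ci(fit, 0.95)[0]


class TestVIF:
    def test_orthogonal_predictors(self):
        x = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        report = vif(x)
        assert report.vifs["a"] == pytest.approx(1.0)
        assert report.vifs["b"] == pytest.approx(1.0)

    def test_known_correlation_closed_form(self):
        # two predictors with correlation 0.5 -> VIF = 1/(1-0.25)
        rng = np.random.default_rng(1)
        a = rng.normal(size=5000)
        b = 0.5 * a + np.sqrt(1 - 0.25) * rng.normal(size=5000)
        r = np.corrcoef(a, b)[0, 1]
        report = vif(pd.DataFrame({"a": a, "b": b}))
        assert report.vifs["a"] == pytest.approx(1 / (1 - r**2), rel=1e-6)

    def test_duplicate_column_flagged_infinite(self):
        x = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [4.0, 1, 3, 2]})
        report = vif(x)
        assert np.isinf(report.vifs["a"])
        assert ("a", "b") in report.collinear_pairs


class TestChisqAssociation:
    @staticmethod
    def _expand(table):
        a, b = [], []
        for i in (0, 1):
            for j in (0, 1):
                a += [i] * table[i][j]
                b += [j] * table[i][j]
        return a, b

    def test_exact_independence(self):
        a, b = self._expand([[15, 15], [15, 15]])
        t = chisq_association(a, b)
        assert t.statistic == pytest.approx(0.0)
        assert t.p_value == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # all expected cells 20: chi2 = 4 * (30-20)^2/20 = 20
        a, b = self._expand([[30, 10], [10, 30]])
        t = chisq_association(a, b)
        assert t.statistic == pytest.approx(20.0)
        assert t.df == 1

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 2, 200)
        b = rng.integers(0, 2, 200)
        t = chisq_association(a, b)
        observed = t.table
        rows = observed.sum(axis=1, keepdims=True)
        cols = observed.sum(axis=0, keepdims=True)
        expected = rows * cols / observed.sum()
        assert t.statistic == pytest.approx(((observed - expected) ** 2 / expected).sum())


class TestBinnedResiduals:
    def test_well_specified_fit_stays_in_band(self):
        inside = 0
        total = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=800)
            p = 1 / (1 + np.exp(-(-0.5 + 0.8 * x)))
            y = (rng.random(800) < p).astype(float)
            fit = fit_logistic(y, pd.DataFrame({"x": x}))
            table = binned_residuals(fit, y, n_bins=10)
            inside += (table["mean_residual"].abs() <= table["band_half_width"]).sum()
            total += len(table)
        assert inside / total >= 0.9

    def test_residuals_sum_to_zero_with_intercept(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=400)
        y = (rng.random(400) < 0.3).astype(float)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        table = binned_residuals(fit, y, n_bins=8)
        total = (table["mean_residual"] * table["n"]).sum()
        assert abs(total) < 1e-6

    def test_single_bin_rejected(self):
        fit = fit_logistic([1] * 5 + [0] * 15, None)
        with pytest.raises(ValueError):
            binned_residuals(fit, [1] * 5 + [0] * 15, n_bins=1)
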
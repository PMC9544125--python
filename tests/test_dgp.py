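"""Unit tests for the calibrated data-generating process."""

import numpy as np
import pytest
from scipy.special import expit

from pswsim import dgp


def unit_row(j: int) -> np.ndarray:
    """Covariate matrix with a single subject having x_j = 1, rest 0."""
    X = np.zeros((1, 10))
    X[0, j] = 1.0
    return X


class TestGenerateCovariates:
    def test_structure_and_moments(self):
        X = dgp.generate_covariates(200_000, seed=0)
        assert X.shape == (200_000, 10)
        # binary columns carry only 0/1 at the stated prevalences
        assert set(np.unique(X[:, 5:])) == {0.0, 1.0}
        np.testing.assert_allclose(
            X[:, 5:].mean(axis=0), [0.1, 0.2, 0.3, 0.4, 0.5], atol=0.005
        )
        # continuous columns: standard normal, equicorrelated at 0.2
        np.testing.assert_allclose(X[:, :5].mean(axis=0), 0.0, atol=0.01)
        np.testing.assert_allclose(X[:, :5].std(axis=0), 1.0, atol=0.01)
        corr = np.corrcoef(X[:, :5].T)
        off_diag = corr[np.triu_indices(5, k=1)]
        np.testing.assert_allclose(off_diag, 0.2, atol=0.01)

    def test_deterministic_under_seed(self):
        a = dgp.generate_covariates(500, seed=42)
        b = dgp.generate_covariates(500, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            dgp.generate_covariates(0, seed=1)


class TestTreatmentModel:
    @pytest.mark.parametrize(
        "X, alpha0, sigma, expected",
        [
            (np.zeros((1, 10)), 0.0, 1.0, 0.0),
            (unit_row(4), 0.0, 1.0, np.log(2.0)),  # x5 carries log(2)
            (unit_row(0), 0.0, 2.0, 2.0 * np.log(1.1)),
            (unit_row(9), 0.5, 1.0, 0.5 + np.log(0.5)),  # x10 carries log(0.5)
        ],
    )
    def test_linear_predictor(self, X, alpha0, sigma, expected):
        lp = dgp.treatment_linear_predictor(X, alpha0, sigma)
        np.testing.assert_allclose(lp, [expected], atol=1e-12)

    def test_zero_row_gives_half_propensity(self):
        lp = dgp.treatment_linear_predictor(np.zeros((1, 10)), 0.0)
        assert expit(lp[0]) == 0.5

    def test_intercept_calibration_on_zero_covariates(self):
        X = np.zeros((100, 10))
        a0 = dgp.calibrate_treatment_intercept(X, 0.5)
        assert abs(a0) < 1e-3

    def test_intercept_monotone_in_prevalence(self):
        X = dgp.generate_covariates(20_000, seed=5)
        a = [dgp.calibrate_treatment_intercept(X, p) for p in (0.2, 0.5, 0.8)]
        assert a[0] < a[1] < a[2]

    def test_calibration_closes_on_target(self):
        X = dgp.generate_covariates(20_000, seed=5)
        a0 = dgp.calibrate_treatment_intercept(X, 0.3)
        prev = expit(dgp.treatment_linear_predictor(X, a0)).mean()
        assert abs(prev - 0.3) <= 1e-4

    def test_unreachable_target_raises(self):
        with pytest.raises(ValueError):
            dgp.calibrate_treatment_intercept(np.zeros((10, 10)), 1.5)


class TestAssignTreatment:
    def test_mean_matches_probability(self):
        ps = np.full(100_000, 0.5)
        z = dgp.assign_treatment(ps, seed=3)
        assert set(np.unique(z)) <= {0, 1}
        assert abs(z.mean() - 0.5) < 0.006  # ~4 binomial SDs

    def test_reproducible(self):
        ps = np.random.default_rng(0).uniform(0.2, 0.8, 1000)
        np.testing.assert_array_equal(
            dgp.assign_treatment(ps, seed=9), dgp.assign_treatment(ps, seed=9)
        )

    def test_invalid_probabilities(self):
        with pytest.raises(ValueError):
            dgp.assign_treatment(np.array([0.0, 0.5]), seed=1)


class TestContinuousOutcome:
    def test_error_variance_closure(self):
        X = dgp.generate_covariates(20_000, seed=11)
        s2 = dgp.calibrate_error_variance(X)
        v = np.var(dgp.outcome_linear_predictor(X))
        assert abs(v / (v + s2) - 0.25) < 1e-12

    def test_error_variance_matches_line_search(self):
        # independent oracle: 1-D scan of sigma^2 for R^2 closest to 0.25
        X = dgp.generate_covariates(5_000, seed=12)
        v = np.var(dgp.outcome_linear_predictor(X))
        grid = np.linspace(0.5 * v, 6.0 * v, 20_001)
        r2 = v / (v + grid)
        best = grid[np.argmin(np.abs(r2 - 0.25))]
        assert abs(dgp.calibrate_error_variance(X) - best) < (grid[1] - grid[0])

    def test_uniform_effect_exactly_two(self):
        X = dgp.generate_covariates(1_000, seed=1)
        y0, y1 = dgp.generate_continuous_potential_outcomes(X, sigma2=4.0, seed=2)
        np.testing.assert_allclose(y1 - y0, 2.0, atol=1e-12)

    @pytest.mark.parametrize(
        "X, expected_effect",
        [
            (np.zeros((1, 10)), 2.0),
            (unit_row(0), 2.0 + 0.25 * 2.5),
            (unit_row(7), 2.0 + 0.25 * 5.0),  # x8 main effect 5
        ],
    )
    def test_interaction_effect(self, X, expected_effect):
        y0, y1 = dgp.generate_continuous_potential_outcomes(
            X, sigma2=1.0, interactions=True, seed=3
        )
        np.testing.assert_allclose(y1 - y0, [expected_effect], atol=1e-12)

    def test_empirical_r_squared(self, pop_small):
        lp = dgp.outcome_linear_predictor(pop_small.covariates)
        r2 = np.var(lp) / np.var(pop_small.y_cont_0)
        assert abs(r2 - 0.25) < 0.01


class TestBinaryOutcome:
    def test_outcome_intercept_zero_covariates(self):
        a0 = dgp.calibrate_outcome_intercept(np.zeros((50, 10)), 0.5)
        assert abs(a0) < 1e-3

    def test_outcome_intercept_order_invariant(self):
        X = dgp.generate_covariates(2_000, seed=8)
        a = dgp.calibrate_outcome_intercept(X, 0.2)
        b = dgp.calibrate_outcome_intercept(X[::-1], 0.2)
        assert a == b

    def test_null_treatment_log_odds(self):
        X = dgp.generate_covariates(2_000, seed=8)
        a0 = dgp.calibrate_outcome_intercept(X, 0.2)
        at = dgp.calibrate_treatment_log_odds(X, a0, target_rd=0.0)
        assert abs(at) < 1e-3

    def test_log_odds_monotone_in_target(self):
        X = dgp.generate_covariates(2_000, seed=8)
        a0 = dgp.calibrate_outcome_intercept(X, 0.2)
        solved = [
            dgp.calibrate_treatment_log_odds(X, a0, target_rd=t)
            for t in (-0.05, -0.02, 0.03)
        ]
        assert solved[0] < solved[1] < solved[2]

    def test_null_effect_couples_outcomes(self):
        X = dgp.generate_covariates(500, seed=4)
        calib = dgp.CalibrationResult(0.0, -1.5, 0.0, 1.0)
        y0, y1 = dgp.generate_binary_potential_outcomes(X, calib, seed=6)
        np.testing.assert_array_equal(y0, y1)

    def test_calibration_closure(self, pop_small):
        # control prevalence 0.2 and ATE risk difference -0.02
        assert abs(pop_small.y_bin_0.mean() - 0.2) < 0.01
        rd = pop_small.y_bin_1.mean() - pop_small.y_bin_0.mean()
        assert abs(rd - (-0.02)) < 0.005


class TestSuperPopulation:
    def test_reproducible(self):
        a = dgp.build_super_population(2_000, 0.3, seed=21)
        b = dgp.build_super_population(2_000, 0.3, seed=21)
        np.testing.assert_array_equal(a.covariates, b.covariates)
        np.testing.assert_array_equal(a.treatment, b.treatment)
        np.testing.assert_array_equal(a.y_bin_1, b.y_bin_1)
        assert a.calibration == b.calibration

    def test_treatment_prevalence(self, pop_small):
        assert abs(pop_small.treatment.mean() - 0.5) < 0.01

    def test_observed_outcome_selects_potential(self, pop_small):
        z = pop_small.treatment
        np.testing.assert_array_equal(
            pop_small.y_cont, np.where(z == 1, pop_small.y_cont_1, pop_small.y_cont_0)
        )

    def test_draw_sample_without_replacement(self, pop_small):
        s = dgp.draw_sample(pop_small, 500, np.random.default_rng(2))
        assert s.n == 500
        assert set(np.unique(s.Z)) <= {0, 1}
        with pytest.raises(ValueError):
            dgp.draw_sample(pop_small, pop_small.n + 1, np.random.default_rng(2))


class TestTrueEstimands:
    @pytest.mark.parametrize("family", ["ATE", "ATT", "MW", "OW"])
    def test_mean_difference_is_two(self, pop_small, family):
        est = dgp.true_estimands(pop_small, family)
        assert est["mean_diff"] == pytest.approx(2.0, abs=1e-10)

    def test_ate_risk_difference(self, pop_small):
        est = dgp.true_estimands(pop_small, "ATE")
        assert est["risk_diff"] == pytest.approx(-0.02, abs=0.005)

    def test_att_matches_direct_subsetting(self, pop_small):
        # independent route: average potential-outcome contrast over the
        # realised treated subjects instead of tilting by e(x)
        est = dgp.true_estimands(pop_small, "ATT")
        treated = pop_small.treatment == 1
        direct_rd = (pop_small.y_bin_1[treated] - pop_small.y_bin_0[treated]).mean()
        assert est["risk_diff"] == pytest.approx(direct_rd, abs=0.005)

    def test_unknown_family(self, pop_small):
        with pytest.raises(ValueError):
            dgp.true_estimands(pop_small, "XXX")
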
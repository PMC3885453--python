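"""Moment estimators: hand-checked examples, exact plug-in identities,
variance algebra and unbiasedness of the corrected estimators."""

import numpy as np
import pytest
from scipy.optimize import fsolve

import rrtmodels.moments as mm
from rrtmodels import (
    DoubleResponseDesign,
    HuangDesign,
    Population,
    Scrambler,
    ThreeStageParams,
    TwoSampleDesign,
)
from rrtmodels.mc import Scenario, _replicate_estimates
from rrtmodels.simulate import _double_matrices, _two_sample_matrices


class TestPointEstimators:
    def test_split_mean_hand_example_and_numeric_oracle(self):
        """(theta2*zbar1 + theta1*zbar2)/(theta1+theta2) with theta=(2,4)
        and means (10.6, 8.8) gives 10.0; cross-checked by solving the two
        moment equations numerically."""
        assert mm.mean_split(10.6, 8.8, 2, 4) == pytest.approx(10.0)

        def equations(v):
            mu, a = v
            return [mu + a * 2 - 10.6, mu - a * 4 - 8.8]

        mu_num, a_num = fsolve(equations, [1.0, 0.1])
        assert mm.mean_split(10.6, 8.8, 2, 4) == pytest.approx(mu_num)
        w = mm.sensitivity_split(10.6, 8.8, 2, 4, 0.3, 0.1)
        assert w == pytest.approx((a_num - 0.1) / 0.6) == pytest.approx(1 / 3)

    def test_mehta_mean_hand_example_and_numeric_oracle(self):
        assert mm.mean_mehta(10.8, 11.6, 2, 4) == pytest.approx(10.0)

        def equations(v):
            mu, a = v
            return [mu + a * 2 - 10.8, mu + a * 4 - 11.6]

        mu_num, _ = fsolve(equations, [1.0, 0.1])
        assert mm.mean_mehta(10.8, 11.6, 2, 4) == pytest.approx(mu_num)

    def test_agreeing_subsample_means_return_common_value(self):
        for th1, th2 in [(1, 2), (2, 4), (0.5, 7)]:
            assert mm.mean_split(5.5, 5.5, th1, th2) == pytest.approx(5.5)
        assert mm.sensitivity_split(5.5, 5.5, 1, 2, 0.3, 0.0) == pytest.approx(0.0)

    @pytest.mark.parametrize("design_kind", ["split", "mehta", "double"])
    def test_exact_expectation_plugin_recovers_truth(self, design_kind):
        """Feeding the closed-form expected responses as observed means
        returns (mu, W) at machine precision."""
        mu, t, f, w = 10.0, 0.3, 0.1, 0.45
        a = f + (1 - t - f) * w
        th1, th2 = 2.0, 4.0
        if design_kind == "mehta":
            zb1, zb2 = mu + a * th1, mu + a * th2
            got_mu = mm.mean_mehta(zb1, zb2, th1, th2)
            got_w = mm.sensitivity_mehta(zb1, zb2, th1, th2, t, f)
        else:
            zb1, zb2 = mu + a * th1, mu - a * th2
            got_mu = mm.mean_split(zb1, zb2, th1, th2)
            got_w = mm.sensitivity_split(zb1, zb2, th1, th2, t, f)
        assert got_mu == pytest.approx(mu, abs=1e-12)
        assert got_w == pytest.approx(w, abs=1e-12)

    def test_gupta_is_f_zero_specialisation(self):
        zb1, zb2, th1, th2, t = 10.7, 11.4, 2.0, 4.0, 0.3
        assert mm.mean_gupta(zb1, zb2, th1, th2) == mm.mean_mehta(zb1, zb2, th1, th2)
        assert mm.sensitivity_gupta(zb1, zb2, th1, th2, t) == mm.sensitivity_mehta(
            zb1, zb2, th1, th2, t, 0.0)

    def test_degenerate_theta_configurations_rejected(self):
        with pytest.raises(ValueError):
            mm.mean_mehta(10, 11, 2, 2)
        with pytest.raises(ValueError):
            mm.sensitivity_split(10, 9, 2, 4, 0.6, 0.4)  # T + F = 1

    def test_w_outside_unit_interval_reported_raw(self):
        w = mm.sensitivity_split(8.8, 10.6, 2, 4, 0.3, 0.1)  # negative A-hat
        assert w < 0


class TestHuangSolve:
    def test_exact_plugin_common_multiplicative_mean(self):
        mu, w = 10.0, 0.4
        mult = Scrambler(1.3, 0.2)
        design = HuangDesign(mult, Scrambler(2.0, 1.0), mult, Scrambler(4.0, 1.0), 50, 50)
        zb1 = mu + w * ((1.3 - 1) * mu + 2.0)
        zb2 = mu + w * ((1.3 - 1) * mu + 4.0)
        got_mu, got_w = mm.huang_solve(zb1, zb2, design)
        assert got_mu == pytest.approx(mu, abs=1e-10)
        assert got_w == pytest.approx(w, abs=1e-10)

    def test_exact_plugin_unequal_multiplicative_means_root_solve(self):
        mu, w = 10.0, 0.4
        design = HuangDesign(Scrambler(1.3, 0.2), Scrambler(2.0, 1.0),
                             Scrambler(1.6, 0.2), Scrambler(4.0, 1.0), 50, 50)
        zb1 = mu + w * ((1.3 - 1) * mu + 2.0)
        zb2 = mu + w * ((1.6 - 1) * mu + 4.0)
        got_mu, got_w = mm.huang_solve(zb1, zb2, design)
        assert got_mu == pytest.approx(mu, abs=1e-8)
        assert got_w == pytest.approx(w, abs=1e-8)

    def test_unit_multiplicative_mean_reduces_to_additive_algebra(self):
        one = Scrambler(1.0, 0.0, "point_mass")
        design = HuangDesign(one, Scrambler(2.0, 1.0), one, Scrambler(4.0, 1.0), 50, 50)
        mu, w = 10.0, 0.4
        zb1, zb2 = mu + w * 2.0, mu + w * 4.0
        got_mu, got_w = mm.huang_solve(zb1, zb2, design)
        assert got_mu == pytest.approx(mm.mean_mehta(zb1, zb2, 2.0, 4.0))
        assert got_w == pytest.approx(w)


class TestVarianceFormulas:
    def test_response_variance_limits_and_value(self):
        assert mm.response_variance(4.0, 0.0, 2.0, 1.0) == pytest.approx(4.0)
        assert mm.response_variance(4.0, 1.0, 2.0, 1.0) == pytest.approx(5.0)
        assert mm.response_variance(4.0, 0.5, 2.0, 1.0) == pytest.approx(5.5)

    def test_variances_scale_inversely_with_sample_size(self, pop, scr_pair, params):
        a = params.scramble_probability
        d1 = TwoSampleDesign(*scr_pair, -1, 100, 150)
        d2 = TwoSampleDesign(*scr_pair, -1, 300, 450)
        assert mm.var_mean_split(d1, pop, a) == pytest.approx(
            3 * mm.var_mean_split(d2, pop, a))
        assert mm.var_sensitivity_split(d1, pop, a, 0.3, 0.1) == pytest.approx(
            3 * mm.var_sensitivity_split(d2, pop, a, 0.3, 0.1))

    def test_mehta_to_split_ratio_is_theta_sum_sq_over_diff_sq(self, pop, params):
        """With equal subsample sizes and shared scrambler variances the
        variance ratio collapses to (theta1+theta2)^2/(theta2-theta1)^2:
        4 for thetas (1, 3)."""
        a = params.scramble_probability
        s1, s2 = Scrambler(1.0, 0.5), Scrambler(3.0, 0.5)
        split = TwoSampleDesign(s1, s2, -1, 100, 100)
        mehta = TwoSampleDesign(s1, s2, +1, 100, 100)
        ratio = mm.var_mean_mehta(mehta, pop, a) / mm.var_mean_split(split, pop, a)
        expected = (1 + 3) ** 2 / (3 - 1) ** 2
        # shared gamma^2 but different theta make sigma_Z1 != sigma_Z2, yet
        # both variances share the same numerator, so the ratio is exact
        assert ratio == pytest.approx(expected)
        assert expected == 4

    def test_double_mean_variance_honest_limit_is_sigma_over_n(self, pop, double_design):
        assert mm.var_mean_double(double_design, pop, 0.0) == pytest.approx(
            pop.var_x / double_design.n)
        assert mm.var_sensitivity_double(double_design, pop, 0.0, 0.3, 0.1) == 0.0

    @pytest.mark.parametrize("estimator_id", ["split_mean", "split_sensitivity"])
    def test_split_variance_formula_against_simulation(self, pop, params, estimator_id):
        from rrtmodels.mc import analytic_variance, empirical_moments

        sc = Scenario(pop, params, Scrambler(2.0, 1.0), Scrambler(4.0, 1.0),
                      100, 100, reps=5000, seed=101)
        _, mc_var, _ = empirical_moments(estimator_id, sc)
        assert mc_var == pytest.approx(analytic_variance(estimator_id, sc), rel=0.08)


class TestUnbiasedCorrections:
    @pytest.fixture
    def simulated_moments(self, pop, params, scr_pair):
        design = TwoSampleDesign(*scr_pair, -1, 120, 80)
        z1, z2 = _two_sample_matrices(design, pop, params, seed=55, reps=4000)
        return design, z1, z2

    def test_variance_estimates_unbiased_over_replicates(self, pop, params, simulated_moments):
        """MC mean of the plug-in variance estimate matches the closed-form
        variance; plug-in preserves unbiasedness because the variance is
        linear in the response variances."""
        design, z1, z2 = simulated_moments
        a = params.scramble_probability
        v_mu_samples = (
            design.theta2**2 * z1.var(axis=1, ddof=1) / design.n1
            + design.theta1**2 * z2.var(axis=1, ddof=1) / design.n2
        ) / design.denom**2
        truth = mm.var_mean_split(design, pop, a)
        se = v_mu_samples.std(ddof=1) / np.sqrt(v_mu_samples.size)
        assert v_mu_samples.mean() == pytest.approx(truth, abs=4 * se)

    def test_variance_estimate_scale_equivariance_and_degenerate_zero(
            self, params, scr_pair):
        design = TwoSampleDesign(*scr_pair, -1, 4, 4)
        sample1 = mm.MomentSummary(10.0, 9.0, 2.0, 3.0, 4, 4)
        sample2 = mm.MomentSummary(20.0, 18.0, 8.0, 12.0, 4, 4)  # responses doubled
        v1 = mm.unbiased_var_estimates(sample1, design, params)
        v2 = mm.unbiased_var_estimates(sample2, design, params)
        assert v2[0] == pytest.approx(4 * v1[0])
        const = mm.MomentSummary(10.0, 9.0, 0.0, 0.0, 4, 4)
        assert mm.unbiased_var_estimates(const, design, params) == (0.0, 0.0)
        with pytest.raises(ValueError):
            mm.unbiased_var_estimates(mm.MomentSummary(1, 1, 0, 0, 1, 4), design, params)

    def test_a_functions_unbiased_over_replicates(self, pop, params, simulated_moments):
        design, z1, z2 = simulated_moments
        a = params.scramble_probability
        zb1, zb2 = z1.mean(axis=1), z2.mean(axis=1)
        s1, s2 = z1.var(axis=1, ddof=1), z2.var(axis=1, ddof=1)
        a_hat = (zb1 - zb2) / design.denom
        v_a = (s1 / design.n1 + s2 / design.n2) / design.denom**2
        a_sq = a_hat**2 - v_a
        a1ma = a_hat - a_sq
        for est, truth in [(a_hat, a), (a_sq, a**2), (a1ma, a * (1 - a))]:
            se = est.std(ddof=1) / np.sqrt(est.size)
            assert est.mean() == pytest.approx(truth, abs=4 * se)

    def test_a_functions_match_momentsummary_api(self, pop, params, scr_pair):
        design = TwoSampleDesign(*scr_pair, -1, 120, 80)
        z1, z2 = _two_sample_matrices(design, pop, params, seed=56)
        m = mm.MomentSummary(z1.mean(), z2.mean(), z1.var(ddof=1), z2.var(ddof=1),
                             z1.size, z2.size)
        a_hat, a_sq, a1ma = mm.unbiased_A_functions(m, design, params)
        assert a_hat == pytest.approx((z1.mean() - z2.mean()) / 6.0)
        assert a1ma == pytest.approx(a_hat - a_sq)

    @pytest.mark.parametrize("k", [0.0, 0.5, 1.0])
    def test_sigma_x_estimator_unbiased(self, pop, params, scr_pair, k):
        design = TwoSampleDesign(*scr_pair, -1, 100, 100)
        reps = 4000
        z1, z2 = _two_sample_matrices(design, pop, params, seed=77, reps=reps)
        zb1, zb2 = z1.mean(axis=1), z2.mean(axis=1)
        s1, s2 = z1.var(axis=1, ddof=1), z2.var(axis=1, ddof=1)
        a_hat = (zb1 - zb2) / design.denom
        v_a = (s1 / design.n1 + s2 / design.n2) / design.denom**2
        a1ma = a_hat - (a_hat**2 - v_a)
        comp1 = s1 - a_hat * design.scrambler1.gamma_sq - a1ma * design.theta1**2
        comp2 = s2 - a_hat * design.scrambler2.gamma_sq - a1ma * design.theta2**2
        est = k * comp1 + (1 - k) * comp2
        se = est.std(ddof=1) / np.sqrt(reps)
        assert est.mean() == pytest.approx(pop.var_x, abs=4 * se)

    def test_sigma_x_point_mass_scrambler_drops_gamma_term(self, params):
        design = TwoSampleDesign(Scrambler(2.0, 0.0, "point_mass"),
                                 Scrambler(4.0, 0.0, "point_mass"), -1, 10, 10)
        m = mm.MomentSummary(10.8, 8.4, 5.0, 6.0, 10, 10)
        a_hat, _, a1ma = mm.unbiased_A_functions(m, design, params)
        got = mm.estimate_sigma_x(m, design, params, k=1.0)
        assert got == pytest.approx(m.s_sq_1 - a1ma * design.theta1**2)

    def test_sigma_x_invalid_k_rejected(self, params, scr_pair):
        design = TwoSampleDesign(*scr_pair, -1, 10, 10)
        m = mm.MomentSummary(10.0, 9.0, 2.0, 3.0, 10, 10)
        with pytest.raises(ValueError):
            mm.estimate_sigma_x(m, design, params, k=1.5)
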
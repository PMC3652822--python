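"""Small-switching approximation layer against the exact-dynamics oracle."""

import math

import numpy as np
import pytest

import persisterpop as pp
from persisterpop.dynamics import sample_exact

GAPS = pp.presets.ecoli_gaps()


def exact_ratio_curve(env, r0_np, t_grid, total=1.0):
    """Oriented exact ratio r(t) sampled from the linear dynamics; r0_np
    is the initial n/p ratio."""
    n0 = total * r0_np / (1 + r0_np)
    traj = sample_exact(env, pp.PopulationState(0.0, n0, total - n0), t_grid)
    if env.rates.mu_n >= env.rates.mu_p:
        return traj.n / traj.p
    return traj.p / traj.n


class TestRatioFixedPoints:
    def test_one_way_switching_factorizes(self):
        env = pp.growth_environment(2.0, 0.2, 0.2, 0.0)
        fp = pp.ratio_fixed_points(env)
        assert fp.r_stable == pytest.approx((1.8 - 0.2) / 0.2, rel=1e-14)
        assert fp.r_unstable == 0.0

    def test_tiny_switching_leading_order(self):
        env = pp.presets.ecoli_growth(1e-6, 1e-6)
        fp = pp.ratio_fixed_points(env)
        assert fp.r_stable == pytest.approx(1.8 / 1e-6, rel=1e-5)

    @pytest.mark.parametrize("a,b", [(1e-6, 1e-4), (1e-3, 1e-5), (0.08, 0.03)])
    @pytest.mark.parametrize("condition", ["growth", "stress"])
    def test_stable_root_is_dominant_eigen_structure(self, a, b, condition):
        env = (
            pp.presets.ecoli_growth(a, b)
            if condition == "growth"
            else pp.presets.ecoli_stress(a, b)
        )
        fp = pp.ratio_fixed_points(env)
        _, ratio_np = pp.dominant_eigenpair(env)
        oriented = ratio_np if condition == "growth" else 1.0 / ratio_np
        assert fp.r_stable == pytest.approx(oriented, rel=1e-10)
        assert fp.r_stable > 0 > fp.r_unstable or fp.r_unstable == 0.0

    def test_rhs_sign_brackets_stable_point(self):
        # flow is toward r_stable: positive below, negative above
        env = pp.presets.ecoli_growth(1e-4, 1e-3)
        fp = pp.ratio_fixed_points(env)
        a, b = 1e-4, 1e-3

        def rhs(r):
            return -a * r * r + (1.8 - a + b) * r + b

        for r in np.linspace(fp.r_stable * 0.1, fp.r_stable * 0.99, 7):
            assert rhs(r) > 0
        for r in np.linspace(fp.r_stable * 1.01, fp.r_stable * 10, 7):
            assert rhs(r) < 0

    def test_requires_outward_switching(self):
        env = pp.growth_environment(2.0, 0.2, 0.0, 1e-3)
        with pytest.raises(pp.ValidationError):
            pp.ratio_fixed_points(env)


class TestSteadyStateStructure:
    def test_persister_fraction_leading_order(self):
        env = pp.presets.ecoli_growth(1.8e-6, 1e-4)
        ss = pp.steady_state_structure(env, GAPS)
        assert ss.persister_fraction == pytest.approx(1e-6, rel=1e-5)

    def test_fraction_ratio_consistency(self):
        env = pp.presets.ecoli_growth(1e-4, 1e-3)
        ss = pp.steady_state_structure(env, GAPS)
        assert ss.persister_fraction == 1.0 / (1.0 + ss.ratio_star)

    @pytest.mark.parametrize("a", [1e-6, 1e-5, 1e-4])
    @pytest.mark.parametrize("b", [1e-6, 1e-4, 1e-3])
    def test_effective_rate_error_quadratic_in_switching(self, a, b):
        env = pp.presets.ecoli_growth(a, b)
        ss = pp.steady_state_structure(env, GAPS)
        lam, _ = pp.dominant_eigenpair(env)
        assert abs(ss.effective_rate - lam) <= 10.0 * a * b / 1.8

    def test_stress_effective_rate_is_minus_kappa_p_minus_b(self):
        env = pp.presets.ecoli_stress(1e-5, 1e-3)
        ss = pp.steady_state_structure(env, GAPS)
        assert ss.effective_rate == pytest.approx(-(0.1 + 1e-3))

    def test_symmetric_parameters(self):
        # a=b, mu_p = -mu_n: persister fraction a/(2 mu_n) at leading order
        a = 1e-4
        env = pp.growth_environment(1.0, -1.0, a, a)
        ss = pp.steady_state_structure(env, pp.RateGaps(2.0, 2.0))
        assert ss.persister_fraction == pytest.approx(a / 2.0, rel=1e-3)

    def test_relaxation_rate_matches_ode_linearization(self):
        # numeric slope of the ratio ODE at the exact stable fixed point
        a, b = 1e-3, 5e-3
        env = pp.presets.ecoli_growth(a, b)
        ss = pp.steady_state_structure(env, GAPS)
        r_s = pp.ratio_fixed_points(env).r_stable

        def rhs(r):
            return -a * r * r + (1.8 - a + b) * r + b

        h = r_s * 1e-6
        slope = (rhs(r_s + h) - rhs(r_s - h)) / (2 * h)
        assert ss.relaxation_rate == pytest.approx(-slope, rel=1e-6)

    def test_mislabeled_condition_rejected(self):
        env = pp.presets.ecoli_growth()
        with pytest.raises(pp.ValidationError):
            pp.steady_state_structure(env, pp.RateGaps(-1.8, 1.9))


class TestOrientationSymmetry:
    def test_exchange_rules_map_growth_onto_stress(self):
        # swapping phenotype roles and a<->b must reproduce the oriented
        # outputs exactly
        a, b = 2e-4, 7e-3
        env_g = pp.growth_environment(2.0, 0.2, a, b)
        env_m = pp.EnvironmentParams(
            rates=pp.PhenotypeRates(mu_n=0.2, mu_p=2.0),
            switching=pp.SwitchingRates(a=b, b=a),
            label="mirror-stress",
        )
        fp_g, fp_m = pp.ratio_fixed_points(env_g), pp.ratio_fixed_points(env_m)
        assert fp_m.r_stable == pytest.approx(fp_g.r_stable, rel=1e-14)
        assert fp_m.r_unstable == pytest.approx(fp_g.r_unstable, rel=1e-14)
        gaps = pp.RateGaps(delta_mu=1.8, delta_kappa=1.8)
        ss_g = pp.steady_state_structure(env_g, gaps)
        ss_m = pp.steady_state_structure(env_m, gaps)
        assert ss_m.ratio_star == ss_g.ratio_star
        assert ss_m.relaxation_rate == ss_g.relaxation_rate
        assert ss_m.persister_fraction == pytest.approx(1.0 - ss_g.persister_fraction)


class TestStationaryPhaseFraction:
    def test_balance_values(self):
        assert pp.stationary_phase_fraction(pp.SwitchingRates(3e-4, 3e-4)) == 0.5
        assert pp.stationary_phase_fraction(
            pp.SwitchingRates(1e-6, 1e-4)
        ) == pytest.approx(0.00990, abs=1e-5)

    def test_zero_rates_rejected(self):
        with pytest.raises(pp.ValidationError):
            pp.stationary_phase_fraction(pp.SwitchingRates(0.0, 0.0))

    def test_matches_capacity_model_long_time(self):
        a, b = 1e-3, 0.05
        env = pp.presets.ecoli_growth(a, b, carrying_capacity=1e8)
        grid = np.linspace(0.0, 400.0, 120)
        traj = pp.integrate_capacity(env, pp.PopulationState(0, 1e4, 0.0), grid)
        frac = traj.p[-1] / traj.total[-1]
        assert frac == pytest.approx(pp.stationary_phase_fraction(pp.SwitchingRates(a, b)), rel=0.05)


class TestLogisticRatio:
    def test_fixed_point_is_constant(self):
        env = pp.presets.ecoli_growth(1e-5, 1e-4)
        r_star = 1.8 / 1e-5
        for t in (0.0, 1.0, 40.0):
            assert pp.logistic_ratio(t, r_star, env, GAPS) == pytest.approx(r_star, rel=1e-12)

    def test_long_time_limit(self):
        env = pp.presets.ecoli_growth(1e-5, 1e-4)
        assert pp.logistic_ratio(50.0, 3.0, env, GAPS) == pytest.approx(1.8 / 1e-5, rel=1e-6)

    def test_initial_condition_exact(self):
        env = pp.presets.ecoli_stress(1e-5, 1e-4)
        assert pp.logistic_ratio(0.0, 2.5, env, GAPS) == 2.5

    def test_tracks_exact_ratio_within_one_percent(self):
        env = pp.presets.ecoli_growth(1e-6, 1e-6)
        grid = np.linspace(0.0, 15.0, 200)
        exact = exact_ratio_curve(env, 1.0, grid)
        approx = np.array([pp.logistic_ratio(t, 1.0, env, GAPS) for t in grid])
        assert np.max(np.abs(approx - exact) / exact) < 0.01

    def test_error_scales_at_least_linearly(self):
        grid = np.linspace(0.0, 15.0, 120)
        errs = []
        for scale in (1e-4, 1e-5, 1e-6):
            env = pp.presets.ecoli_growth(scale, scale)
            exact = exact_ratio_curve(env, 1.0, grid)
            approx = np.array([pp.logistic_ratio(t, 1.0, env, GAPS) for t in grid])
            errs.append(float(np.max(np.abs(approx - exact) / exact)))
        # a 10x reduction of the switching rates cuts the error >= 10x
        assert errs[1] <= errs[0] / 10.0 * 1.05
        assert errs[2] <= errs[1] / 10.0 * 1.05
        assert errs[2] < 0.01

    def test_negative_initial_ratio_rejected(self):
        with pytest.raises(pp.ValidationError):
            pp.logistic_ratio(1.0, -0.5, pp.presets.ecoli_growth(), GAPS)


class TestAverageSubpopGrowth:
    def test_no_switching_returns_bare_rates(self):
        env = pp.growth_environment(2.0, 0.2, 0.0, 0.0)
        assert pp.average_subpop_growth(0.0, 5.0, env, GAPS, 10.0) == (2.0, 0.2)

    def test_long_time_rates_converge_to_effective_rate(self):
        env = pp.presets.ecoli_growth(1e-6, 1e-6)
        rn, rp = pp.average_subpop_growth(0.0, 2000.0, env, GAPS, 1.8 / 1e-6)
        eff = pp.steady_state_structure(env, GAPS).effective_rate
        assert rn == pytest.approx(eff, rel=1e-5)
        assert rp == pytest.approx(eff, rel=1e-5)

    @pytest.mark.parametrize("condition", ["growth", "stress"])
    def test_matches_exact_trajectory_averages(self, condition):
        a, b = 1e-5, 1e-4
        env = (
            pp.presets.ecoli_growth(a, b)
            if condition == "growth"
            else pp.presets.ecoli_stress(a, b)
        )
        r0_np = 50.0
        s0 = pp.PopulationState(0.0, r0_np / (1 + r0_np), 1 / (1 + r0_np))
        T = 10.0
        traj = sample_exact(env, s0, [0.0, T])
        rn_num = math.log(traj.n[1] / traj.n[0]) / T
        rp_num = math.log(traj.p[1] / traj.p[0]) / T
        r0 = r0_np if condition == "growth" else 1.0 / r0_np
        rn, rp = pp.average_subpop_growth(0.0, T, env, GAPS, r0)
        assert rn == pytest.approx(rn_num, rel=0.01, abs=2e-3)
        assert rp == pytest.approx(rp_num, rel=0.01, abs=2e-3)


class TestTotalDoubleExponential:
    def test_single_population_single_exponential(self):
        env = pp.growth_environment(2.0, 0.2, 0.0, 1e-4)
        val = pp.total_double_exponential(3.0, 5.0, 0.0, env, GAPS)
        assert val == pytest.approx(5.0 * math.exp(2.0 * 3.0), rel=1e-12)

    def test_initial_value_exact(self):
        env = pp.presets.ecoli_stress(1e-5, 1e-3)
        assert pp.total_double_exponential(0.0, 7.0, 3.0, env, GAPS) == pytest.approx(10.0)

    @pytest.mark.parametrize("condition", ["stress", "growth"])
    def test_within_two_percent_of_exact_over_15h(self, condition):
        a, b = 1e-5, 1e-3
        if condition == "stress":
            env = pp.presets.ecoli_stress(a, b)
            n0, p0 = 1e8, 1e8 * a / 1.8
        else:
            env = pp.presets.ecoli_growth(a, b)
            n0, p0 = 1e2 * b / 1.9, 1e2
        grid = np.linspace(0.0, 15.0, 100)
        traj = sample_exact(env, pp.PopulationState(0, n0, p0), grid)
        approx = np.array(
            [pp.total_double_exponential(t, n0, p0, env, GAPS) for t in grid]
        )
        assert np.max(np.abs(approx - traj.total) / traj.total) < 0.02

    def test_negative_counts_rejected(self):
        with pytest.raises(pp.ValidationError):
            pp.total_double_exponential(1.0, -1.0, 2.0, pp.presets.ecoli_growth(), GAPS)


class TestAverageTotalGrowth:
    def test_pure_normal_no_switching(self):
        env = pp.growth_environment(2.0, 0.2, 0.0, 0.0)
        for t in (0.5, 5.0, 50.0):
            assert pp.average_total_growth(t, env, GAPS, math.inf) == pytest.approx(2.0)

    def test_long_time_limit_is_effective_rate(self):
        env = pp.presets.ecoli_growth(1e-5, 1e-4)
        rate = pp.average_total_growth(4000.0, env, GAPS, 1.0)
        assert rate == pytest.approx(2.0 - 1e-5, rel=1e-4)

    def test_matches_numeric_log_slope(self):
        a, b = 1e-5, 1e-4
        env = pp.presets.ecoli_growth(a, b)
        r0 = 10.0
        s0 = pp.PopulationState(0.0, r0 / (1 + r0), 1 / (1 + r0))
        for T in (2.0, 8.0, 15.0):
            traj = sample_exact(env, s0, [0.0, T])
            num = math.log(traj.total[1] / traj.total[0]) / T
            assert pp.average_total_growth(T, env, GAPS, r0) == pytest.approx(num, rel=0.01)
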
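"""Closed-form two-compartment kernel against an independent stiff-ODE
oracle, analytic AUC identities, covariate equations and exposure metrics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from colipk.data import Covariates, DoseEvent, Regimen, mu_to_mg
from colipk.pkmodel import (IndividualParams, PopulationParams,
                            add_residual_error, exposure_metrics,
                            individual_params, model_auc, simulate_profile,
                            steady_state_css_avg)
from colipk.synth import generate_true_params


def ode_profile(ind, doses, times, rtol=1e-10):
    """Independent oracle: numerically integrate the two-compartment
    infusion ODE system with a stiff-capable solver."""
    k10, k12 = ind.CL / ind.V, ind.CL2 / ind.V
    k21 = ind.CL2 / ind.V2 if ind.V2 > 0 else 0.0

    def rate_in(t):
        return sum(d.rate for d in doses
                   if d.start_time <= t < d.start_time + d.infusion_duration)

    def rhs(t, y):
        a1, a2 = y
        return [rate_in(t) - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]

    sol = solve_ivp(rhs, (0.0, max(times)), [0.0, 0.0], method="LSODA",
                    t_eval=times, max_step=0.25, rtol=rtol, atol=1e-13)
    return sol.y[0] / ind.V


TYPICAL = IndividualParams(V=16.1, V2=50.5, CL=1.50, CL2=1.71)


class TestClosedForm:
    def test_single_infusion_matches_ode(self):
        doses = [DoseEvent(0.0, 22.0, 2.0)]
        times = np.linspace(0.05, 48.0, 80)
        closed = simulate_profile(TYPICAL, doses, times).concentrations
        oracle = ode_profile(TYPICAL, doses, times)
        np.testing.assert_allclose(closed, oracle, rtol=1e-6)

    def test_randomized_parameters_match_ode(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            ind = IndividualParams(
                V=rng.uniform(5, 60), V2=rng.uniform(5, 200),
                CL=rng.uniform(0.2, 10), CL2=rng.uniform(0.05, 10))
            doses = [DoseEvent(0.0, rng.uniform(10, 90), rng.uniform(0.5, 3))]
            times = np.linspace(0.1, 36.0, 25)
            closed = simulate_profile(ind, doses, times).concentrations
            oracle = ode_profile(ind, doses, times)
            np.testing.assert_allclose(closed, oracle, rtol=1e-6)

    def test_superposition(self):
        d1 = [DoseEvent(0.0, 22.0, 2.0)]
        d2 = [DoseEvent(12.0, 33.0, 1.0)]
        times = np.linspace(0.0, 36.0, 60)
        both = simulate_profile(TYPICAL, d1 + d2, times).concentrations
        split = (simulate_profile(TYPICAL, d1, times).concentrations
                 + simulate_profile(TYPICAL, d2, times).concentrations)
        np.testing.assert_allclose(both, split, rtol=1e-12, atol=1e-15)

    def test_zero_before_first_dose(self):
        prof = simulate_profile(TYPICAL, [DoseEvent(4.0, 22.0, 2.0)],
                                [0.0, 2.0, 3.999])
        assert np.all(prof.concentrations == 0.0)

    def test_one_compartment_limit(self):
        # CL2 -> 0 collapses to the one-compartment infusion closed form
        ind = IndividualParams(V=16.1, V2=1.0, CL=1.5, CL2=0.0)
        R, T, k = 11.0, 2.0, 1.5 / 16.1
        t = np.linspace(0.1, 24.0, 40)
        expected = np.where(
            t <= T, R / 1.5 * (1 - np.exp(-k * t)),
            R / 1.5 * (1 - np.exp(-k * T)) * np.exp(-k * (t - T)))
        got = simulate_profile(ind, [DoseEvent(0.0, 22.0, T)], t).concentrations
        np.testing.assert_allclose(got, expected, rtol=1e-6)

    def test_near_repeated_root_stable(self):
        # alpha ~ beta to 1e-10: result must still match the ODE oracle
        ind = IndividualParams(V=10.0, V2=10.0 * (1 + 1e-10), CL=1.0, CL2=1e-8)
        t = np.linspace(0.1, 24.0, 30)
        closed = simulate_profile(ind, [DoseEvent(0.0, 22.0, 2.0)], t).concentrations
        oracle = ode_profile(ind, [DoseEvent(0.0, 22.0, 2.0)], t)
        np.testing.assert_allclose(closed, oracle, rtol=1e-6)

    def test_nonnegative_concentrations(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            ind = IndividualParams(V=rng.uniform(1, 100), V2=rng.uniform(1, 300),
                                   CL=rng.uniform(0.01, 20), CL2=rng.uniform(0, 20))
            t = rng.uniform(0, 100, 20)
            prof = simulate_profile(ind, [DoseEvent(0.0, 44.0, 1.0)], np.sort(t))
            assert np.all(prof.concentrations >= 0.0)


class TestAnalyticAuc:
    def test_auc_zero_to_inf_is_dose_over_cl(self):
        doses = [DoseEvent(0.0, 22.0, 2.0)]
        assert model_auc(TYPICAL, doses, 0.0, np.inf) == pytest.approx(
            22.0 / 1.50, rel=1e-12)

    def test_auc_matches_dense_trapezoid(self):
        reg = Regimen(maintenance_dose=0.75, interval=12, loading_dose=1.0)
        doses = reg.dose_events(72.0)
        grid = np.arange(0.0, 24.0 + 1e-9, 0.01)
        dense = simulate_profile(TYPICAL, doses, grid).concentrations
        trap = np.trapezoid(dense, grid)
        assert model_auc(TYPICAL, doses, 0.0, 24.0) == pytest.approx(
            trap, rel=1e-3)

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            model_auc(TYPICAL, [DoseEvent(0, 22, 2)], 10.0, 5.0)

    def test_partial_interval_additivity(self):
        doses = [DoseEvent(0.0, 40.0, 1.5)]
        whole = model_auc(TYPICAL, doses, 0.0, 30.0)
        split = (model_auc(TYPICAL, doses, 0.0, 7.3)
                 + model_auc(TYPICAL, doses, 7.3, 30.0))
        assert whole == pytest.approx(split, rel=1e-12)


class TestCovariateModel:
    def test_reference_covariates_give_typical_values(self, true_params):
        cov = Covariates(crcl=57.5, alt=37.0, weight=55, age=60, sex="male")
        ind = individual_params(true_params, cov)
        assert ind.CL == pytest.approx(1.50)
        assert ind.V2 == pytest.approx(50.5)
        assert ind.V == pytest.approx(16.1)
        assert ind.CL2 == pytest.approx(1.71)

    def test_doubled_crcl_power_function(self, true_params):
        cov = Covariates(crcl=115.0, alt=37.0, weight=55, age=60, sex="male")
        ind = individual_params(true_params, cov)
        assert ind.CL == pytest.approx(1.50 * 2.0 ** 0.353)

    def test_zero_exponents_ignore_covariates(self, true_params):
        p = true_params.replace(dV2dALT=0.0, dCLdCrCL=0.0)
        cov = Covariates(crcl=150.0, alt=400.0, weight=55, age=60, sex="male")
        ind = individual_params(p, cov)
        assert ind.CL == pytest.approx(p.tvCL)
        assert ind.V2 == pytest.approx(p.tvV2)

    def test_monotone_in_covariates(self, true_params):
        def cl(crcl):
            cov = Covariates(crcl=crcl, alt=37, weight=55, age=60, sex="male")
            return individual_params(true_params, cov).CL

        def v2(alt):
            cov = Covariates(crcl=57.5, alt=alt, weight=55, age=60, sex="male")
            return individual_params(true_params, cov).V2

        crcls = [10, 30, 60, 120, 190]
        assert all(cl(a) < cl(b) for a, b in zip(crcls, crcls[1:]))
        alts = [7, 37, 100, 400]
        assert all(v2(a) < v2(b) for a, b in zip(alts, alts[1:]))

    def test_eta_scales_lognormally(self, true_params):
        cov = Covariates(crcl=57.5, alt=37.0, weight=55, age=60, sex="male")
        ind = individual_params(true_params, cov, eta_V=0.3, eta_CL=-0.2)
        assert ind.V == pytest.approx(16.1 * np.exp(0.3))
        assert ind.CL == pytest.approx(1.50 * np.exp(-0.2))

    def test_population_params_invariants(self):
        with pytest.raises(ValueError):
            PopulationParams(tvV=-1, tvV2=50, tvCL=1.5, tvCL2=1.7,
                             dV2dALT=0.6, dCLdCrCL=0.35, omega2_V=0.02,
                             omega2_CL=0.2, sigma_prop=0.23)


class TestExposureMetrics:
    def test_steady_state_average_identity(self):
        # 36 mg q12h at CL = 1.5 L/h: Css,avg = 36 / (1.5 * 12) = 2 mg/L
        reg = Regimen(maintenance_dose=36.0 / 44.0, interval=12)
        assert steady_state_css_avg(1.50, reg) == pytest.approx(2.0)

    def test_metric_ordering_and_dose_linearity(self):
        reg1 = Regimen(maintenance_dose=0.5, interval=12)
        reg2 = Regimen(maintenance_dose=1.0, interval=12)
        m1 = exposure_metrics(TYPICAL, reg1, eval_day=3)
        m2 = exposure_metrics(TYPICAL, reg2, eval_day=3)
        assert m1.css_min <= m1.css_avg <= m1.css_max
        for field in ("auc_0_24_day1", "auc_24_day3", "css_min", "css_max",
                      "css_avg", "css_avg_ss"):
            assert getattr(m2, field) == pytest.approx(
                2.0 * getattr(m1, field), rel=1e-9)

    def test_day3_average_below_true_steady_state(self):
        # terminal half-life ~48 h: day-3 exposure still accumulating
        reg = Regimen(maintenance_dose=0.75, interval=12)
        m = exposure_metrics(TYPICAL, reg, eval_day=3)
        assert m.css_avg < m.css_avg_ss
        assert m.css_avg > 0.5 * m.css_avg_ss

    def test_rejects_eval_day_zero(self):
        with pytest.raises(ValueError):
            exposure_metrics(TYPICAL, Regimen(maintenance_dose=0.5, interval=12),
                             eval_day=0)


class TestResidualError:
    def test_sigma_zero_identity(self, rng):
        conc = np.array([0.5, 1.0, 3.0])
        np.testing.assert_array_equal(add_residual_error(conc, 0.0, rng), conc)

    def test_moments(self, rng):
        draws = add_residual_error(np.full(100_000, 2.0), 0.228, rng)
        se_mean = 2.0 * 0.228 / np.sqrt(100_000)
        assert draws.mean() == pytest.approx(2.0, abs=3 * se_mean)
        assert draws.std() == pytest.approx(2.0 * 0.228, rel=0.03)

    def test_negative_draws_truncated(self, rng):
        draws = add_residual_error(np.full(10_000, 0.01), 5.0, rng)
        assert np.all(draws >= 0.0)
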
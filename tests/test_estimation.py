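"""Estimation engine: Laplace objective against independent oracles,
information-criterion identities, SCM mechanics, bootstrap and pcVPC."""

import numpy as np
import pytest
from scipy import integrate, optimize

from colipk.data import Covariates, DoseEvent, PatientRecord, PlasmaSample
from colipk.estimation import (ModelSpec, PopPKModel, base_model_spec,
                               bootstrap, final_model_spec, fit, neg2ll,
                               one_compartment_spec, pcvpc, scm)
from colipk.pkmodel import IndividualParams, simulate_profile
from colipk.synth import generate_enriched_study, generate_true_params


@pytest.fixture(scope="module")
def fitted_small(enriched_small):
    records, _ = enriched_small
    model = PopPKModel(records, final_model_spec(),
                       refs={"CRCL": 57.5, "ALT": 37.0})
    return model.fit(compute_se=True)


class TestObjective:
    @pytest.fixture()
    def one_eta_setup(self):
        cov = Covariates(crcl=57.5, alt=37.0, weight=55, age=60, sex="male")
        doses = [DoseEvent(0.0, 33.0, 2.0)]
        spec = ModelSpec(n_compartments=2, iiv_parameters=("CL",))
        records = [
            PatientRecord("A", cov, doses, [PlasmaSample(6.0, 1.2)]),
            PatientRecord("B", cov, doses, [PlasmaSample(6.0, 1.4)]),
        ]
        values = {"tvV": 16.1, "tvV2": 50.5, "tvCL": 1.5, "tvCL2": 1.71,
                  "omega2_CL": 0.197, "sigma_prop": 0.228}
        return spec, records, values

    @staticmethod
    def _g_1d(eta, y, t_obs, doses, omega2, sigma):
        ind = IndividualParams(V=16.1, V2=50.5, CL=1.5 * np.exp(eta), CL2=1.71)
        c = simulate_profile(ind, doses, [t_obs]).concentrations[0]
        var = (sigma * c) ** 2
        return (0.5 * ((y - c) ** 2 / var + np.log(2 * np.pi * var))
                + 0.5 * (eta ** 2 / omega2 + np.log(2 * np.pi * omega2)))

    def test_matches_independent_laplace_oracle(self, one_eta_setup):
        """One subject, one observation, proportional error: the engine's
        value equals a hand-rolled 1-D Laplace integral (independent mode
        search + second-difference curvature)."""
        spec, records, values = one_eta_setup
        engine_val = neg2ll(spec, records, values)

        def laplace_1d(y):
            r = optimize.minimize_scalar(
                lambda e: self._g_1d(e, y, 6.0, records[0].doses, 0.197, 0.228),
                bounds=(-4, 4), method="bounded", options={"xatol": 1e-12})
            h = 1e-5
            g0 = self._g_1d(r.x, y, 6.0, records[0].doses, 0.197, 0.228)
            gp = self._g_1d(r.x + h, y, 6.0, records[0].doses, 0.197, 0.228)
            gm = self._g_1d(r.x - h, y, 6.0, records[0].doses, 0.197, 0.228)
            return 2 * g0 + np.log((gp - 2 * g0 + gm) / h ** 2) - np.log(2 * np.pi)

        oracle = laplace_1d(1.2) + laplace_1d(1.4)
        assert engine_val == pytest.approx(oracle, rel=1e-6)

    def test_laplace_close_to_exact_quadrature(self, one_eta_setup):
        """The approximation should track the exact marginal integral to a
        few percent at this sample size (informational guard)."""
        spec, records, values = one_eta_setup
        engine_val = neg2ll(spec, records, values)

        def exact(y):
            I, _ = integrate.quad(
                lambda e: np.exp(-self._g_1d(e, y, 6.0, records[0].doses,
                                             0.197, 0.228)), -5, 5, limit=200)
            return -2 * np.log(I)

        assert engine_val == pytest.approx(exact(1.2) + exact(1.4), rel=0.05)

    def test_zero_iiv_reduces_to_naive_likelihood(self, one_eta_setup):
        spec, records, values = one_eta_setup
        values = dict(values, omega2_CL=0.0)
        engine_val = neg2ll(spec, records, values)

        def naive(y):
            ind = IndividualParams(V=16.1, V2=50.5, CL=1.5, CL2=1.71)
            c = simulate_profile(ind, records[0].doses, [6.0]).concentrations[0]
            var = (0.228 * c) ** 2
            return (y - c) ** 2 / var + np.log(2 * np.pi * var)

        assert engine_val == pytest.approx(naive(1.2) + naive(1.4), rel=1e-8)

    def test_deterministic(self, enriched_small, true_params):
        records, _ = enriched_small
        model = PopPKModel(records, final_model_spec(),
                           refs={"CRCL": 57.5, "ALT": 37.0})
        assert model.neg2ll(true_params) == model.neg2ll(true_params)


class TestFit:
    def test_information_criterion_identities(self, fitted_small):
        k = fitted_small.k_parameters
        assert k == 9
        assert fitted_small.aic == pytest.approx(fitted_small.neg2ll + 2 * k)
        assert fitted_small.bic == pytest.approx(
            fitted_small.neg2ll + k * np.log(fitted_small.n_obs))

    def test_nesting_extra_parameter_never_hurts(self, enriched_small):
        records, _ = enriched_small
        base = fit(base_model_spec(), records, compute_se=False)
        ext = fit(final_model_spec(), records,
                  refs={"CRCL": 57.5, "ALT": 37.0}, compute_se=False)
        assert ext.neg2ll <= base.neg2ll + 1e-6

    def test_refit_from_estimates_is_stationary(self, enriched_small,
                                                fitted_small):
        records, _ = enriched_small
        again = fit(final_model_spec(), records, inits=fitted_small.params,
                    refs={"CRCL": 57.5, "ALT": 37.0}, compute_se=False)
        assert again.neg2ll == pytest.approx(fitted_small.neg2ll, abs=1e-2)

    def test_cv_percent_and_shrinkage_reported(self, fitted_small):
        assert set(fitted_small.cv_percent) <= set(fitted_small.params)
        assert fitted_small.cv_percent.get("tvCL", 0) > 0
        for par, shr in fitted_small.eta_shrinkage.items():
            assert shr <= 100.0

    def test_summary_table(self, fitted_small):
        text = fitted_small.summary()
        for token in ("tvV2", "dCLdCRCL", "omega2_CL", "sigma_prop", "AIC"):
            assert token in text

    def test_population_params_round_trip(self, fitted_small):
        pop = fitted_small.population_params
        assert pop.tvCL == pytest.approx(fitted_small.params["tvCL"])
        assert pop.crcl_ref == 57.5

    def test_requires_two_subjects(self, enriched_small):
        records, _ = enriched_small
        with pytest.raises(ValueError):
            PopPKModel(records[:1], final_model_spec())


class TestScm:
    def test_empty_candidates_returns_base(self, enriched_small):
        records, _ = enriched_small
        res = scm(base_model_spec(), records, candidates=[], compute_se=False)
        assert res.final_assignments == ()
        assert res.forward_trace == []

    def test_trace_thresholds(self, enriched_small):
        records, _ = enriched_small
        res = scm(base_model_spec(), records,
                  candidates=[("CL", "CRCL", "power")], compute_se=False)
        for name, dofv, accepted in res.forward_trace:
            if accepted:
                assert dofv > 3.84
        if res.final_assignments:
            # retained covariates must survive backward elimination
            for name, increase, removed in res.backward_trace:
                if not removed:
                    assert increase > 6.63


class TestBootstrap:
    def test_identity_resample_returns_point_estimates(self, enriched_small,
                                                       fitted_small):
        records, _ = enriched_small
        boot = bootstrap(final_model_spec(), records, n_resamples=1,
                         rng=np.random.default_rng(0),
                         inits=fitted_small.params,
                         refs={"CRCL": 57.5, "ALT": 37.0},
                         resampler=lambda rng, n: np.arange(n))
        for k, v in boot.median.items():
            assert v == pytest.approx(fitted_small.params[k], rel=1e-3)
        assert boot.n_failed == 0

    def test_resample_preserves_subject_count(self, enriched_small,
                                              fitted_small):
        records, _ = enriched_small
        seen = []

        def spy(rng, n):
            idx = rng.integers(0, n, n)
            seen.append(len(idx))
            return idx

        boot = bootstrap(final_model_spec(), records, n_resamples=3,
                         rng=np.random.default_rng(1),
                         inits=fitted_small.params,
                         refs={"CRCL": 57.5, "ALT": 37.0}, resampler=spy)
        assert seen == [len(records)] * 3
        for k in boot.median:
            assert boot.ci_lower[k] <= boot.median[k] <= boot.ci_upper[k]


class TestPcVpc:
    def test_degenerate_model_bands_collapse_to_prediction(self):
        p = generate_true_params().replace(sigma_prop=1e-9, omega2_V=0.0,
                                           omega2_CL=0.0)
        records, _ = generate_enriched_study(n_patients=12, params=p, seed=2)
        spec = final_model_spec()
        values = {"tvV": p.tvV, "tvV2": p.tvV2, "tvCL": p.tvCL,
                  "tvCL2": p.tvCL2, "dCLdCRCL": p.dCLdCrCL,
                  "dV2dALT": p.dV2dALT, "omega2_V": 0.0, "omega2_CL": 0.0,
                  "sigma_prop": 1e-9}
        v = pcvpc((spec, values), records, n_sim=100,
                  rng=np.random.default_rng(0),
                  refs={"CRCL": 57.5, "ALT": 37.0})
        for q in (5, 50, 95):
            np.testing.assert_allclose(v.observed[q], v.observed[50],
                                       rtol=1e-6)
            lo, hi = v.sim_ci[q]
            np.testing.assert_allclose(lo, v.observed[q], rtol=1e-5)
            np.testing.assert_allclose(hi, v.observed[q], rtol=1e-5)

    def test_constant_prediction_correction_is_identity(self, true_params):
        # identical design and covariates: one PRED per bin, pc = identity
        cov = Covariates(crcl=57.5, alt=37.0, weight=55, age=60, sex="male")
        doses = [DoseEvent(0.0, 33.0, 2.0)]  # single dose: bin == time point
        rng = np.random.default_rng(3)
        records = []
        times = [3.0, 8.0, 13.5, 20.0]
        for i in range(12):
            plasma = [PlasmaSample(t, float(rng.lognormal(0.3, 0.4)))
                      for t in times]
            records.append(PatientRecord(f"C{i}", cov, doses, plasma))
        v = pcvpc((final_model_spec(), {
            "tvV": 16.1, "tvV2": 50.5, "tvCL": 1.5, "tvCL2": 1.71,
            "dCLdCRCL": 0.353, "dV2dALT": 0.635, "omega2_V": 0.0267,
            "omega2_CL": 0.197, "sigma_prop": 0.228}), records, n_sim=100,
            rng=np.random.default_rng(0), n_bins=4,
            refs={"CRCL": 57.5, "ALT": 37.0})
        raw = {t: [] for t in times}
        for r in records:
            for s in r.plasma:
                raw[s.time].append(s.concentration)
        for k, t in enumerate(sorted(times)):
            assert v.observed[50][k] == pytest.approx(
                np.median(raw[t]), rel=1e-9)

    def test_self_simulation_calibration(self, true_params):
        """Data simulated from the model itself: observed percentiles fall
        inside their 80% simulation bands in most bins."""
        records, _ = generate_enriched_study(n_patients=60,
                                             params=true_params, seed=11)
        values = {"tvV": 16.1, "tvV2": 50.5, "tvCL": 1.5, "tvCL2": 1.71,
                  "dCLdCRCL": 0.353, "dV2dALT": 0.635, "omega2_V": 0.0267,
                  "omega2_CL": 0.197, "sigma_prop": 0.228}
        v = pcvpc((final_model_spec(), values), records, n_sim=200,
                  rng=np.random.default_rng(4), n_bins=6,
                  refs={"CRCL": 57.5, "ALT": 37.0})
        inside = 0
        total = 0
        for q in (5, 50, 95):
            lo, hi = v.sim_ci[q]
            inside += int(np.sum((v.observed[q] >= lo) & (v.observed[q] <= hi)))
            total += len(v.observed[q])
        assert inside / total >= 0.7

    def test_requires_enough_simulations(self, enriched_small, true_params):
        records, _ = enriched_small
        with pytest.raises(ValueError):
            pcvpc((final_model_spec(), {
                "tvV": 16.1, "tvV2": 50.5, "tvCL": 1.5, "tvCL2": 1.71,
                "dCLdCRCL": 0.353, "dV2dALT": 0.635, "omega2_V": 0.0267,
                "omega2_CL": 0.197, "sigma_prop": 0.228}), records, n_sim=10,
                rng=np.random.default_rng(0))
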
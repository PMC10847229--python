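"""Pharmacokinetics: closed forms, NCA, allometry, population recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import linregress

from levnet import pk
from levnet import synthetic as syn

PARAMS = pk.PKParameterSet(ka=2.0, cl_f_typ=0.0035, v_f_typ=0.015,
                           ref_weight_kg=0.025)


class TestClosedForm:
    def test_concentration_is_zero_at_dose_time(self):
        prof = pk.simulate_concentration(PARAMS, 0.25, 0.025, [0.0, 1.0])
        assert prof.conc_ng_per_ml[0] == 0.0

    def test_fast_absorption_approaches_bolus(self):
        # ka >> ke: well past tmax the curve matches D/V * exp(-ke t)
        # (relative gap is ke/(ka-ke), ~0.33% at ka = 300*ke)
        p = pk.PKParameterSet(ka=300 * PARAMS.cl_f_typ / PARAMS.v_f_typ,
                              cl_f_typ=PARAMS.cl_f_typ,
                              v_f_typ=PARAMS.v_f_typ, ref_weight_kg=0.025)
        ke = p.cl_f_typ / p.v_f_typ
        t = np.array([2.0, 4.0, 8.0])
        c = pk.one_compartment_concentration(t, 0.25, p.ka, p.cl_f_typ,
                                             p.v_f_typ)
        bolus = 0.25 / p.v_f_typ * np.exp(-ke * t)
        np.testing.assert_allclose(c, bolus, rtol=0.01)

    def test_equal_rate_limit_is_continuous(self):
        # ka == ke hits the analytic limit; nearby ka agrees closely
        v, cl = 0.015, 0.0035
        ke = cl / v
        t = np.linspace(0.1, 10, 50)
        exact = pk.one_compartment_concentration(t, 0.25, ke, cl, v)
        near = pk.one_compartment_concentration(t, 0.25, ke * (1 + 1e-7), cl, v)
        np.testing.assert_allclose(exact, near, rtol=1e-5)

    def test_matches_ode_integration(self):
        # depot -> central two-state linear system as independent oracle
        ka, cl, v, dose = 1.7, 0.004, 0.018, 0.75

        def rhs(t, y):
            depot, central = y
            return [-ka * depot, ka * depot - cl / v * central]

        t_eval = np.array([0.25, 0.5, 1, 2, 4, 6, 24], dtype=float)
        sol = solve_ivp(rhs, (0, 24.0), [dose, 0.0], t_eval=t_eval,
                        rtol=1e-11, atol=1e-14)
        oracle = sol.y[1] / v
        closed = pk.one_compartment_concentration(t_eval, dose, ka, cl, v)
        np.testing.assert_allclose(closed, oracle, rtol=1e-6)

    def test_tmax_closed_form_matches_grid_argmax(self):
        ke = PARAMS.cl_f_typ / PARAMS.v_f_typ
        tmax = pk.tmax_closed_form(PARAMS.ka, ke)
        t = np.linspace(0.01, 12, 4000)
        c = pk.one_compartment_concentration(t, 0.25, PARAMS.ka,
                                             PARAMS.cl_f_typ, PARAMS.v_f_typ)
        assert abs(t[np.argmax(c)] - tmax) < (t[1] - t[0]) * 1.5


class TestAllometry:
    def test_identity_at_reference_weight(self):
        cl, v = pk.apply_allometry(PARAMS, PARAMS.ref_weight_kg)
        assert cl == PARAMS.cl_f_typ and v == PARAMS.v_f_typ

    def test_doubling_weight_forced_by_exponents(self):
        cl, v = pk.apply_allometry(PARAMS, 2 * PARAMS.ref_weight_kg)
        assert cl == pytest.approx(PARAMS.cl_f_typ * 2 ** 0.75, rel=1e-14)
        assert v == pytest.approx(PARAMS.v_f_typ * 2.0, rel=1e-14)

    def test_log_log_slope_is_exactly_three_quarters(self):
        weights = np.geomspace(0.01, 0.05, 30)
        cls = [pk.apply_allometry(PARAMS, w)[0] for w in weights]
        slope = linregress(np.log(weights), np.log(cls)).slope
        assert abs(slope - 0.75) < 1e-10

    @pytest.mark.parametrize("form,expected", [
        ("power", (56 / 30) ** 0.3),
        ("proportional", 1 + 0.3 * (56 / 30 - 1)),
    ])
    def test_dose_covariate_forms(self, form, expected):
        p = pk.PKParameterSet(ka=2, cl_f_typ=1.0, v_f_typ=5.0,
                              ref_weight_kg=0.025, dose_effect_cl=0.3,
                              dose_covariate_form=form)
        cl, _ = pk.apply_allometry(p, 0.025, dose_mg_per_kg=56.0)
        assert cl == pytest.approx(expected, rel=1e-12)


class TestNCA:
    def _dense_profile(self, params=PARAMS, dose=0.25, w=0.025):
        ke = params.cl_f_typ / params.v_f_typ
        t_half = math.log(2) / ke
        times = np.arange(0.01, 10 * t_half, 0.01)
        return pk.simulate_concentration(params, dose, w, times)

    def test_dense_noiseless_auc_recovers_clearance(self):
        prof = self._dense_profile()
        res = pk.run_nca(prof)
        assert res.cl_f_obs == pytest.approx(PARAMS.cl_f_typ, rel=0.005)

    def test_pure_exponential_terminal_slope_exact(self):
        k = 0.31
        t = np.array([1.0, 2.0, 4.0, 6.0])
        c = 800.0 * np.exp(-k * t)
        prof = pk.ConcentrationProfile(times_h=np.concatenate([[0.5], t]),
                                       conc_ng_per_ml=np.concatenate([[900.0], c]),
                                       dose_mg=0.25, weight_kg=0.025)
        res = pk.run_nca(prof)
        assert res.lambda_z == pytest.approx(k, rel=1e-12)

    def test_cmax_tmax_are_the_observed_peak(self):
        prof = pk.ConcentrationProfile(
            times_h=np.array([0.25, 0.5, 1.0, 2.0, 4.0, 6.0]),
            conc_ng_per_ml=np.array([100.0, 400.0, 300.0, 150.0, 60.0, 20.0]),
            dose_mg=0.25, weight_kg=0.025)
        res = pk.run_nca(prof)
        assert res.tmax == 0.5 and res.cmax == 400.0

    def test_increasing_terminal_phase_flagged(self):
        prof = pk.ConcentrationProfile(
            times_h=np.array([0.5, 1.0, 2.0, 4.0, 6.0]),
            conc_ng_per_ml=np.array([10.0, 20.0, 40.0, 80.0, 160.0]),
            dose_mg=0.25, weight_kg=0.025)
        res = pk.run_nca(prof)
        assert res.lambda_z is None and res.auc_0_inf is None
        assert "not estimable" in res.lambda_z_message

    def test_scale_equivariance(self):
        prof = self._dense_profile()
        res = pk.run_nca(prof)
        scaled = pk.ConcentrationProfile(times_h=prof.times_h,
                                         conc_ng_per_ml=3.0 * prof.conc_ng_per_ml,
                                         dose_mg=prof.dose_mg,
                                         weight_kg=prof.weight_kg)
        res3 = pk.run_nca(scaled)
        assert res3.cmax == pytest.approx(3 * res.cmax, rel=1e-12)
        assert res3.auc_0_inf == pytest.approx(3 * res.auc_0_inf, rel=1e-9)
        assert res3.cl_f_obs == pytest.approx(res.cl_f_obs / 3, rel=1e-9)

    def test_trapezoid_refinement_converges_to_dose_over_cl(self):
        # AUC conservation under monotone grid refinement
        truth = 0.25 / PARAMS.cl_f_typ * 1000.0  # ng*h/mL
        errors = []
        for dt in (0.5, 0.1, 0.02):
            ke = PARAMS.cl_f_typ / PARAMS.v_f_typ
            times = np.arange(dt, 12 * math.log(2) / ke, dt)
            prof = pk.simulate_concentration(PARAMS, 0.25, 0.025, times)
            res = pk.run_nca(prof)
            errors.append(abs(res.auc_0_inf - truth) / truth)
        assert errors[0] >= errors[1] >= errors[2]
        assert errors[2] < 0.005


class TestExposure:
    def test_auc_is_dose_over_clearance(self):
        p = pk.PKParameterSet(ka=2, cl_f_typ=0.05, v_f_typ=0.5,
                              ref_weight_kg=0.025)
        est = pk.predict_individual_auc(p, "a1", 0.25, 0.025)
        assert est.auc == pytest.approx(5.0, rel=1e-15)
        assert est.auc_daily_bid == pytest.approx(10.0, rel=1e-15)

    def test_auc_doubles_with_dose_without_covariate(self):
        a = pk.predict_individual_auc(PARAMS, "a", 0.25, 0.025)
        b = pk.predict_individual_auc(PARAMS, "a", 0.50, 0.025)
        assert b.auc == pytest.approx(2 * a.auc, rel=1e-15)

    def test_model_auc_matches_dense_nca(self):
        est = pk.predict_individual_auc(PARAMS, "a", 0.25, 0.025)
        ke = PARAMS.cl_f_typ / PARAMS.v_f_typ
        times = np.arange(0.01, 12 * math.log(2) / ke, 0.01)
        prof = pk.simulate_concentration(PARAMS, 0.25, 0.025, times)
        nca = pk.run_nca(prof)
        assert nca.auc_0_inf / 1000.0 == pytest.approx(est.auc, rel=0.005)


class TestExposureRegression:
    def test_collinear_pairs_give_r2_of_one(self):
        c05 = np.array([1.0, 2.0, 3.0, 4.0])
        reg = pk.exposure_concentration_regression(2.5 * c05 + 1, c05)
        assert reg.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_r2_matches_normal_equations(self, rng):
        x = rng.uniform(100, 5000, 25)
        y = 0.05 * x + rng.normal(0, 20, 25)
        reg = pk.exposure_concentration_regression(y, x)
        sxy = np.cov(x, y, ddof=1)
        r2 = sxy[0, 1] ** 2 / (sxy[0, 0] * sxy[1, 1])
        assert reg.r_squared == pytest.approx(r2, abs=1e-12)

    def test_permutation_null_slope_p_uniform(self, rng):
        x = rng.uniform(0, 1, 20)
        pvals = []
        for _ in range(400):
            y = rng.normal(size=20)
            pvals.append(pk.exposure_concentration_regression(y, x).p_value)
        hist, _ = np.histogram(pvals, bins=10, range=(0, 1))
        # chi-square uniformity check, generous threshold
        chi2 = ((hist - 40.0) ** 2 / 40.0).sum()
        assert chi2 < 27.9  # chi2(9) at p=0.001

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pk.exposure_concentration_regression([1, 2, 3], [5, 5, 5])


class TestPopulationFit:
    def test_noiseless_exact_identifiability(self):
        sim = syn.generate_pk_profiles(
            syn.PKSimSpec(structural=PARAMS, bsv_sd=0, prop_error_sd=0, seed=12))
        res = pk.PopulationPKModel(sim.observations).fit(
            covariate_selection="none")
        assert res.params.ka == pytest.approx(PARAMS.ka, rel=1e-6)
        assert res.params.cl_f_typ == pytest.approx(PARAMS.cl_f_typ, rel=1e-6)
        assert res.params.v_f_typ == pytest.approx(PARAMS.v_f_typ, rel=1e-6)

    def test_recovery_under_variability(self):
        # 50 replicates at study-scale noise: typicals within 15% >=90%
        ok_cl = ok_v = 0
        n_rep = 50
        for rep in range(n_rep):
            sim = syn.generate_pk_profiles(
                syn.PKSimSpec(structural=PARAMS, bsv_sd=0.2,
                              prop_error_sd=0.15, seed=1000 + rep))
            res = pk.PopulationPKModel(sim.observations).fit(
                covariate_selection="none")
            ok_cl += abs(res.params.cl_f_typ - PARAMS.cl_f_typ) / PARAMS.cl_f_typ <= 0.15
            ok_v += abs(res.params.v_f_typ - PARAMS.v_f_typ) / PARAMS.v_f_typ <= 0.15
        assert ok_cl >= 0.9 * n_rep
        assert ok_v >= 0.9 * n_rep

    def test_dose_covariate_detection_power_and_type1(self):
        with_effect = pk.PKParameterSet(
            ka=2.0, cl_f_typ=0.0035, v_f_typ=0.015, ref_weight_kg=0.025,
            dose_effect_cl=0.35)
        kept_effect = kept_null = 0
        n_rep = 20
        for rep in range(n_rep):
            sim = syn.generate_pk_profiles(
                syn.PKSimSpec(structural=with_effect, bsv_sd=0.1,
                              prop_error_sd=0.1, seed=2000 + rep))
            res = pk.PopulationPKModel(sim.observations).fit()
            kept_effect += res.covariate_decisions["dose_on_cl"]
            sim0 = syn.generate_pk_profiles(
                syn.PKSimSpec(structural=PARAMS, bsv_sd=0.1,
                              prop_error_sd=0.1, seed=3000 + rep))
            res0 = pk.PopulationPKModel(sim0.observations).fit()
            kept_null += res0.covariate_decisions["dose_on_cl"]
        assert kept_effect >= 0.9 * n_rep
        assert kept_null <= 0.2 * n_rep

    def test_summary_reports_estimates_and_decisions(self):
        sim = syn.generate_pk_profiles(
            syn.PKSimSpec(structural=PARAMS, bsv_sd=0.1, prop_error_sd=0.1,
                          seed=13))
        res = pk.PopulationPKModel(sim.observations).fit()
        text = res.summary()
        assert "OFV" in text and "covariate decisions" in text
        assert "log_cl_f_typ" in text
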
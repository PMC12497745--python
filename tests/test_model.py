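"""Structural model: covariate scaling, individual realization,
concentration kinetics and the residual model."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clozapk as cz
from clozapk.model import MGL_TO_NGML

from _oracles import ode_concentration, superposition_trough


class TestTypicalParams:
    def test_reference_subject_recovers_standard_values_exactly(self, final_pop):
        tv = cz.typical_params(final_pop, cz.CovariateVector(weight=70.0, zop=0))
        assert tv.cl == final_pop.cl_std
        assert tv.v == final_pop.v_std
        assert tv.ka == final_pop.ka

    @pytest.mark.parametrize(
        "weight, zop, cl_expected, v_expected",
        [
            (70.0, 0, 29.6, 308.0),
            # 29.6 * (40/70)**0.75 * 0.746 and 308 * 40/70
            (40.0, 1, 14.5128264562, 176.0),
            (120.0, 0, 29.6 * (120.0 / 70.0) ** 0.75, 308.0 * 120.0 / 70.0),
        ],
    )
    def test_allometry_and_interaction_factor(self, final_pop, weight, zop, cl_expected, v_expected):
        tv = cz.typical_params(final_pop, cz.CovariateVector(weight=weight, zop=zop))
        assert tv.cl == pytest.approx(cl_expected, rel=1e-9)
        assert tv.v == pytest.approx(v_expected, rel=1e-9)

    def test_zopiclone_multiplies_clearance_by_exact_factor(self, final_pop):
        for w in (45.0, 70.0, 110.0):
            cl0 = cz.typical_params(final_pop, cz.CovariateVector(weight=w, zop=0)).cl
            cl1 = cz.typical_params(final_pop, cz.CovariateVector(weight=w, zop=1)).cl
            assert cl1 / cl0 == pytest.approx(1.0 + final_pop.theta_zop, rel=1e-12)

    @given(w_lo=st.floats(38.0, 119.0), bump=st.floats(0.5, 30.0))
    @settings(max_examples=50, deadline=None)
    def test_clearance_strictly_increases_with_weight(self, w_lo, bump):
        pop = cz.PopulationParameters()
        cl_lo = cz.typical_params(pop, cz.CovariateVector(weight=w_lo)).cl
        cl_hi = cz.typical_params(pop, cz.CovariateVector(weight=w_lo + bump)).cl
        assert cl_hi > cl_lo

    def test_extra_multiplicative_effects_compose(self, final_pop):
        eff = cz.CovariateEffect(target="cl", name="crcl", kind="power", q=0.5, s_m=60.0)
        cov = cz.CovariateVector(weight=70.0, zop=0, extras={"crcl": 90.0})
        tv = cz.typical_params(final_pop, cov, [eff])
        assert tv.cl == pytest.approx(29.6 * (90.0 / 60.0) ** 0.5, rel=1e-12)

    def test_nonpositive_factor_names_offending_effect(self, final_pop):
        eff = cz.CovariateEffect(target="cl", name="flag", kind="linear", q=-2.0)
        cov = cz.CovariateVector(weight=70.0, zop=0, extras={"flag": 1.0})
        with pytest.raises(cz.InvalidModelError, match="flag"):
            cz.typical_params(final_pop, cov, [eff])


class TestIndividualParams:
    def test_zero_eta_is_identity(self, final_pop):
        tv = cz.typical_params(final_pop, cz.CovariateVector(weight=70.0))
        ind = cz.individual_params(tv, 0.0)
        assert ind.cl_i == tv.cl and ind.v_i == tv.v and ind.ka_i == tv.ka

    def test_lognormal_realization(self, final_pop):
        tv = cz.typical_params(final_pop, cz.CovariateVector(weight=70.0))
        up = cz.individual_params(tv, 0.348)
        dn = cz.individual_params(tv, -0.348)
        assert up.cl_i == pytest.approx(29.6 * math.exp(0.348), rel=1e-12)  # 41.9205
        # symmetric etas multiply back to the squared typical value
        assert up.cl_i * dn.cl_i == pytest.approx(tv.cl**2, rel=1e-12)


class TestConcentration:
    def test_no_absorption_at_dose_time(self, typical_ind):
        assert cz.concentration(typical_ind, [cz.DoseEvent(0.0, 560.0)], 0.0) == 0.0

    def test_single_dose_matches_ode_integration(self, typical_ind):
        got = cz.concentration(typical_ind, [cz.DoseEvent(0.0, 560.0)], 12.0)
        want = ode_concentration(29.6, 308.0, 1.3, 560.0, 12.0)
        assert got == pytest.approx(want, rel=1e-7)
        assert got == pytest.approx(619.64, rel=1e-3)

    def test_repeating_regimen_equals_explicit_superposition(self, typical_ind):
        regimen = [cz.DoseEvent(0.0, 280.0, interval=12.0)]
        t = 10 * 12.0 + 5.0
        explicit = [cz.DoseEvent(12.0 * k, 280.0) for k in range(11)]
        a = cz.concentration(typical_ind, regimen, t)
        b = cz.concentration(typical_ind, explicit, t)
        assert a == pytest.approx(b, rel=1e-12)

    def test_flip_flop_degeneracy_is_continuous(self):
        # ke == ka: clearance chosen so CL/V = ka
        v = 100.0
        ka = 1.3
        ind_eq = cz.IndividualParams(cl_i=ka * v, v_i=v, ka_i=ka)
        ind_near = cz.IndividualParams(cl_i=ka * v * (1 + 1e-6), v_i=v, ka_i=ka)
        doses = [cz.DoseEvent(0.0, 100.0)]
        for t in (1.0, 6.0, 24.0):
            assert cz.concentration(ind_eq, doses, t) == pytest.approx(
                cz.concentration(ind_near, doses, t), rel=1e-4
            )
        # and matches the analytic limit D*ka*t*exp(-ka t)/V
        t = 2.0
        want = 100.0 * ka * t * math.exp(-ka * t) / v * MGL_TO_NGML
        assert cz.concentration(ind_eq, doses, t) == pytest.approx(want, rel=1e-9)

    def test_mg_per_l_to_ng_per_ml_factor(self):
        assert MGL_TO_NGML == 1000.0


class TestSteadyStateTrough:
    def test_zero_dose_gives_zero(self, typical_ind):
        assert cz.steady_state_trough(typical_ind, 0.0, 12.0) == 0.0

    def test_matches_long_superposition(self, typical_ind):
        ss = cz.steady_state_trough(typical_ind, 280.0, 12.0)
        sup = superposition_trough(typical_ind, 280.0, 12.0, n_doses=50)
        assert ss == pytest.approx(sup, rel=1e-3)
        assert ss == pytest.approx(452.70, rel=1e-3)

    def test_twenty_doses_within_a_tenth_percent(self, typical_ind):
        ss = cz.steady_state_trough(typical_ind, 280.0, 12.0)
        sup = superposition_trough(typical_ind, 280.0, 12.0, n_doses=20)
        assert abs(ss - sup) / ss < 1e-3

    @given(scale=st.floats(0.3, 3.0))
    @settings(max_examples=40, deadline=None)
    def test_trough_strictly_decreases_in_clearance(self, typical_ind, scale):
        base = cz.steady_state_trough(typical_ind, 280.0, 12.0)
        faster = cz.IndividualParams(
            cl_i=typical_ind.cl_i * (1.0 + scale), v_i=typical_ind.v_i, ka_i=typical_ind.ka_i
        )
        assert cz.steady_state_trough(faster, 280.0, 12.0) < base


class TestResidualModel:
    @pytest.mark.parametrize(
        "conc, eps, expected",
        [(400.0, 0.257, 502.8), (400.0, 0.0, 400.0), (0.0, 0.9, 0.0), (250.0, -0.1, 225.0)],
    )
    def test_proportional_error(self, conc, eps, expected):
        assert cz.apply_residual(conc, eps) == pytest.approx(expected, rel=1e-12)

    def test_variance_scales_with_prediction_squared(self):
        rng = np.random.default_rng(0)
        eps = rng.normal(0.0, 0.257, 20000)
        for f in (100.0, 900.0):
            obs = cz.apply_residual(f, eps)
            assert np.std(obs) / f == pytest.approx(0.257, rel=0.05)


class TestValidation:
    def test_population_invariants_rejected(self):
        with pytest.raises(cz.InvalidModelError):
            cz.PopulationParameters(cl_std=-1.0)
        with pytest.raises(cz.InvalidModelError):
            cz.PopulationParameters(theta_zop=-1.0)
        with pytest.raises(cz.InvalidModelError):
            cz.PopulationParameters(sigma_prop=0.0)

    def test_covariates_validated(self):
        with pytest.raises(cz.ValidationError):
            cz.CovariateVector(weight=0.0)
        with pytest.raises(cz.ValidationError):
            cz.CovariateVector(weight=70.0, zop=2)

    def test_empty_dose_history_rejected(self, typical_ind):
        with pytest.raises(cz.InvalidModelError):
            cz.concentration(typical_ind, [], 1.0)
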
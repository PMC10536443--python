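"""Estimators: algebraic inversions, least-squares fits, round-trip identities."""

import numpy as np
import pytest

from photofvcb import (
    GasExchangeRecord,
    KineticParameters,
    PAMRecord,
    TemperatureResponse,
    beta_from_saturating_co2,
    cc_from_ci,
    cc_from_electron_transport,
    damage_rates_from_qn,
    electron_flow_from_pam,
    electron_flow_potential,
    fit_damage_constants,
    fit_gm_light_response,
    fit_light_response,
    fit_temperature_response,
    gm_from_gas_exchange,
    mesophyll_conductance,
    psii_fraction,
    steady_state,
    temperature_activity,
    vcmax_from_point,
)
from photofvcb.errors import DomainError, FitError

LIGHTS = np.array([108.0, 239.0, 425.0, 758.0])


class TestAlgebraicEstimators:
    def test_beta_identity_and_values(self):
        assert beta_from_saturating_co2(200.0 * 0.4 / 4, 200.0, 0.4) == 1.0
        assert beta_from_saturating_co2(8.4, 200.0, 0.4) == pytest.approx(0.42)
        assert beta_from_saturating_co2(0.0, 200.0, 0.4) == 0.0
        with pytest.raises(DomainError):
            beta_from_saturating_co2(1.0, 0.0, 0.4)

    def test_psii_fraction_values(self):
        assert psii_fraction(0.5, 0.5) == 0.5
        assert psii_fraction(0.9, 0.6) == pytest.approx(0.6)
        assert psii_fraction(0.9, 0.0) == 1.0
        with pytest.raises(DomainError):
            psii_fraction(0.0, 0.5)

    def test_electron_flow_from_pam(self):
        rec = PAMRecord(par=239.0, y_i=0.5, y_ii=0.5)
        assert electron_flow_from_pam(rec, beta=0.42, dii_ref=0.5) == pytest.approx(50.19)
        assert electron_flow_from_pam(
            PAMRecord(par=239.0, y_i=0.5, y_ii=0.0), beta=0.42, dii_ref=0.5
        ) == 0.0
        with pytest.warns(UserWarning):
            electron_flow_from_pam(rec, beta=0.42)

    def test_gm_from_gas_exchange(self):
        rec = GasExchangeRecord(par=239, co2=360, a_hv=4.0, ci=300.0, gs=0.17, rd=1.0)
        assert gm_from_gas_exchange(rec, 200.0) == pytest.approx(0.03)
        zero = GasExchangeRecord(par=239, co2=360, a_hv=1.0, ci=300.0, gs=0.17, rd=1.0)
        assert gm_from_gas_exchange(zero, 200.0) == 0.0
        with pytest.raises(DomainError):
            gm_from_gas_exchange(rec, 300.0)
        with pytest.warns(UserWarning):
            assert gm_from_gas_exchange(rec, 350.0) < 0

    def test_cc_from_ci_and_round_trip_at_zero_rd(self):
        rec = GasExchangeRecord(par=239, co2=360, a_hv=3.0, ci=300.0, gs=0.17, rd=0.0)
        assert cc_from_ci(rec, 0.03) == pytest.approx(200.0)
        zero = GasExchangeRecord(par=239, co2=360, a_hv=0.0, ci=300.0, gs=0.17, rd=0.0)
        assert cc_from_ci(zero, 0.03) == 300.0
        gm = gm_from_gas_exchange(rec, 200.0)
        assert cc_from_ci(rec, gm) == pytest.approx(200.0, rel=1e-12)
        with pytest.raises(DomainError):
            cc_from_ci(rec, 0.0)

    def test_vcmax_inversion(self, p):
        assert vcmax_from_point(0.0, 90.0, p) == 0.0
        assert vcmax_from_point(1.4606, 90.0, p) == pytest.approx(18.2, abs=0.01)
        assert vcmax_from_point(2.0, 90.0, p) == pytest.approx(
            2 * vcmax_from_point(1.0, 90.0, p)
        )
        with pytest.raises(DomainError):
            vcmax_from_point(1.0, p.Gamma_star, p)

    def test_etc_limited_cc_inversion_inverts_forward_model(self, p):
        st = steady_state(108.0, p)
        assert st.limitation == "ETC"
        j = st.rates.J_eff
        assert cc_from_electron_transport(st.rates.A_hv, j, p.Gamma_star) == \
            pytest.approx(st.Cc, rel=1e-10)


class TestDamageRatesFromQn:
    def _records(self, qns, par=108.0, dt=70.0):
        return [PAMRecord(par=par, y_i=0.5, y_ii=0.5, qn=q, pulse_index=i,
                          pulse_duration=dt) for i, q in enumerate(qns)]

    def test_single_interval_rates(self):
        df = damage_rates_from_qn(self._records([0.0, 0.021]))
        assert df.vd.iloc[0] == pytest.approx(3e-4)
        assert df.kd.iloc[0] == pytest.approx(3e-4)

    def test_constant_quenching_gives_zero_rates(self):
        df = damage_rates_from_qn(self._records([0.1, 0.1, 0.1]))
        assert (df.vd == 0).all() and (df.kd == 0).all()

    def test_single_pulse_rejected(self):
        with pytest.raises(DomainError):
            damage_rates_from_qn(self._records([0.1]))

    def test_decreasing_quenching_warns(self):
        with pytest.warns(UserWarning):
            damage_rates_from_qn(self._records([0.2, 0.1]))


class TestLightResponseFit:
    def test_noiseless_round_trip_is_exact(self, p):
        js = electron_flow_potential(LIGHTS, p)
        fr = fit_light_response(LIGHTS, js, p.beta_prime)
        assert fr["Jmax"] == pytest.approx(p.Jmax, rel=1e-6)
        assert fr["theta"] == pytest.approx(p.theta, rel=1e-6)
        assert fr.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_of_jmax(self, p):
        rng = np.random.default_rng(1)
        pars = np.repeat(LIGHTS, 7)
        js = electron_flow_potential(pars, p) * (1 + 0.02 * rng.standard_normal(pars.size))
        fr = fit_light_response(pars, js, p.beta_prime)
        assert abs(fr["Jmax"] - p.Jmax) / p.Jmax < 0.05

    def test_underdetermined_rejected(self, p):
        with pytest.raises(FitError):
            fit_light_response([239.0, 239.0], [30.0, 31.0], p.beta_prime)

    def test_random_truth_round_trips(self):
        rng = np.random.default_rng(3)
        pars = np.array([60.0, 150.0, 300.0, 600.0, 1200.0])
        for _ in range(5):
            p = KineticParameters(Jmax=rng.uniform(20, 120),
                                  theta=rng.uniform(0.1, 0.9))
            fr = fit_light_response(pars, electron_flow_potential(pars, p), p.beta_prime)
            assert fr["Jmax"] == pytest.approx(p.Jmax, rel=1e-5)
            assert fr["theta"] == pytest.approx(p.theta, rel=1e-4)


class TestGmLightResponseFit:
    PARS = np.array([0.0, 100.0, 250.0, 500.0, 800.0, 1200.0, 2000.0, 4000.0])

    def test_noiseless_round_trip_is_exact(self, p):
        gms = mesophyll_conductance(self.PARS, p)
        fr = fit_gm_light_response(self.PARS, gms)
        for name, truth in (("gd", p.gd), ("dg_max", p.dg_max),
                            ("hill_n", p.hill_n), ("hill_K", p.hill_K)):
            assert fr[name] == pytest.approx(truth, rel=1e-5)
        assert fr.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_noisy_recovery_with_fixed_dark_conductance(self, p):
        rng = np.random.default_rng(1)
        pars = np.repeat(self.PARS[1:], 3)
        gms = mesophyll_conductance(pars, p) * (1 + 0.02 * rng.standard_normal(pars.size))
        fr = fit_gm_light_response(pars, gms, fixed={"gd": p.gd})
        assert abs(fr["dg_max"] - p.dg_max) / p.dg_max < 0.10

    def test_flat_input_reports_degeneracy(self):
        fr = fit_gm_light_response([100.0, 200.0, 400.0, 800.0], [0.03] * 4)
        assert fr["dg_max"] == 0.0
        assert fr.warnings

    def test_underdetermined_rejected(self):
        with pytest.raises(FitError):
            fit_gm_light_response([100.0, 200.0], [0.02, 0.03])


class TestDamageConstantsFit:
    def _kds(self, p, pars=LIGHTS):
        out = []
        for par in pars:
            st = steady_state(par, p)
            out.append(p.kd0 * (p.alpha * st.rates.Wj + st.rates.Wj - st.rates.W))
        return np.array(out)

    def test_noiseless_round_trip_is_exact(self, p):
        fr = fit_damage_constants(self._kds(p), LIGHTS, p)
        assert fr["kd0"] == pytest.approx(p.kd0, rel=1e-6)
        assert fr["alpha"] == pytest.approx(p.alpha, rel=1e-6)

    def test_noisy_recovery(self, p):
        rng = np.random.default_rng(1)
        pars = np.repeat(LIGHTS, 7)
        kds = self._kds(p, pars) * (1 + 0.05 * rng.standard_normal(pars.size))
        fr = fit_damage_constants(kds, pars, p)
        assert abs(fr["kd0"] - p.kd0) / p.kd0 < 0.10
        assert abs(fr["alpha"] - p.alpha) / p.alpha < 0.20

    def test_balanced_flows_flag_alpha_degeneracy(self, p):
        pars = np.array([50.0, 108.0])   # both strongly ETC-limited: Wj = W
        fr = fit_damage_constants(self._kds(p, pars), pars, p)
        assert fr.warnings

    def test_single_light_level_rejected(self, p):
        with pytest.raises(FitError):
            fit_damage_constants([1e-5], [239.0], p)


class TestTemperatureResponseFit:
    def test_noiseless_round_trip_asymmetric(self, tr_j):
        temps = np.array([5.0, 12.0, 20.0, 27.0, 33.0, 38.0, 44.0])
        fr = fit_temperature_response(temps, temperature_activity(temps, tr_j))
        assert fr["t_opt"] == pytest.approx(tr_j.t_opt, abs=1e-4)
        assert fr["sigma_lo"] == pytest.approx(tr_j.sigma_lo, abs=1e-3)
        assert fr["sigma_hi"] == pytest.approx(tr_j.sigma_hi, abs=1e-3)

    def test_symmetric_constrained_noisy_recovery(self, tr_c):
        rng = np.random.default_rng(1)
        temps = np.repeat([10.0, 15.0, 23.0, 30.0, 37.0, 41.0, 42.0], 5)
        acts = temperature_activity(temps, tr_c) * (1 + 0.03 * rng.standard_normal(temps.size))
        fr = fit_temperature_response(temps, acts, symmetric=True)
        assert abs(fr["t_opt"] - tr_c.t_opt) < 2.0
        assert fr["sigma_lo"] == fr["sigma_hi"]

    def test_two_points_rejected(self):
        with pytest.raises(FitError):
            fit_temperature_response([20.0, 30.0], [0.9, 0.95])

    def test_optimum_outside_range_warns(self):
        tr = TemperatureResponse(50.0, 20.0, 20.0)
        temps = np.array([5.0, 10.0, 15.0, 20.0, 25.0])
        fr = fit_temperature_response(temps, temperature_activity(temps, tr))
        assert fr.warnings
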
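"""Steady-state CO2 balance, Euler damage stepping, protocols and sweeps."""

import numpy as np
import pytest
from scipy.optimize import brentq

from photofvcb import (
    KineticParameters,
    Protocol,
    Segment,
    electron_flow_potential,
    mesophyll_conductance,
    run_protocol,
    select_final_cc,
    standard_protocol,
    steady_cc_etc,
    steady_cc_rubisco,
    steady_ci,
    steady_state,
    step_euler,
    sweep_act_heatmap,
    sweep_temperature,
)
from photofvcb.dynamics import cc_residual_etc, cc_residual_rubisco
from photofvcb.errors import DomainError, ParameterError


class TestSteadyCi:
    def test_no_gradient(self):
        assert steady_ci(360.0, 360.0, 0.17, 0.03) == 360.0

    def test_sealed_mesophyll_equilibrates_with_air(self):
        assert steady_ci(100.0, 360.0, 0.17, 1e-12) == pytest.approx(360.0, abs=1e-6)

    def test_weighted_mean_value(self):
        assert steady_ci(223.0, 360.0, 0.17, 0.03) == pytest.approx(339.45, abs=1e-2)

    def test_lies_between_cc_and_co(self):
        ci = steady_ci(150.0, 360.0, 0.2, 0.05)
        assert 150.0 < ci < 360.0

    def test_zero_conductances_rejected(self):
        with pytest.raises(DomainError):
            steady_ci(100.0, 360.0, 0.0, 0.0)


class TestSteadyCc:
    def test_zero_consumption_closed_form_both_branches(self, p):
        gm = 0.03
        expected = p.Co + p.Rd * (p.gs + gm) / (p.gs * gm)
        assert steady_cc_rubisco(p, gm, act_c=0.0) == pytest.approx(expected, rel=1e-12)
        assert steady_cc_etc(p, gm, 0.0) == pytest.approx(expected, rel=1e-12)

    def test_doubling_conductances_halves_equilibrium_offset(self, p):
        gm = 0.03
        off1 = steady_cc_etc(p, gm, 0.0) - p.Co
        off2 = steady_cc_etc(p.replace(gs=2 * p.gs), 2 * gm, 0.0) - p.Co
        assert off2 == pytest.approx(off1 / 2, rel=1e-12)

    def test_air_equilibrium_without_sinks(self):
        p = KineticParameters(Rd=1e-12, Vcmax=1e-9)
        assert steady_cc_rubisco(p, 0.03) == pytest.approx(p.Co, rel=1e-6)

    def test_residuals_vanish_at_returned_roots(self, p):
        gm = mesophyll_conductance(239.0, p)
        j = electron_flow_potential(239.0, p)
        ccj = steady_cc_etc(p, gm, j)
        ccc = steady_cc_rubisco(p, gm)
        assert abs(cc_residual_etc(ccj, p, gm, j)) < 1e-8
        assert abs(cc_residual_rubisco(ccc, p, gm)) < 1e-8

    def test_roots_lie_in_physical_bracket(self, p):
        gm = mesophyll_conductance(239.0, p)
        j = electron_flow_potential(239.0, p)
        g_tot = p.gs * gm / (p.gs + gm)
        hi = p.Co + p.Rd / g_tot
        for cc in (steady_cc_etc(p, gm, j), steady_cc_rubisco(p, gm)):
            assert p.Gamma_star < cc < hi

    @pytest.mark.parametrize("par,co2", [(108.0, 360.0), (425.0, 360.0), (239.0, 100.0)])
    def test_agrees_with_bracketed_root_finder(self, p, par, co2):
        gm = mesophyll_conductance(par, p)
        j = electron_flow_potential(par, p)
        g_tot = p.gs * gm / (p.gs + gm)
        hi = co2 + p.Rd / g_tot + 1.0
        ref_j = brentq(lambda cc: cc_residual_etc(cc, p, gm, j, co2=co2),
                       p.Gamma_star, hi, xtol=1e-10)
        ref_c = brentq(lambda cc: cc_residual_rubisco(cc, p, gm, co2=co2),
                       p.Gamma_star, hi, xtol=1e-10)
        assert steady_cc_etc(p, gm, j, co2=co2) == pytest.approx(ref_j, abs=1e-7)
        assert steady_cc_rubisco(p, gm, co2=co2) == pytest.approx(ref_c, abs=1e-7)


class TestSelectFinalCc:
    @pytest.mark.parametrize("ccc,ccj,expected", [
        (125.0, 280.0, 280.0),   # low light: ETC limitation
        (230.0, 168.0, 230.0),   # high light: Rubisco limitation
        (200.0, 200.0, 200.0),   # tie
    ])
    def test_max_rule(self, ccc, ccj, expected):
        assert select_final_cc(ccc, ccj) == expected

    def test_selected_branch_has_smaller_rate(self, p):
        st = steady_state(239.0, p)
        if st.limitation == "ETC":
            assert st.rates.Wj <= st.rates.Wc
        else:
            assert st.rates.Wc <= st.rates.Wj

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            select_final_cc(-1.0, 100.0)


class TestStepEuler:
    def test_darkness_causes_no_damage(self, p, tr_c, tr_j):
        seg = Segment(60.0, 0.0)
        st0 = steady_state(0.0, p, temperature=23.0)
        st1 = step_euler(st0, seg, p, tr_c, tr_j, dt=1.0)
        assert st1.Aj == st0.Aj == 1.0
        assert st1.time == st0.time + 1.0

    def test_single_update_matches_damage_law(self, p, tr_c, tr_j):
        from photofvcb import damage_rate

        seg = Segment(60.0, 758.0, temperature=None, act_j=1.0, act_c=1.0)
        st0 = steady_state(758.0, p)
        expected = 1.0 + 1.0 * damage_rate(st0.rates.Wj, st0.rates.W, 1.0, p)
        st1 = step_euler(st0, seg, p, tr_c, tr_j, dt=1.0)
        assert st1.Aj == pytest.approx(expected, rel=1e-9)

    def test_step_size_convergence_of_final_damage(self, p, tr_c, tr_j):
        coarse = run_protocol(standard_protocol(758.0, dt=0.2), p, tr_c, tr_j)
        fine = run_protocol(standard_protocol(758.0, dt=0.1), p, tr_c, tr_j)
        assert abs(coarse.final_Aj - fine.final_Aj) < 1e-3


class TestRunProtocol:
    def test_negligible_damage_constant_preserves_aj(self, tr_c, tr_j, short_protocol):
        p = KineticParameters(kd0=1e-30)
        tc = run_protocol(short_protocol(758.0), p, tr_c, tr_j)
        assert tc.final_Aj == 1.0

    def test_trajectory_invariants(self, p, tr_c, tr_j, short_protocol):
        proto = short_protocol(425.0, stress_temperature=37.0)
        tc = run_protocol(proto, p, tr_c, tr_j)
        aj = np.array([s.Aj for s in tc.states])
        t = tc.times
        assert np.all(np.diff(t) > 0)
        assert np.all(np.diff(aj) <= 0)
        assert 0 < tc.final_Aj < 1
        assert t[-1] == pytest.approx(proto.total_duration)
        for s in tc.states:
            assert (s.limitation == "ETC") == (s.rates.Wj <= s.rates.Wc)

    def test_more_light_means_more_damage(self, p, tr_c, tr_j, short_protocol):
        low = run_protocol(short_protocol(108.0), p, tr_c, tr_j).final_Aj
        high = run_protocol(short_protocol(758.0), p, tr_c, tr_j).final_Aj
        assert high < low

    def test_final_aj_monotone_in_kd0(self, tr_c, tr_j, short_protocol):
        rng = np.random.default_rng(11)
        proto = short_protocol(425.0)
        finals = []
        for kd0 in sorted(rng.uniform(1e-5, 5e-4, size=4)):
            finals.append(run_protocol(proto, KineticParameters(kd0=kd0),
                                       tr_c, tr_j).final_Aj)
        assert np.all(np.diff(finals) < 0)

    def test_final_aj_monotone_in_par(self, p, tr_c, tr_j, short_protocol):
        finals = [run_protocol(short_protocol(par), p, tr_c, tr_j).final_Aj
                  for par in (50.0, 200.0, 500.0, 900.0)]
        assert np.all(np.diff(finals) < 0)

    def test_full_inactivation_freezes_damage_during_stress(self, p, tr_c, tr_j):
        proto = standard_protocol(425.0, stress_act_j=0.0, stress_act_c=0.0,
                                  phase_duration=120.0, record_every=120.0)
        tc = run_protocol(proto, p, tr_c, tr_j)
        times = tc.times
        i_start = int(np.argmin(np.abs(times - 120.0)))
        i_end = int(np.argmin(np.abs(times - 240.0)))
        assert tc.states[i_end].Aj == tc.states[i_start].Aj

    def test_timecourse_dataframe_schema(self, p, tr_c, tr_j, short_protocol):
        df = run_protocol(short_protocol(239.0), p, tr_c, tr_j).to_dataframe()
        assert list(df.columns) == ["time_s", "Aj", "Cc_ppm", "Ci_ppm", "W", "Wj",
                                    "Wc", "Ahv", "gm", "limitation"]

    def test_protocol_validation(self):
        with pytest.raises(ParameterError):
            Protocol(segments=(), dt=0.1)
        with pytest.raises(ParameterError):
            Protocol(segments=(Segment(1.0, 100.0),), dt=2.0)
        with pytest.raises(ParameterError):
            Segment(10.0, 100.0, gs_scale=1.5)


class TestSweeps:
    def test_heatmap_consistent_with_scalar_run(self, p, tr_c, tr_j):
        grid = np.array([0.0, 1.0])
        m = sweep_act_heatmap(grid, grid, 425.0, p, tr_c, tr_j,
                              phase_duration=120.0)
        scalar = run_protocol(
            standard_protocol(425.0, stress_act_j=1.0, stress_act_c=1.0,
                              phase_duration=120.0),
            p, tr_c, tr_j,
        ).final_Aj
        assert m[1, 1] == pytest.approx(scalar, rel=1e-9)
        assert m.shape == (2, 2)
        assert np.all((m > 0) & (m <= 1))

    def test_heatmap_min_at_active_etc_inactive_rubisco(self, p, tr_c, tr_j):
        grid = np.linspace(0, 1, 5)
        m = sweep_act_heatmap(grid, grid, 425.0, p, tr_c, tr_j, phase_duration=120.0)
        assert m.argmin() == np.ravel_multi_index((4, 0), m.shape)

    def test_temperature_sweep_matches_protocol_at_base(self, p, tr_c, tr_j):
        df = sweep_temperature([23.0], [239.0], p, tr_c, tr_j, phase_duration=120.0)
        scalar = run_protocol(standard_protocol(239.0, phase_duration=120.0),
                              p, tr_c, tr_j).final_Aj
        assert df.final_aj.iloc[0] == pytest.approx(scalar, rel=1e-9)

    def test_higher_light_curves_lie_below(self, p, tr_c, tr_j):
        df = sweep_temperature([15.0, 30.0, 40.0], [108.0, 758.0], p, tr_c, tr_j,
                               phase_duration=120.0)
        piv = df.pivot(index="temperature", columns="par", values="final_aj")
        assert (piv[758.0] < piv[108.0]).all()
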
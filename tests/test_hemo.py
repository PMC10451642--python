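"""Circuit-model unit and property tests."""

import math

import numpy as np
import pytest

from pulmovib import hemo


class TestPoiseuille:
    def test_fourth_power_law(self):
        r1 = hemo.resistance_from_radius(0.004, 3.5e-3, 0.05)
        r2 = hemo.resistance_from_radius(0.002, 3.5e-3, 0.05)
        assert r2 == pytest.approx(16.0 * r1)

    def test_unit_normalised_identity(self):
        # 8*1*(pi/8) / (pi*1) = 1
        assert hemo.resistance_from_radius(1.0, 1.0, math.pi / 8) == pytest.approx(1.0)

    def test_hand_value(self):
        # 8 * 3.5e-3 * 0.05 / (pi * 0.005^4) = 1.4e-3 / 1.963495e-9
        assert hemo.resistance_from_radius(0.005, 3.5e-3, 0.05) == pytest.approx(
            713_014.27, rel=1e-6
        )

    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, 0, 1), (1, 1, -2)])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            hemo.resistance_from_radius(*bad)


class TestStenosisSchedule:
    def test_radius_at_zero_and_frozen(self):
        sched = hemo.StenosisSchedule(r0=0.7, gr=0.0)
        assert hemo.radius_at_time(0.0, sched) == 0.7
        assert hemo.radius_at_time(57.0, sched) == 0.7

    def test_negative_time_rejected(self):
        sched = hemo.StenosisSchedule(r0=0.7, gr=0.1)
        with pytest.raises(ValueError):
            hemo.radius_at_time(-0.1, sched)

    def test_resistance_grows_linearly(self):
        # composing the quartic radius decay with Poiseuille's law gives
        # R(t)/R(0) = 1 + gr*t exactly
        sched = hemo.StenosisSchedule(r0=0.31, gr=0.37, eta=2.1, pipe_len=0.4)
        R0 = sched.resistance_at(0.0)
        for t in (0.5, 3.0, 17.0, 120.0):
            assert sched.resistance_at(t) / R0 == pytest.approx(
                1.0 + sched.gr * t, rel=1e-12
            )

    def test_for_resistance_inverts(self):
        sched = hemo.StenosisSchedule.for_resistance(0.16, gr=0.05)
        assert sched.resistance_at(0.0) == pytest.approx(0.16, rel=1e-12)


class TestComplianceFormula:
    def test_full_and_empty_can_have_zero_compliance(self):
        assert hemo.compliance_value(0.5, 0.5, 0.01, 101325, 9810) == 0.0
        assert hemo.compliance_value(0.0, 0.5, 0.01, 101325, 9810) == 0.0

    def test_hand_value(self):
        # num = 0.25*0.25*0.01 = 6.25e-4
        # den = 101325*0.5 + (9810*0.25-101325)*0.25 = 25945.3125
        got = hemo.compliance_value(0.25, 0.5, 0.01, 101325, 9810)
        assert got == pytest.approx(6.25e-4 / 25945.3125, rel=1e-12)

    def test_overfull_rejected(self):
        with pytest.raises(ValueError):
            hemo.compliance_value(0.6, 0.5, 0.01, 101325, 9810)


class TestPHClassification:
    @pytest.mark.parametrize("mpap,expect", [(26.0, True), (25.0, False), (0.0, False)])
    def test_strict_threshold(self, mpap, expect):
        assert hemo.classify_ph(mpap) is expect


class TestDerivatives:
    def test_equilibrium_is_stationary(self):
        m = hemo.normal_model()
        # equal pressures everywhere, no inertance flow
        P = 7.0
        E0 = m.rv.elastance(0.0)
        y = np.array([
            m.rv.V0 + P / E0, P * m.pap.C, P * m.pad.C, P * m.pv.C,
            P * m.C_res, 0.0,
        ])
        rate = hemo.derivatives(y, 0.0, m)
        # valve leak flows are O(P/R_reverse); everything else must vanish
        assert np.all(np.abs(rate) < 1e-2)

    def test_rc_discharge_matches_analytic(self):
        # isolate pad discharging through R_pad into a clamped-pressure pv:
        # dV/dt = -(V/C - 0)/R  ->  exponential decay with tau = R*C
        m = hemo.normal_model()
        R, C = m.pad.R, m.pad.C
        V0 = 40.0
        dt = 1e-4
        V = V0
        for _ in range(int(0.5 / dt)):  # RK4 on the scalar subsystem
            f = lambda v: -(v / C) / R
            k1 = f(V)
            k2 = f(V + 0.5 * dt * k1)
            k3 = f(V + 0.5 * dt * k2)
            k4 = f(V + dt * k3)
            V += dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        assert V == pytest.approx(V0 * math.exp(-0.5 / (R * C)), rel=1e-3)

    def test_reverse_gradient_blocks_valve(self):
        m = hemo.normal_model()
        v = m.valve_p
        assert v.flow(5.0) == pytest.approx(5.0 / v.R_forward)
        # reverse conduction is only the tiny leak
        assert abs(v.flow(-5.0)) <= 5.0 / v.R_reverse + 1e-12

    def test_shape_mismatch_rejected(self):
        m = hemo.normal_model()
        with pytest.raises(ValueError):
            hemo.derivatives(np.zeros(4), 0.0, m)


@pytest.fixture(scope="module")
def normal_result():
    return hemo.simulate(hemo.normal_model(), n_cycles=40)


class TestSimulate:
    def test_normal_state_rv_systolic(self, normal_result):
        """Steady state reproduces the ~23 mmHg RV systolic pressure."""
        s = hemo.summarize_pressures(normal_result)
        assert s["RV_systolic"] == pytest.approx(23.0, rel=0.15)
        assert normal_result.steady

    def test_volume_conserved(self, normal_result):
        tv = normal_result.total_volume()
        assert np.ptp(tv) < 0.1  # mL over the whole run

    def test_zero_drive_decays(self):
        m = hemo.normal_model()
        m.rv.Emax = m.rv.Emin  # no contraction
        res = hemo.simulate(m, n_cycles=20, stop_at_steady=False)
        q_late = res.flows["Q_pp"][-1000:]
        q_early = res.flows["Q_pp"][:1000]
        assert np.abs(q_late).max() < 0.05 * max(np.abs(q_early).max(), 1.0)
        p_late = res.pressures["P_pap"][-1000:]
        assert np.ptp(p_late) < 0.5

    def test_dpas_rv_peak_nondecreasing(self):
        m = hemo.normal_model()
        sched = hemo.StenosisSchedule.for_resistance(m.pad.R, gr=0.1)
        res = hemo.simulate(m, n_cycles=25, stenosis=sched, stop_at_steady=False)
        peaks = hemo.summarize_pressures(res, steady_only=False)
        pc = peaks["per_cycle"]["RV_systolic"]
        assert all(b >= a - 1e-9 for a, b in zip(pc[5:], pc[6:]))

    def test_pasp_monotone_in_distal_resistance(self):
        pasps = []
        for Rd in (0.10, 0.16, 0.30, 0.50):
            m = hemo.normal_model()
            m.pad.R = Rd
            res = hemo.simulate(m, n_cycles=40)
            pasps.append(hemo.summarize_pressures(res)["PASP"])
        assert all(b > a for a, b in zip(pasps, pasps[1:]))

    def test_valve_rectification(self, normal_result):
        q = normal_result.flows["Q_pval"]
        fwd = np.sum(q[q > 0])
        rev = -np.sum(q[q < 0])
        assert rev < 0.01 * fwd

    def test_instability_reported_with_node(self):
        m = hemo.normal_model()
        m.init_state[3] = -1e9  # pathological initial volume at pv
        with pytest.raises(hemo.InstabilityError, match="P_pv"):
            hemo.simulate(m, n_cycles=1)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            hemo.simulate(hemo.normal_model(), dt=-1.0)


class TestPVLoop:
    def test_loops_close(self, normal_result):
        loops = hemo.pv_loop(normal_result)
        for V, P in loops:
            extent = np.ptp(V) + np.ptp(P)
            gap = abs(V[-1] - V[0]) + abs(P[-1] - P[0])
            assert gap < 0.01 * extent

    def test_isovolumic_segments_visible(self, normal_result):
        # some portion of the loop moves > 2 mmHg while volume changes < 1 mL
        V, P = hemo.pv_loop(normal_result)[-1]
        dV = np.abs(np.diff(V))
        dP = np.abs(np.diff(P))
        iso = (dP > 10 * dV + 1e-9) & (dP > 0.01)
        assert np.sum(dP[iso]) > 2.0

    def test_area_matches_trapezoid_oracle(self, normal_result):
        V, P = hemo.pv_loop(normal_result)[-1]
        # independent shoelace evaluation of the signed loop area
        Vc = np.append(V, V[0])
        Pc = np.append(P, P[0])
        shoelace = 0.5 * np.sum(Pc[:-1] * np.diff(Vc) - Vc[:-1] * np.diff(Pc))
        # same orientation and magnitude (sign convention may differ)
        assert abs(hemo.loop_area(V, P)) == pytest.approx(abs(shoelace), rel=1e-6)
        assert abs(shoelace) > 100.0  # meaningful stroke work, mmHg*mL


class TestSummaries:
    def test_constant_pressure(self):
        res = hemo.SimResult(
            t=np.arange(0, 2, 1e-3),
            pressures={"P_pap": np.full(2000, 9.0), "P_rv": np.full(2000, 9.0)},
            flows={}, volumes={}, dt=1e-3, period=1.0,
            cycle_starts=np.array([0, 1000, 2000]), steady=False,
        )
        s = hemo.summarize_pressures(res, steady_only=False)
        assert s["PASP"] == pytest.approx(9.0)
        assert s["mPAP"] == pytest.approx(9.0)

    def test_sinusoid(self):
        t = np.arange(0, 2, 1e-3)
        p = 10.0 + 3.0 * np.sin(2 * np.pi * t)
        res = hemo.SimResult(
            t=t, pressures={"P_pap": p, "P_rv": p}, flows={}, volumes={},
            dt=1e-3, period=1.0, cycle_starts=np.array([0, 1000, 2000]),
            steady=False,
        )
        s = hemo.summarize_pressures(res, steady_only=False)
        assert s["PASP"] == pytest.approx(13.0, abs=0.01)
        assert s["mPAP"] == pytest.approx(10.0, abs=0.01)

    def test_empty_rejected(self):
        res = hemo.SimResult(
            t=np.array([]), pressures={"P_pap": np.array([]), "P_rv": np.array([])},
            flows={}, volumes={}, dt=1e-3, period=1.0,
            cycle_starts=np.array([0]), steady=False,
        )
        with pytest.raises(ValueError):
            hemo.summarize_pressures(res, steady_only=False)
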
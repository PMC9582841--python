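"""Biochemical model: rates, signals, fixed point, integrator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import myogrowth as mg
from myogrowth.pathway import a2_signal_step

# closed-form fixed-point cascade at resting inputs, frozen from the
# triangular solution x1*=a10/b1, x2*=(a20+c21 x1*)/b2, x3*=(a3-c32 x2*)/b3,
# x4*=(a4+c42 x2*-c43 x3*)/b4 evaluated independently
FIXED_POINT = (0.045, 1.000614, 0.4339386, 0.4689852846)


class TestSteadyState:
    def test_cascade_matches_frozen_values(self, pathway_params):
        xs = mg.steady_state(pathway_params)
        assert xs == pytest.approx(FIXED_POINT, rel=1e-9)

    def test_rates_vanish_at_fixed_point(self, pathway_params):
        p = pathway_params
        rates = mg.pathway_rates(FIXED_POINT, p, a1=p.a10, a2=p.a20)
        assert np.all(np.abs(rates) < 1e-12)

    def test_matches_long_time_integration(self, pathway_params, stimulus):
        p = pathway_params
        state = mg.initial_state(p)
        end = mg.integrate(state, 6000.0, 0.05, lambda t: p.a10,
                           lambda t: p.a20, p)
        assert (end.x1, end.x2, end.x3, end.x4) == pytest.approx(
            mg.steady_state(p), abs=1e-7)

    def test_isolated_logistic_limit(self):
        # with negligible couplings each species settles at a_i / b_i
        p = mg.PathwayParameters(c21=1e-15, c32=1e-15, c42=1e-15, c43=1e-15)
        xs = mg.steady_state(p)
        expect = (p.a10 / p.b1, p.a20 / p.b2, p.a3 / p.b3, p.a4 / p.b4)
        assert xs == pytest.approx(expect, rel=1e-9)

    def test_non_positive_fixed_point_flagged(self):
        # a huge inhibition of FOXO by AKT drives x3* negative
        p = mg.PathwayParameters(c32=1.0)
        with pytest.raises(ValueError, match="not positive"):
            mg.steady_state(p)


class TestPathwayRates:
    def test_zero_population_has_zero_rate(self, pathway_params):
        rates = mg.pathway_rates((0.0, 0.5, 0.4, 0.4), pathway_params,
                                 a1=5.0, a2=0.5)
        assert rates[0] == 0.0

    def test_logistic_fixed_point_of_x1(self, pathway_params):
        p = pathway_params
        rates = mg.pathway_rates((p.a10 / p.b1, 1.0, 0.4, 0.4), p,
                                 a1=p.a10, a2=p.a20)
        assert rates[0] == pytest.approx(0.0, abs=1e-15)

    def test_negative_population_rejected(self, pathway_params):
        with pytest.raises(ValueError, match="non-negative"):
            mg.pathway_rates((-0.1, 1.0, 0.4, 0.4), pathway_params, 0.1, 0.5)


class TestMyofibrilRate:
    def test_thresholds_give_zero(self, pathway_params):
        p = pathway_params
        assert mg.myofibril_rate(p.x3_thr, p.x4_thr, 1.0, p) == 0.0

    @pytest.mark.parametrize("z", [0.5, 1.3, 0.2, 1.5])
    def test_zero_at_or_beyond_size_bounds(self, pathway_params, z):
        assert mg.myofibril_rate(0.9, 0.9, z, pathway_params) == 0.0

    def test_pure_hypertrophy_branch(self, pathway_params):
        p = pathway_params
        rate = mg.myofibril_rate(p.x3_thr - 0.05, p.x4_thr + 0.1, 1.0, p)
        assert rate == pytest.approx(p.k1 * 0.1)
        assert rate == pytest.approx(2.5e-3)

    def test_pure_atrophy_branch(self, pathway_params):
        p = pathway_params
        rate = mg.myofibril_rate(p.x3_thr + 0.1, p.x4_thr - 0.05, 1.0, p)
        assert rate == pytest.approx(-p.k2 * 0.1)

    def test_balance_branch(self, pathway_params):
        p = pathway_params
        rate = mg.myofibril_rate(p.x3_thr + 0.2, p.x4_thr + 0.1, 1.0, p)
        assert rate == pytest.approx(p.k1 * 0.1 - p.k2 * 0.2)

    def test_k1_override(self, pathway_params):
        p = pathway_params
        rate = mg.myofibril_rate(0.1, p.x4_thr + 0.1, 1.0, p, k1=0.05)
        assert rate == pytest.approx(0.005)

    @settings(derandomize=True, max_examples=200)
    @given(
        x3=st.floats(0.3, 0.6), x4=st.floats(0.3, 0.6),
        dx3=st.floats(-1e-3, 1e-3), dx4=st.floats(-1e-3, 1e-3),
    )
    def test_lipschitz_continuity_across_thresholds(self, x3, x4, dx3, dx4):
        """Each branch vanishes on its threshold line, so the piecewise law
        is globally Lipschitz with constants k1, k2."""
        p = mg.PathwayParameters()
        f0 = mg.myofibril_rate(x3, x4, 1.0, p)
        f1 = mg.myofibril_rate(x3 + dx3, x4 + dx4, 1.0, p)
        bound = p.k2 * abs(dx3) + p.k1 * abs(dx4) + 1e-15
        assert abs(f1 - f0) <= bound


class TestTrainingSignals:
    SESSIONS = [(0.0, 1.0), (48.0, 49.0)]

    def test_a1_inside_session_scales_with_load(self, stimulus):
        from dataclasses import replace
        # intensity * f_max = 10 kgf -> a1 = (2/50) * 10 = 0.4 / h
        stim = replace(stimulus, intensity=1.0, f_max=10.0)
        assert mg.a1_signal(0.5, self.SESSIONS, stim) == pytest.approx(0.4)

    def test_a1_outside_session_is_resting(self, stimulus):
        from dataclasses import replace
        stim = replace(stimulus, f_max=10.0)
        assert mg.a1_signal(24.0, self.SESSIONS, stim) == pytest.approx(9.0e-2)

    def test_a1_proportional_to_intensity(self, stimulus):
        from dataclasses import replace
        stim = replace(stimulus, intensity=0.0, f_max=10.0)
        assert mg.a1_signal(0.5, self.SESSIONS, stim) == 0.0

    def test_a2_resting_without_sessions(self, stimulus):
        assert mg.a2_signal(math.inf, stimulus) == pytest.approx(0.4875)

    def test_a2_holds_after_pulse_window(self, stimulus):
        assert mg.a2_signal(17.0, stimulus) == pytest.approx(0.4875)
        assert mg.a2_signal(40.0, stimulus) == pytest.approx(0.4875)

    def test_a2_starts_at_resting_value(self, stimulus):
        assert mg.a2_signal(0.0, stimulus) == pytest.approx(stimulus.a20,
                                                            abs=1e-15)

    def test_a2_peak_at_t1_minus_tau(self, stimulus):
        # the pulse derivative vanishes at u = -1, i.e. 17 - 6 = 11 h
        ts = np.linspace(0.0, 17.0, 17001)
        vals = np.asarray(mg.a2_signal(ts, stimulus))
        assert ts[np.argmax(vals)] == pytest.approx(11.0, abs=2e-3)
        peak = 0.4875 + 0.5 / math.e - 0.5 * (17 / 6) * math.exp(-17 / 6)
        assert vals.max() == pytest.approx(peak, rel=1e-12)

    def test_a2_closed_form_matches_ode_integration(self, stimulus):
        """Independent oracle: integrate the printed pulse ODE numerically."""
        tau, t1 = stimulus.tau_h, stimulus.t1_pulse

        def rhs(t, y):
            u = (t - t1) / tau
            return [0.5 * (-1.0 / tau - u / tau) * math.exp(u)]

        sol = solve_ivp(rhs, (0.0, 16.99), [stimulus.a20], rtol=1e-11,
                        atol=1e-13, dense_output=True)
        for ts in (1.0, 5.0, 11.0, 16.5):
            assert mg.a2_signal(ts, stimulus) == pytest.approx(
                float(sol.sol(ts)[0]), rel=1e-8)

    def test_a2_step_equals_closed_form(self, stimulus):
        assert a2_signal_step(0.5, 3.0, 0.05, stimulus) == pytest.approx(
            mg.a2_signal(3.05, stimulus), rel=1e-14)


class TestRK4:
    def test_fixed_point_is_stationary(self, pathway_params):
        p = pathway_params
        x1, x2, x3, x4 = mg.steady_state(p)
        state = mg.PathwayState(t=0.0, x1=x1, x2=x2, x3=x3, x4=x4, z=1.0)
        out = mg.rk4_step(state, 0.05, lambda t: p.a10, lambda t: p.a20, p)
        for name in ("x1", "x2", "x3", "x4", "z"):
            assert getattr(out, name) == pytest.approx(
                getattr(state, name), abs=1e-12)

    def test_matches_logistic_closed_form(self):
        """With negligible couplings and constant drivers each species is an
        isolated logistic with a known solution."""
        p = mg.PathwayParameters(c21=1e-300, c32=1e-300, c42=1e-300,
                                 c43=1e-300)
        x0, r, K = 0.3, p.a20, p.a20 / p.b2
        state = mg.PathwayState(t=0.0, x1=0.045, x2=x0, x3=0.3, x4=0.3, z=1.0)
        state = mg.integrate(state, 10.0, 0.01, lambda t: p.a10,
                             lambda t: p.a20, p)
        expect = K * x0 * math.exp(r * 10.0) / (K + x0 * (math.exp(r * 10.0) - 1))
        assert state.x2 == pytest.approx(expect, rel=1e-9)

    def test_convergence_order_at_least_3p8(self):
        """dt-halving study on the full five-state system with smooth
        drivers, away from the threshold kinks of the myofibril law."""
        p = mg.PathwayParameters()
        a1 = lambda t: p.a10 * (1.0 + 0.5 * math.sin(t / 5.0))
        a2 = lambda t: p.a20 * (1.0 + 0.3 * math.cos(t / 7.0))

        def final(dt):
            s = mg.PathwayState(t=0.0, x1=0.2, x2=0.9, x3=0.30, x4=0.60,
                                z=1.0)
            s = mg.integrate(s, 20.0, dt, a1, a2, p)
            return np.array([s.x1, s.x2, s.x3, s.x4, s.z])

        y1, y2, y3 = final(0.2), final(0.1), final(0.05)
        e1 = np.linalg.norm(y1 - y2)
        e2 = np.linalg.norm(y2 - y3)
        order = math.log2(e1 / e2)
        assert order >= 3.8

    def test_richardson_dt_halving_small_change(self, pathway_params):
        p = pathway_params
        a1, a2 = (lambda t: p.a10), (lambda t: p.a20)

        def final(dt):
            s = mg.initial_state(p)
            s = mg.integrate(s, 100.0, dt, a1, a2, p)
            return np.array([s.x1, s.x2, s.x3, s.x4, s.z])

        y1, y2 = final(0.05), final(0.025)
        rel = np.linalg.norm(y1 - y2) / np.linalg.norm(y2)
        assert rel < 1e-6

    def test_z_clamped_to_bounds(self, pathway_params):
        from dataclasses import replace
        p = replace(pathway_params, z_max=1.0005)
        state = mg.PathwayState(t=0.0, x1=0.045, x2=1.0, x3=0.3, x4=0.9,
                                z=1.0)
        for _ in range(200):
            state = mg.rk4_step(state, 0.05, lambda t: p.a10,
                                lambda t: p.a20, p)
            assert p.z_min <= state.z <= p.z_max

    def test_nonpositive_dt_rejected(self, pathway_params):
        state = mg.initial_state(pathway_params)
        with pytest.raises(ValueError):
            mg.rk4_step(state, 0.0, lambda t: 0.1, lambda t: 0.5,
                        pathway_params)


class TestHomeostasis:
    def test_fixed_point_sits_on_thresholds(self, pathway_params):
        p = pathway_params
        _, _, x3s, x4s = mg.steady_state(p)
        assert abs(x3s - p.x3_thr) / p.x3_thr < 1e-3
        assert abs(x4s - p.x4_thr) / p.x4_thr < 1e-3
        # both species rest below threshold: the myofibril law is silent
        assert mg.myofibril_rate(x3s, x4s, 1.0, p) == 0.0
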
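"""Single-cell dynamics: gate curves, membrane equation, integrator contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from timecellchain import (
    CellParams,
    CellState,
    IntegratorConfig,
    h_d_inf,
    m_d_inf,
    membrane_rhs,
    resting_state,
    step,
)


class TestGateCurves:
    @pytest.mark.parametrize(
        "v, expected, tol",
        [
            (-65.0, 0.5, 1e-12),       # sigmoid midpoint
            (-100.0, 0.0, 1e-7),       # activation gate closes when hyperpolarized
            (-50.0, 1.0 - 1.0 / (1.0 + math.exp(7.5)), 1e-12),
        ],
    )
    def test_m_inf_values(self, v, expected, tol):
        assert m_d_inf(v) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize(
        "v, expected, tol",
        [
            (-65.0, 0.5, 1e-12),
            (-75.0, 1.0 / (1.0 + math.exp(-10.0)), 1e-12),
            (-50.0, 1.0 / (1.0 + math.exp(15.0)), 1e-12),
        ],
    )
    def test_h_inf_values(self, v, expected, tol):
        assert h_d_inf(v) == pytest.approx(expected, abs=tol)

    def test_m_inf_increases_with_depolarization(self):
        # activation opens with excitation, inactivation closes with it
        v = np.linspace(-100.0, -30.0, 200)
        assert np.all(np.diff(m_d_inf(v)) > 0)
        assert np.all(np.diff(h_d_inf(v)) < 0)

    @given(v=st.floats(min_value=-200.0, max_value=100.0))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_gates_bounded(self, v):
        assert 0.0 <= m_d_inf(v) <= 1.0
        assert 0.0 <= h_d_inf(v) <= 1.0


class TestMembraneRhs:
    def test_leak_equilibrium(self):
        p = CellParams(g_D=0.0)
        state = CellState(v=p.E_L, m_d=0.0, h_d=1.0)
        dv, _, _ = membrane_rhs(state, p)
        assert dv == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_at_potassium_reversal(self, params):
        # at v = E_K the D-current vanishes regardless of its gates:
        # dv/dt = -g_L (E_K - E_L) / C_m = -8 * (-25) / 200 = +1.0 mV/ms
        state = CellState(v=params.E_K, m_d=0.7, h_d=0.9)
        dv, _, _ = membrane_rhs(state, params)
        assert dv == pytest.approx(1.0, abs=1e-12)

    def test_resting_point_regression(self, params):
        # bisection oracle: rest sits where leak balances the tonic D-current
        v_rest = resting_state(params)
        assert v_rest == pytest.approx(-67.2706, abs=1e-3)
        state = CellState(v=v_rest, m_d=float(m_d_inf(v_rest)), h_d=float(h_d_inf(v_rest)))
        dv, dm, dh = membrane_rhs(state, params)
        assert dv == pytest.approx(0.0, abs=1e-6)
        assert dm == pytest.approx(0.0, abs=1e-9)
        assert dh == pytest.approx(0.0, abs=1e-9)

    def test_rejects_non_finite_state(self, params):
        with pytest.raises(FloatingPointError):
            membrane_rhs(CellState(v=float("nan")), params)


class TestStep:
    def test_synaptic_decay_closed_form(self, params, integ):
        # s(t) = exp(-beta t): after 5 ms at beta = 0.2, s = e^-1
        state = CellState(v=-70.0, s=1.0)
        n = int(round(5.0 / integ.dt))
        for _ in range(n):
            state, spiked = step(state, params, integ, n_inh=60.0)
            assert not spiked
        assert state.s == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_threshold_reset_contract(self, params, integ):
        state = CellState(v=params.V_T + 0.5, m_d=1.0, h_d=0.0, s=0.2)
        new, spiked = step(state, params, integ, i_input=1000.0)
        assert spiked
        assert new.v == params.v_R
        assert new.s == 1.0
        assert new.firing

    def test_leak_only_relaxation_matches_analytic(self, integ):
        # with only the leak current, v(t) -> E_L with tau = C_m/g_L = 25 ms
        p = CellParams(g_D=0.0)
        state = CellState(v=-80.0)
        t, v0 = 0.0, -80.0
        while t < 100.0:
            state, _ = step(state, p, integ)
            t += integ.dt
            analytic = p.E_L + (v0 - p.E_L) * math.exp(-t / (p.C_m / p.g_L))
            assert abs(state.v - analytic) < 0.1

    def test_gate_relaxation_exact_at_frozen_voltage(self, params, integ):
        # holding v fixed, h_d follows its exponential relaxation law exactly
        v_hold = -60.0
        h0, t_end = 1.0, 2000.0
        state = CellState(v=v_hold, h_d=h0)
        h_inf = float(h_d_inf(v_hold))
        n = int(round(t_end / integ.dt))
        for k in range(n):
            new, _ = step(state, params, integ, n_inh=1e6)  # clamp escape away
            state = CellState(v=v_hold, m_d=new.m_d, h_d=new.h_d, s=new.s)
        analytic = h_inf + (h0 - h_inf) * math.exp(-t_end / params.h_d_tau)
        assert abs(state.h_d - analytic) < 1e-6

    @given(
        v=st.floats(min_value=-100.0, max_value=-45.0),
        m=st.floats(min_value=0.0, max_value=1.0),
        h=st.floats(min_value=0.0, max_value=1.0),
        s=st.floats(min_value=0.0, max_value=1.0),
        s_pre=st.floats(min_value=0.0, max_value=1.0),
        n_inh=st.floats(min_value=0.0, max_value=60.0),
    )
    @settings(deadline=None, max_examples=150, derandomize=True)
    def test_gates_stay_bounded_under_any_drive(self, v, m, h, s, s_pre, n_inh):
        p, integ = CellParams(), IntegratorConfig()
        state = CellState(v=v, m_d=m, h_d=h, s=s)
        for _ in range(20):
            state, _ = step(state, p, integ, s_pre=s_pre, n_inh=n_inh)
            assert 0.0 <= state.m_d <= 1.0
            assert 0.0 <= state.h_d <= 1.0
            assert 0.0 <= state.s <= 1.0

    def test_s_non_increasing_between_spikes(self, params, integ):
        state = CellState(v=-70.0, s=0.8)
        prev = state.s
        for _ in range(200):
            state, spiked = step(state, params, integ, n_inh=60.0)
            if not spiked:
                assert state.s <= prev
            prev = state.s

    def test_determinism(self, params, integ):
        def run():
            state = CellState(v=-70.0, s=1.0)
            out = []
            for _ in range(500):
                state, _ = step(state, params, integ, s_pre=0.3, n_inh=10.0)
                out.append((state.v, state.m_d, state.h_d, state.s))
            return out

        assert run() == run()


class TestValidation:
    def test_reset_must_be_below_threshold(self):
        with pytest.raises(ValueError):
            CellParams(v_R=-40.0)

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            CellParams(g_D=-1.0)

    def test_default_reversal_ordering(self, params):
        assert params.E_Inh < params.E_K < params.E_L < params.V_T < params.E_Exc

    def test_dt_must_be_positive(self):
        with pytest.raises(ValueError):
            IntegratorConfig(dt=0.0)
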
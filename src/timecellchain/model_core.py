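"""Single time-cell dynamics: membrane equation, D-current kinetics, synaptic decay.

The cell is a spikeless integrate-and-fire unit with four currents,

    C_m dv/dt = -(I_L + I_D + I_Exc + I_Inh) + I_input + I_noise,

where the D-type potassium current I_D = g_D * m_d * h_d**2 * (v - E_K)
carries a fast activation gate m_d (tau ~ 0.6 ms) and a slowly inactivating
gate h_d (tau ~ seconds).  The slow decay of h_d under depolarizing drive is
what converts a level of inhibition into a delay-to-spike: the stronger the
inhibition, the further h_d must fall before the membrane can escape to
threshold.  A threshold crossing (v >= V_T) is recorded as a spike event and
the membrane is reset to v_R; no action-potential waveform is modelled.

Gates are advanced by exponential relaxation toward their voltage-dependent
targets (exact for frozen v over one step); the voltage by an explicit Euler
update.  This split handles the stiffness gap between m_d (0.6 ms) and h_d
(1500 ms) at dt = 0.05 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, fields

import numpy as np

__all__ = [
    "CellParams",
    "CellState",
    "IntegratorConfig",
    "m_d_inf",
    "h_d_inf",
    "membrane_rhs",
    "step",
    "resting_state",
]


@dataclass(frozen=True)
class CellParams:
    """Biophysical constants of one time cell.

    Values are the model's published numerals, treated as one consistent
    arbitrary-unit system (voltages in mV, times in ms); no unit conversion
    is applied.
    """

    C_m: float = 200.0      # membrane capacitance
    g_L: float = 8.0        # leak conductance
    E_L: float = -65.0      # leak reversal (mV)
    g_D: float = 4.0        # D-current maximal conductance
    E_K: float = -90.0      # potassium reversal (mV)
    m_d_tau: float = 0.6    # D-current activation time constant (ms)
    h_d_tau: float = 1500.0  # D-current inactivation time constant (ms)
    V_T: float = -50.0      # spike threshold (mV)
    v_R: float = -85.0      # reset potential (mV)
    v_init: float = -75.0   # initial membrane potential (mV)
    g_Exc: float = 15.0     # feedforward excitatory maximal conductance
    g_Excr: float = 50.0    # recurrent (within-ensemble) excitatory conductance
    E_Exc: float = 0.0      # excitatory reversal (mV)
    beta: float = 0.2       # synaptic decay rate (1/ms)
    g_Inh: float = 0.02     # per-unit inhibitory conductance
    E_Inh: float = -100.0   # inhibitory reversal (mV)

    def __post_init__(self) -> None:
        for name in ("C_m", "g_L", "g_D", "g_Exc", "g_Excr", "g_Inh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("m_d_tau", "h_d_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not self.v_R < self.V_T:
            raise ValueError(
                f"reset must lie below threshold (v_R={self.v_R}, V_T={self.V_T})"
            )

    def with_overrides(self, **kwargs) -> "CellParams":
        return replace(self, **kwargs)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


@dataclass
class CellState:
    """Instantaneous dynamical variables of one cell.

    ``firing`` marks the persistent-firing regime of the ensemble the unit
    stands for: set at the first threshold crossing, cleared when the
    successor in a chain silences the cell.
    """

    v: float
    m_d: float = 0.0
    h_d: float = 1.0
    s: float = 0.0
    firing: bool = False

    @classmethod
    def initial(cls, params: CellParams) -> "CellState":
        return cls(v=params.v_init, m_d=0.0, h_d=1.0, s=0.0, firing=False)

    def require_finite(self) -> None:
        for name in ("v", "m_d", "h_d", "s"):
            if not math.isfinite(getattr(self, name)):
                raise FloatingPointError(
                    f"non-finite state variable {name}={getattr(self, name)!r}"
                )


@dataclass(frozen=True)
class IntegratorConfig:
    """Fixed-step integration settings.

    dt = 0.05 ms keeps spike times converged to well under 1 ms against a
    halved step (see the dt-convergence tests).
    """

    dt: float = 0.05
    method: str = "exponential-euler"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.method != "exponential-euler":
            raise ValueError(f"unknown integration method {self.method!r}")


def m_d_inf(v):
    """Steady-state D-current activation, 1 - 1/(1 + exp((v + 65)/2))."""
    return 1.0 - 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) + 65.0) / 2.0))


def h_d_inf(v):
    """Steady-state D-current inactivation, 1/(1 + exp(v + 65)).

    Near 1 at hyperpolarized v (the current recharges under inhibition),
    near 0 at depolarized v (it inactivates under excitation).
    """
    return 1.0 / (1.0 + np.exp(np.asarray(v, dtype=float) + 65.0))


def membrane_rhs(
    state: CellState,
    params: CellParams,
    s_pre: float = 0.0,
    n_inh: float = 0.0,
    i_input: float = 0.0,
    i_noise: float = 0.0,
) -> tuple[float, float, float]:
    """Time derivatives (dv/dt, dm_d/dt, dh_d/dt) of the membrane system.

    ``s_pre`` is the presynaptic (feedforward) synaptic variable; the cell's
    own ``state.s`` drives the recurrent term only while the persistent-firing
    flag is set.  ``n_inh`` is the accumulated-inhibition count N in
    I_Inh = N * g_Inh * (v - E_Inh).
    """
    state.require_finite()
    p = params
    v = state.v
    i_l = p.g_L * (v - p.E_L)
    i_d = p.g_D * state.m_d * state.h_d**2 * (v - p.E_K)
    s_self = state.s if state.firing else 0.0
    i_exc = (p.g_Exc * s_pre + p.g_Excr * s_self) * (v - p.E_Exc)
    i_inh = n_inh * p.g_Inh * (v - p.E_Inh)
    dv = (-(i_l + i_d + i_exc + i_inh) + i_input + i_noise) / p.C_m
    dm = (float(m_d_inf(v)) - state.m_d) / p.m_d_tau
    dh = (float(h_d_inf(v)) - state.h_d) / p.h_d_tau
    return dv, dm, dh


def step(
    state: CellState,
    params: CellParams,
    config: IntegratorConfig,
    s_pre: float = 0.0,
    n_inh: float = 0.0,
    i_input: float = 0.0,
    i_noise: float = 0.0,
) -> tuple[CellState, bool]:
    """Advance one integration step; returns (new_state, spiked).

    Gates relax exponentially toward their frozen-v targets; s decays as
    exp(-beta*dt); v takes an explicit Euler step.  A threshold crossing
    resets v to v_R and the synaptic variable to 1.
    """
    p, dt = params, config.dt
    dv, _, _ = membrane_rhs(state, p, s_pre, n_inh, i_input, i_noise)
    v_old = state.v
    m_new = state.m_d + (float(m_d_inf(v_old)) - state.m_d) * (
        1.0 - math.exp(-dt / p.m_d_tau)
    )
    h_new = state.h_d + (float(h_d_inf(v_old)) - state.h_d) * (
        1.0 - math.exp(-dt / p.h_d_tau)
    )
    s_new = state.s * math.exp(-p.beta * dt)
    v_new = v_old + dv * dt
    spiked = v_new >= p.V_T
    if spiked:
        v_new = p.v_R
        s_new = 1.0
    out = CellState(v=v_new, m_d=m_new, h_d=h_new, s=s_new,
                    firing=state.firing or spiked)
    out.require_finite()
    return out, spiked


def resting_state(params: CellParams, n_inh: float = 0.0) -> float:
    """Resting membrane potential: the v* solving
    g_L(v-E_L) + g_D m_inf(v) h_inf(v)^2 (v-E_K) + N g_Inh (v-E_Inh) = 0.

    Solved by bisection on [E_Inh, V_T); the balance of leak against the
    tonically active D-current puts rest a couple of mV below E_L.
    """
    p = params

    def f(v: float) -> float:
        return (
            p.g_L * (v - p.E_L)
            + p.g_D * float(m_d_inf(v)) * float(h_d_inf(v)) ** 2 * (v - p.E_K)
            + n_inh * p.g_Inh * (v - p.E_Inh)
        )

    lo, hi = p.E_Inh, p.V_T - 1e-9
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("no resting point bracketed in [E_Inh, V_T)")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
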
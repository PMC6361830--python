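"""Compiled fixed-step integration kernels.

These are the hot loops behind ``network.advance_trial`` and the single-cell
protocols.  The dynamics are the same as in :mod:`timecellchain.model_core`
(a test cross-checks the two step for step); the kernels add the chain
bookkeeping (inhibition counter, persistent-firing schedule, silencing) and
the Poisson bombardment.

Poisson noise: each cell receives n_presyn independent Poisson trains; unit
events set that unit's synaptic variable s_n to 1, and all s_n decay at
beta_n.  The kernel tracks the per-cell sum S = sum_n s_n exactly using one
last-event time per (cell, unit): between events S decays by exp(-beta_n*dt);
an event of unit u adds 1 - exp(-beta_n*(t - t_last[u])).  The merged event
stream is drawn at rate n_presyn*rate with uniform unit assignment
(superposition property), from numba's seeded MT19937.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by chain_trial_kernel
STATUS_TARGET_REACHED = 0
STATUS_STALLED = 1
STATUS_HORIZON = 2


@njit(cache=True)
def _m_inf(v):
    return 1.0 - 1.0 / (1.0 + np.exp((v + 65.0) / 2.0))


@njit(cache=True)
def _h_inf(v):
    return 1.0 / (1.0 + np.exp(v + 65.0))


@njit(cache=True)
def single_cell_window_kernel(
    v0, m0, h0,
    # scalar cell parameters
    C_m, g_L, E_L, g_D, E_K, m_d_tau, h_d_tau, V_T, v_R,
    g_Inh, E_Inh, E_Exc,
    # protocol
    n_inh, t0, t1, stim_onset, stim_g, stim_off_at_spike,
    dt, trace_every,
):
    """One constant-inhibition window of the single-cell delayed-firing protocol.

    The stimulus is an excitatory conductance step of amplitude ``stim_g``
    (current stim_g*(v - E_Exc)) switched on at ``stim_onset`` and, if
    ``stim_off_at_spike``, released at the first spike.  Returns the final
    state, all spike times in the window, and a subsampled (t, v, m, h)
    trace.
    """
    n_steps = int(round((t1 - t0) / dt))
    em = 1.0 - np.exp(-dt / m_d_tau)
    eh = 1.0 - np.exp(-dt / h_d_tau)
    v, m, h = v0, m0, h0
    spikes = np.empty(1024, np.float64)
    n_spk = 0
    n_tr = n_steps // trace_every + 1
    trace = np.empty((n_tr, 4), np.float64)
    i_tr = 0
    stim_on = True
    for k in range(n_steps):
        t = t0 + k * dt
        if k % trace_every == 0 and i_tr < n_tr:
            trace[i_tr, 0] = t
            trace[i_tr, 1] = v
            trace[i_tr, 2] = m
            trace[i_tr, 3] = h
            i_tr += 1
        i_stim = stim_g * (v - E_Exc) if (stim_on and t >= stim_onset) else 0.0
        i_l = g_L * (v - E_L)
        i_d = g_D * m * h * h * (v - E_K)
        i_inh = n_inh * g_Inh * (v - E_Inh)
        dv = (-(i_l + i_d + i_inh + i_stim)) * dt / C_m
        m += (_m_inf(v) - m) * em
        h += (_h_inf(v) - h) * eh
        v += dv
        if v >= V_T:
            v = v_R
            if n_spk < spikes.size:
                spikes[n_spk] = t + dt
                n_spk += 1
            if stim_off_at_spike:
                stim_on = False
    return v, m, h, spikes[:n_spk], trace[:i_tr]


@njit(cache=True)
def chain_trial_kernel(
    # network
    n_cells,
    g_D_arr, g_Exc_arr,          # per-cell (possibly noise-perturbed)
    # scalar cell parameters
    C_m, g_L, E_L, E_K, m_d_tau, h_d_tau, V_T, v_R, v_init,
    g_Excr, E_Exc, beta, g_Inh, E_Inh,
    # stimulus: conductance step to cell 0 from stim_onset; released at
    # cell 0's first spike, or after stim_duration if that is positive
    stim_g, stim_onset, stim_duration,
    # persistent-firing regime; s_bar > 0 selects mean-field coupling: an
    # actively firing ensemble's synaptic output is held at s_bar (the
    # asynchronous-population average of the reset-decay sawtooth) instead
    # of the single-unit sawtooth itself
    persistent_period, s_bar,
    # run control
    dt, t_end, stop_cell, stall_window,
    # Poisson bombardment (per cell); pnoise_on == 0 disables
    pnoise_on, n_presyn, rate_per_ms, g_noise, beta_n, pseed,
    max_spikes,
):
    """Run one chain trial.  Returns (spike_cells, spike_times, first_spike,
    status) with 0-based cell indices and times in ms.

    Bookkeeping per the model definition: the global inhibition count N
    increments at each cell's first spike; that same event clears the
    predecessor's persistent-firing flag (silencing).  Once silenced a cell
    emits no further spikes.  A trial ends when ``stop_cell`` first fires,
    when no first spike has occurred for ``stall_window`` ms (wave death),
    or at the horizon ``t_end``.
    """
    n_steps = int(round(t_end / dt))
    em = 1.0 - np.exp(-dt / m_d_tau)
    eh = 1.0 - np.exp(-dt / h_d_tau)
    es = np.exp(-beta * dt)
    esn = np.exp(-beta_n * dt)

    v = np.full(n_cells, v_init)
    m = np.zeros(n_cells)
    h = np.ones(n_cells)
    s = np.zeros(n_cells)
    firing = np.zeros(n_cells, np.bool_)
    fired = np.zeros(n_cells, np.bool_)
    next_emit = np.full(n_cells, np.inf)
    first_spike = np.full(n_cells, np.nan)

    spike_cells = np.empty(max_spikes, np.int32)
    spike_times = np.empty(max_spikes, np.float64)
    n_spk = 0

    # Poisson state
    S = np.zeros(n_cells)
    t_last = np.full((n_cells, n_presyn), -1.0e30)
    next_evt = np.full(n_cells, np.inf)
    g_syn_noise = 0.0
    if pnoise_on != 0:
        np.random.seed(pseed)
        g_syn_noise = g_noise / n_presyn
        for i in range(n_cells):
            next_evt[i] = np.random.exponential(1.0 / (n_presyn * rate_per_ms))

    N = 0.0
    status = STATUS_HORIZON
    t_last_first = 0.0
    low = 0  # cells below `low` are silenced and inert

    for k in range(n_steps):
        t = k * dt
        tn = t + dt
        s_prev = s.copy()
        for i in range(low, n_cells):
            vi = v[i]
            if pnoise_on != 0:
                S[i] *= esn
                while next_evt[i] <= tn:
                    u = np.random.randint(0, n_presyn)
                    S[i] += 1.0 - np.exp(-beta_n * (next_evt[i] - t_last[i, u]))
                    t_last[i, u] = next_evt[i]
                    next_evt[i] += np.random.exponential(
                        1.0 / (n_presyn * rate_per_ms)
                    )
            if i > 0:
                if s_bar > 0.0 and firing[i - 1]:
                    s_pre = s_bar
                else:
                    s_pre = s_prev[i - 1]
            else:
                s_pre = 0.0
            s_self = s_prev[i] if firing[i] else 0.0
            i_stim = 0.0
            if i == 0 and t >= stim_onset:
                if stim_duration > 0.0:
                    if t < stim_onset + stim_duration:
                        i_stim = stim_g * (vi - E_Exc)
                elif not fired[0]:
                    i_stim = stim_g * (vi - E_Exc)
            i_l = g_L * (vi - E_L)
            i_d = g_D_arr[i] * m[i] * h[i] * h[i] * (vi - E_K)
            i_exc = (g_Exc_arr[i] * s_pre + g_Excr * s_self) * (vi - E_Exc)
            i_inh = N * g_Inh * (vi - E_Inh)
            i_noise = g_syn_noise * S[i] * (vi - E_Exc)
            m[i] += (_m_inf(vi) - m[i]) * em
            h[i] += (_h_inf(vi) - h[i]) * eh
            s[i] *= es
            v[i] = vi + (-(i_l + i_d + i_exc + i_inh + i_noise + i_stim)) * dt / C_m
            if not np.isfinite(v[i]):
                raise FloatingPointError("membrane potential diverged")

            emit = False
            if firing[i]:
                if tn >= next_emit[i]:
                    emit = True
            elif (not fired[i]) and v[i] >= V_T:
                emit = True
            if emit:
                v[i] = v_R
                s[i] = 1.0
                next_emit[i] = tn + persistent_period
                if n_spk < max_spikes:
                    spike_cells[n_spk] = i
                    spike_times[n_spk] = tn
                    n_spk += 1
                if not fired[i]:
                    fired[i] = True
                    firing[i] = True
                    first_spike[i] = tn
                    N += 1.0
                    t_last_first = tn
                    if i > 0:
                        firing[i - 1] = False
                        next_emit[i - 1] = np.inf
                        if s_bar > 0.0:
                            s[i - 1] = s_bar  # tail decays from the mean level
                        low = i - 1  # predecessor stays one index back for its s tail
                        if i >= 2:
                            s[i - 2] = 0.0  # now inert; kill the frozen tail
                    if i == stop_cell:
                        return (
                            spike_cells[:n_spk],
                            spike_times[:n_spk],
                            first_spike,
                            STATUS_TARGET_REACHED,
                        )
        if tn - t_last_first > stall_window:
            status = STATUS_STALLED
            break
    return spike_cells[:n_spk], spike_times[:n_spk], first_spike, status
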
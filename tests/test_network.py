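"""Chain assembly, trial bookkeeping, and the compiled-kernel/pure-python
agreement on the shared dynamics."""

import numpy as np
import pytest

from timecellchain import (
    CellParams,
    CellState,
    IntegratorConfig,
    NetworkConfig,
    StimulusProtocol,
    build_chain,
    inhibition_trace,
    step,
)
from timecellchain import _kernels  # noqa: F401  (import check)
from timecellchain._kernels import single_cell_window_kernel


class TestBuildChain:
    def test_smallest_chain(self):
        chain = build_chain(NetworkConfig(n_cells=1))
        assert chain.feedforward_edges == []
        assert chain.self_edges == [(1, 1)]

    def test_three_cell_topology(self):
        chain = build_chain(NetworkConfig(n_cells=3))
        assert chain.feedforward_edges == [(1, 2), (2, 3)]
        assert chain.self_edges == [(1, 1), (2, 2), (3, 3)]

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_cells=0)


class TestKernelMatchesPurePython:
    def test_single_cell_trajectory_agreement(self, params, integ):
        """The compiled window kernel and model_core.step integrate the same
        equations: trajectories must agree to float tolerance."""
        n_inh, t_end = 20.0, 400.0
        v, m, h, _, trace = single_cell_window_kernel(
            params.v_init, 0.0, 1.0,
            params.C_m, params.g_L, params.E_L, params.g_D, params.E_K,
            params.m_d_tau, params.h_d_tau, params.V_T, params.v_R,
            params.g_Inh, params.E_Inh, params.E_Exc,
            n_inh, 0.0, t_end, np.inf, 4.0, True, integ.dt, 1,
        )
        state = CellState(v=params.v_init, m_d=0.0, h_d=1.0)
        for _ in range(int(round(t_end / integ.dt))):
            state, _ = step(state, params, integ, n_inh=n_inh)
        assert state.v == pytest.approx(v, abs=1e-9)
        assert state.m_d == pytest.approx(m, abs=1e-12)
        assert state.h_d == pytest.approx(h, abs=1e-12)


class TestAdvanceTrial:
    def test_chain_causality_and_order(self, small_chain_config):
        chain = build_chain(small_chain_config)
        rec = chain.advance_trial(t_end=30_000.0)
        assert rec.status == "completed"
        fs = rec.first_spike
        assert np.all(np.diff(fs) > 0)  # cell i+1 never leads cell i
        # event stream: each cell's first appearance in index order
        first_appearance = [np.argmax(rec.cells == c) for c in range(1, 9)]
        assert first_appearance == sorted(first_appearance)

    def test_no_coupling_no_wave(self, small_chain_config):
        cfg = NetworkConfig(
            n_cells=small_chain_config.n_cells,
            params=CellParams(g_Exc=0.0),
        )
        rec = build_chain(cfg).advance_trial(t_end=20_000.0)
        assert rec.status == "stalled"
        assert rec.n_fired == 1  # only the stimulated cell
        assert set(np.unique(rec.cells)) == {1}

    def test_no_inhibition_intervals_stop_growing(self):
        # without the inhibition build-up the transmission delay never grows:
        # ISIs only settle downward while h_d relaxes from its fully
        # recharged initial value toward its resting level; with inhibition
        # on, the late ISIs turn around and lengthen again
        cfg = NetworkConfig(n_cells=10, params=CellParams(g_Inh=0.0))
        rec = build_chain(cfg).advance_trial(t_end=30_000.0)
        assert rec.status == "completed"
        isi = rec.isi[2:]  # skip the onset transient
        assert np.all(np.diff(isi) <= 0)
        with_inh = build_chain(NetworkConfig(n_cells=10)).advance_trial(
            t_end=30_000.0
        )
        assert with_inh.isi[-1] > with_inh.isi[-5]

    def test_inhibition_staircase(self, small_chain_config, params):
        chain = build_chain(small_chain_config)
        rec = chain.advance_trial(t_end=30_000.0)
        inh = inhibition_trace(rec, params)
        assert np.all(np.diff(inh[:, 1]) >= 0)          # N non-decreasing
        assert inh[-1, 1] == rec.n_fired                # N(end) = cells fired
        assert inh[-1, 2] == pytest.approx(rec.n_fired * params.g_Inh)

    def test_silencing_stops_predecessor(self, small_chain_config):
        chain = build_chain(small_chain_config)
        rec = chain.advance_trial(t_end=30_000.0)
        for k in range(1, small_chain_config.n_cells):
            successor_first = rec.first_spike[k]
            later = rec.times[(rec.cells == k) & (rec.times > successor_first)]
            assert later.size == 0, f"cell {k} spiked after cell {k+1} started"

    def test_deterministic_repeats(self, small_chain_config):
        chain = build_chain(small_chain_config)
        a = chain.advance_trial(t_end=20_000.0)
        b = chain.advance_trial(t_end=20_000.0)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.cells, b.cells)

    def test_stop_cell_truncates(self, small_chain_config):
        chain = build_chain(small_chain_config)
        rec = chain.advance_trial(t_end=30_000.0, stop_cell=4)
        assert rec.status == "completed"
        assert rec.n_fired == 4

    def test_stimulus_must_target_cell_one(self, small_chain_config):
        chain = build_chain(small_chain_config)
        with pytest.raises(ValueError):
            chain.advance_trial(StimulusProtocol(target_cell=3))

    def test_fixed_short_pulse_cannot_start_wave(self, small_chain_config):
        # a 10 ms pulse of the default amplitude leaves the D-current no time
        # to inactivate: documented motivation for the until-spike default
        chain = build_chain(small_chain_config)
        rec = chain.advance_trial(
            StimulusProtocol(duration=10.0), t_end=15_000.0
        )
        assert rec.n_fired == 0
        assert rec.status == "stalled"

    def test_dt_halving_shifts_first_spikes_under_1ms(self):
        cfg = NetworkConfig(n_cells=4)
        chain = build_chain(cfg)
        a = chain.advance_trial(t_end=20_000.0, integrator=IntegratorConfig(dt=0.05))
        b = chain.advance_trial(t_end=20_000.0, integrator=IntegratorConfig(dt=0.025))
        assert a.status == b.status == "completed"
        assert np.all(np.abs(a.first_spike - b.first_spike) < 1.0)

    def test_sawtooth_coupling_variant_still_propagates(self):
        # single-unit sawtooth coupling (no mean-field averaging) is kept as
        # a variant; its delays ride the emission-grid ripple, so spike
        # times are only required to agree with mean-field to ~one period
        cfg = NetworkConfig(n_cells=6, coupling="sawtooth")
        rec = build_chain(cfg).advance_trial(t_end=30_000.0)
        assert rec.status == "completed"
        assert np.all(np.diff(rec.first_spike) > 0)
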
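"""Chain assembly: feedforward routing, global inhibition counter, silencing.

The network is a one-dimensional chain of time-cell ensembles.  Cell i's
feedforward drive reads cell i-1's synaptic variable; each cell's recurrent
drive reads its own.  All cells share the common inhibitory current
I_Inh = N * g_Inh * (v - E_Inh), where N counts the cells that have fired so
far (incremented once, at each cell's first spike).  When cell k+1 first
fires, cell k's persistent-firing regime is cleared ("silencing"): its
synaptic variable still decays naturally, so the successor briefly receives
a decaying tail, but the silenced cell emits no further spikes.

Cell indices are 1-based in all records, matching the "TC 30" / "TC 40"
naming convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model_core import CellParams, IntegratorConfig

__all__ = ["NetworkConfig", "SpikeRecord", "Chain", "build_chain", "inhibition_trace"]

#: default absolute cap on recorded spikes per trial
MAX_SPIKES = 500_000

#: trial outcome labels, indexed by kernel status code
STATUS_LABELS = ("completed", "stalled", "horizon")


@dataclass(frozen=True)
class NetworkConfig:
    """Chain size, shared cell parameters, and the two bookkeeping rules.

    ``persistent_period`` is the inter-spike interval of a unit's
    persistent-firing regime (the ensemble firing rate is its reciprocal);
    see the methods note for how its default is anchored.
    """

    n_cells: int = 60
    params: CellParams = field(default_factory=CellParams)
    persistent_period: float = 16.0      # ms between persistent-regime spikes
    coupling: str = "mean-field"         # or "sawtooth" (single-unit s trace)
    inhibition_increment_rule: str = "first-spike"
    silencing_rule: str = "successor-first-spike"
    stall_window: float = 10_000.0       # ms without a new first spike => wave death
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.persistent_period <= 0:
            raise ValueError("persistent_period must be > 0")
        if self.coupling not in ("mean-field", "sawtooth"):
            raise ValueError(f"unknown coupling {self.coupling!r}")
        if self.inhibition_increment_rule != "first-spike":
            raise ValueError(
                f"unsupported inhibition rule {self.inhibition_increment_rule!r}"
            )
        if self.silencing_rule != "successor-first-spike":
            raise ValueError(f"unsupported silencing rule {self.silencing_rule!r}")

    @property
    def s_bar(self) -> float:
        """Time-average of the reset-decay synaptic sawtooth over one
        persistent-emission period: (1 - exp(-beta*T_p)) / (beta*T_p).
        This is the aggregate synaptic output of an asynchronously firing
        ensemble, and the level a mean-field coupled successor sees."""
        x = self.params.beta * self.persistent_period
        if x == 0.0:
            return 1.0
        return float((1.0 - np.exp(-x)) / x)


@dataclass
class SpikeRecord:
    """Per-trial spike events and per-cell first-spike times.

    ``cells`` holds 1-based cell indices, one entry per spike event, in time
    order.  ``first_spike[k]`` is the first spike time of cell k+1 (NaN if it
    never fired).  ``status`` is "completed" (target cell reached),
    "stalled" (wave death), or "horizon".
    """

    trial: int
    cells: np.ndarray
    times: np.ndarray
    first_spike: np.ndarray
    status: str
    t_end: float

    @property
    def n_fired(self) -> int:
        return int(np.isfinite(self.first_spike).sum())

    @property
    def isi(self) -> np.ndarray:
        """Intervals between consecutive cells' first spikes (activation ISIs)."""
        return np.diff(self.first_spike)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"trial": self.trial, "cell_index": self.cells, "spike_time_ms": self.times}
        )


class Chain:
    """A built chain, ready to run trials."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        n = config.n_cells
        # feedforward edges (i -> i+1) and one self-edge per cell, 1-based
        self.feedforward_edges = [(i, i + 1) for i in range(1, n)]
        self.self_edges = [(i, i) for i in range(1, n + 1)]

    def advance_trial(
        self,
        stimulus=None,
        t_end: float = 60_000.0,
        *,
        trial: int = 0,
        integrator: IntegratorConfig | None = None,
        g_D_per_cell: np.ndarray | None = None,
        g_Exc_per_cell: np.ndarray | None = None,
        poisson=None,
        stop_cell: int | None = None,
    ) -> SpikeRecord:
        """Run one trial and return its :class:`SpikeRecord`.

        ``stimulus`` is a :class:`timecellchain.protocols.StimulusProtocol`
        (defaults to the standard onset-at-zero step to cell 1).
        ``g_D_per_cell`` / ``g_Exc_per_cell`` override the shared maximal
        conductances cell by cell (the noise module produces these draws).
        ``poisson`` is a (n_presyn, rate_hz, g_noise, beta_n, seed) tuple or
        None.  ``stop_cell`` (1-based) ends the trial at that cell's first
        spike; a wave that dies beforehand is reported with status
        "stalled", not raised.
        """
        from .protocols import StimulusProtocol  # cycle-free late import

        cfg = self.config
        p = cfg.params
        n = cfg.n_cells
        integ = integrator or IntegratorConfig()
        stim = stimulus or StimulusProtocol()
        if stim.target_cell != 1:
            raise ValueError("the input pulse targets cell 1 in a chain protocol")
        g_D = np.full(n, p.g_D) if g_D_per_cell is None else np.asarray(
            g_D_per_cell, dtype=float
        )
        g_Exc = np.full(n, p.g_Exc) if g_Exc_per_cell is None else np.asarray(
            g_Exc_per_cell, dtype=float
        )
        if g_D.shape != (n,) or g_Exc.shape != (n,):
            raise ValueError("per-cell conductance arrays must have length n_cells")
        if poisson is None:
            pnoise = (0, 1, 0.0, 0.0, 0.1, 0)
        else:
            n_presyn, rate_hz, g_noise, beta_n, pseed = poisson
            pnoise = (1, int(n_presyn), rate_hz / 1000.0, g_noise, beta_n, int(pseed))
        stop = (stop_cell - 1) if stop_cell is not None else (n - 1)
        if not 0 <= stop < n:
            raise ValueError(f"stop_cell out of range: {stop_cell}")
        duration = stim.duration if stim.duration is not None else -1.0
        cells0, times, first, status = _kernels.chain_trial_kernel(
            n,
            g_D, g_Exc,
            p.C_m, p.g_L, p.E_L, p.E_K, p.m_d_tau, p.h_d_tau, p.V_T, p.v_R,
            p.v_init, p.g_Excr, p.E_Exc, p.beta, p.g_Inh, p.E_Inh,
            stim.amplitude, stim.onset, duration,
            cfg.persistent_period,
            cfg.s_bar if cfg.coupling == "mean-field" else 0.0,
            integ.dt, t_end, stop, cfg.stall_window,
            pnoise[0], pnoise[1], pnoise[2], pnoise[3], pnoise[4], pnoise[5],
            MAX_SPIKES,
        )
        return SpikeRecord(
            trial=trial,
            cells=cells0 + 1,
            times=times,
            first_spike=first,
            status=STATUS_LABELS[status],
            t_end=t_end,
        )


def build_chain(config: NetworkConfig) -> Chain:
    """Assemble the feedforward chain described by ``config``."""
    return Chain(config)


def inhibition_trace(record: SpikeRecord, params: CellParams) -> np.ndarray:
    """Accumulated-inhibition staircase implied by a trial's first spikes.

    Returns an array of rows (t_ms, N, g_inh_total): at each cell's first
    spike the count N steps up by one and the common inhibitory conductance
    is N * g_Inh.  The staircase is non-decreasing by construction of N.
    """
    t_first = np.sort(record.first_spike[np.isfinite(record.first_spike)])
    n_steps = np.arange(1, t_first.size + 1, dtype=float)
    return np.column_stack([t_first, n_steps, n_steps * params.g_Inh])
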
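"""The four runnable experiments: single-cell delays, chain wave, trial
statistics, and parameter sweeps.

Each protocol is deterministic given its configuration and base seed.  The
trial protocol uses a seed ladder (trial i draws from base_seed + i) so any
single trial can be reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .model_core import CellParams, IntegratorConfig
from .network import NetworkConfig, SpikeRecord, build_chain, inhibition_trace
from .noise import NoiseConfig, draw_conductance_arrays

__all__ = [
    "StimulusProtocol",
    "SweepSpec",
    "Fig2Result",
    "TrialsResult",
    "run_fig2_single_cell",
    "run_fig3_chain",
    "run_trials",
    "run_sweep",
    "FIG2_WINDOWS",
]

#: inhibition-count windows of the single-cell protocol:
#: (t_start, t_end, N); the input step starts 1000 ms after each window opens
FIG2_WINDOWS = ((1000.0, 4000.0, 20.0), (4000.0, 7000.0, 40.0), (7000.0, 10000.0, 60.0))

#: offset mixed into the Poisson stream seed so it is decoupled from the
#: conductance-draw stream of the same trial
_PSEED_OFFSET = 1_000_003
_PSEED_MOD = 2_147_483_647


@dataclass(frozen=True)
class StimulusProtocol:
    """External input: an excitatory conductance step to one cell.

    The input current is amplitude * (v - E_Exc).  ``duration=None`` holds
    the step from ``onset`` until the target cell's first spike (the default:
    a brief fixed pulse cannot drive the slow D-current escape); a positive
    ``duration`` gives a fixed square pulse instead.
    """

    amplitude: float = 4.0
    onset: float = 0.0
    duration: float | None = None
    target_cell: int = 1

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.duration is not None and self.duration <= 0:
            raise ValueError("duration must be positive (or None for until-spike)")
        if self.target_cell < 1:
            raise ValueError("target_cell is 1-based")


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter robustness sweep.

    ``parameter`` is 'h_d_tau', 'g_D' (cell parameters) or 'g_noise'
    (Poisson-only noise sweep: conductance jitter is disabled and the
    bombardment enabled, regardless of ``noise``'s own flags).
    """

    parameter: str
    values: tuple
    n_trials: int = 50
    config: NetworkConfig = field(default_factory=NetworkConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    up_to_cell: int | None = None
    t_max: float = 120_000.0
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.parameter not in ("h_d_tau", "g_D", "g_noise"):
            raise ValueError(f"unknown sweep parameter {self.parameter!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not all(np.isfinite(v) for v in self.values):
            raise ValueError("sweep values must be finite")


@dataclass
class Fig2Result:
    """Outcome of the single-cell delayed-firing protocol."""

    n_values: tuple          # inhibition counts, one per window
    onsets: np.ndarray       # input onset per window (ms)
    first_spike: np.ndarray  # first spike time per window (NaN = no spike)
    delays: np.ndarray       # first_spike - onset (NaN = no spike)
    trace: np.ndarray        # rows (t, v, m_d, h_d), subsampled

    def delay_for(self, n: float) -> float:
        return float(self.delays[self.n_values.index(n)])


@dataclass
class TrialsResult:
    """A batch of seeded trials plus exclusion bookkeeping."""

    records: list            # all SpikeRecords, in trial order
    config: NetworkConfig
    noise: NoiseConfig
    up_to_cell: int
    base_seed: int
    n_excluded: int          # trials whose wave died / hit the horizon

    @property
    def completed(self) -> list:
        return [r for r in self.records if r.status == "completed"]

    def first_spike_matrix(self) -> np.ndarray:
        """(n_completed, up_to_cell) matrix of first-spike times."""
        return np.array([r.first_spike[: self.up_to_cell] for r in self.completed])


def run_fig2_single_cell(
    params: CellParams | None = None,
    stimulus: StimulusProtocol | None = None,
    windows=FIG2_WINDOWS,
    onset_after: float = 1000.0,
    integrator: IntegratorConfig | None = None,
    trace_every: int = 20,
) -> Fig2Result:
    """Single isolated cell under three levels of imposed inhibition.

    One continuous simulation: the inhibition count N follows the window
    schedule, and within each window an input step starts ``onset_after`` ms
    after the window opens and is released at the cell's first spike.  The
    reported delay per window is first-spike time minus input onset; a
    window without a spike yields NaN.
    """
    p = params or CellParams()
    stim = stimulus or StimulusProtocol()
    integ = integrator or IntegratorConfig()
    v, m, h = p.v_init, 0.0, 1.0
    traces = []
    onsets, firsts, n_vals = [], [], []

    def segment(n_inh, t0, t1, stim_onset):
        nonlocal v, m, h
        v, m, h, spikes, tr = _kernels.single_cell_window_kernel(
            v, m, h,
            p.C_m, p.g_L, p.E_L, p.g_D, p.E_K, p.m_d_tau, p.h_d_tau, p.V_T,
            p.v_R, p.g_Inh, p.E_Inh, p.E_Exc,
            n_inh, t0, t1, stim_onset, stim.amplitude, True,
            integ.dt, trace_every,
        )
        traces.append(tr)
        return spikes

    lead_end = windows[0][0]
    if lead_end > 0:
        segment(0.0, 0.0, lead_end, np.inf)  # settle at rest, no input
    for t0, t1, n_inh in windows:
        onset = t0 + onset_after
        spikes = segment(n_inh, t0, t1, onset)
        after = spikes[spikes >= onset] if spikes.size else spikes
        firsts.append(after[0] if after.size else np.nan)
        onsets.append(onset)
        n_vals.append(n_inh)

    firsts = np.array(firsts)
    onsets = np.array(onsets)
    return Fig2Result(
        n_values=tuple(n_vals),
        onsets=onsets,
        first_spike=firsts,
        delays=firsts - onsets,
        trace=np.vstack(traces),
    )


def run_fig3_chain(
    config: NetworkConfig | None = None,
    stimulus: StimulusProtocol | None = None,
    t_end: float = 60_000.0,
) -> tuple[SpikeRecord, np.ndarray]:
    """Noise-free chain wave (40 cells, h_d_tau = 3000 by default).

    Returns the full SpikeRecord and the accumulated-inhibition staircase
    (rows t, N, N*g_Inh).  A wave that dies is reported in the record's
    status, not raised.
    """
    cfg = config or NetworkConfig(
        n_cells=40, params=CellParams(h_d_tau=3000.0)
    )
    chain = build_chain(cfg)
    rec = chain.advance_trial(stimulus, t_end=t_end)
    return rec, inhibition_trace(rec, cfg.params)


def run_trials(
    config: NetworkConfig | None = None,
    noise: NoiseConfig | None = None,
    n_trials: int = 200,
    up_to_cell: int | None = None,
    t_max: float = 120_000.0,
) -> TrialsResult:
    """Repeated noisy trials, each run until ``up_to_cell`` first fires.

    Trial i draws its conductances from a generator seeded with
    noise.seed + i and its Poisson stream from a decoupled seed, so the
    whole batch is reproducible from the base seed and any single trial can
    be re-run alone.  Trials whose wave dies (or that hit ``t_max``) are
    kept in ``records`` but counted in ``n_excluded`` and skipped by the
    statistics layer.
    """
    cfg = config or NetworkConfig()
    noise_cfg = noise or NoiseConfig()
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    target = up_to_cell if up_to_cell is not None else cfg.n_cells
    if not 1 <= target <= cfg.n_cells:
        raise ValueError(f"up_to_cell must lie in [1, n_cells], got {target}")
    chain = build_chain(cfg)
    records = []
    n_excluded = 0
    for i in range(n_trials):
        seed_i = noise_cfg.seed + i
        rng = np.random.default_rng(seed_i)
        g_D, g_Exc = draw_conductance_arrays(cfg.params, noise_cfg, rng, cfg.n_cells)
        pseed = (seed_i + _PSEED_OFFSET) % _PSEED_MOD
        rec = chain.advance_trial(
            t_end=t_max,
            trial=i,
            g_D_per_cell=g_D,
            g_Exc_per_cell=g_Exc,
            poisson=noise_cfg.kernel_tuple(pseed),
            stop_cell=target,
        )
        if rec.status != "completed":
            n_excluded += 1
        records.append(rec)
    return TrialsResult(
        records=records,
        config=cfg,
        noise=noise_cfg,
        up_to_cell=target,
        base_seed=noise_cfg.seed,
        n_excluded=n_excluded,
    )


def run_sweep(spec: SweepSpec) -> dict:
    """Run the trial protocol at each sweep value; returns
    {value: (ScalarStats, TrialsResult)}.

    The g_noise sweep isolates the Poisson bombardment: conductance SDs are
    zeroed and the bombardment switched on, so all trial-to-trial
    variability comes from the synaptic noise alone.
    """
    from .stats import scalar_stats

    out = {}
    for value in spec.values:
        cfg, noise_cfg = spec.config, spec.noise
        if spec.parameter == "g_noise":
            noise_cfg = replace(
                noise_cfg, sd_gD=0.0, sd_gExc=0.0, poisson=True, g_noise=float(value)
            )
        else:
            params = cfg.params.with_overrides(**{spec.parameter: float(value)})
            cfg = replace(cfg, params=params)
        noise_cfg = replace(noise_cfg, seed=spec.base_seed)
        res = run_trials(
            config=cfg,
            noise=noise_cfg,
            n_trials=spec.n_trials,
            up_to_cell=spec.up_to_cell,
            t_max=spec.t_max,
        )
        try:
            st = scalar_stats(res)
        except ValueError:
            st = None  # fewer than 2 completed trials: stats undefined
        out[value] = (st, res)
    return out
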
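"""Stochastic ingredients: conductance jitter and Poisson synaptic bombardment.

Two noise sources enter the model.  (1) Trial-to-trial parameter noise: the
maximal conductances g_D and g_Exc are drawn fresh for every cell on every
trial from normal distributions centred on their base values (SD 1 and 5
respectively), truncated at zero.  (2) Membrane noise: each cell receives
n_presyn independent Poisson spike trains (50 Hz each); every presynaptic
event sets that synapse's variable s_n to 1, all s_n decay at rate beta_n,
and the summed current is

    I_noise = (g_noise / n_presyn) * sum_n s_n * (v - E_Exc),

i.e. the printed maximal conductance g_noise is shared across the n_presyn
synapses, which keeps the mean noise conductance (~g_noise/3) perturbative
relative to the leak.  The current is depolarizing (<= 0 for v < E_Exc).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import CellParams

__all__ = [
    "NoiseConfig",
    "draw_conductances",
    "draw_conductance_arrays",
    "poisson_train",
    "poisson_trains",
    "noise_current",
]


@dataclass(frozen=True)
class NoiseConfig:
    """Noise settings for a batch of trials.

    ``poisson`` switches the synaptic bombardment on or off; ``g_noise = 0``
    disables it as well.  ``sd_gD = sd_gExc = 0`` disables conductance
    jitter.  With everything off, repeated trials are identical.
    """

    sd_gD: float = 1.0
    sd_gExc: float = 5.0
    draw_mode: str = "per_trial"   # "per_trial" (shared draw) or "per_cell"
    poisson: bool = True
    n_presyn: int = 100
    rate_hz: float = 50.0
    g_noise: float = 1.0
    beta_n: float = 0.1       # 1/ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_gD < 0 or self.sd_gExc < 0:
            raise ValueError("conductance SDs must be >= 0")
        if self.draw_mode not in ("per_trial", "per_cell"):
            raise ValueError(f"unknown draw_mode {self.draw_mode!r}")
        if self.rate_hz < 0:
            raise ValueError("rate_hz must be >= 0")
        if self.n_presyn < 1:
            raise ValueError("n_presyn must be >= 1")
        if self.g_noise < 0:
            raise ValueError("g_noise must be >= 0")
        if self.beta_n <= 0:
            raise ValueError("beta_n must be > 0")

    @property
    def poisson_active(self) -> bool:
        return self.poisson and self.g_noise > 0 and self.rate_hz > 0

    def kernel_tuple(self, pseed: int):
        """(n_presyn, rate_hz, g_noise, beta_n, seed) for Chain.advance_trial,
        or None when the bombardment is off."""
        if not self.poisson_active:
            return None
        return (self.n_presyn, self.rate_hz, self.g_noise, self.beta_n, pseed)


def draw_conductances(
    base: CellParams, cfg: NoiseConfig, rng: np.random.Generator
) -> CellParams:
    """One noisy parameter set: g_D ~ N(base.g_D, sd_gD),
    g_Exc ~ N(base.g_Exc, sd_gExc), truncated at zero; all else unchanged."""
    g_D = max(0.0, rng.normal(base.g_D, cfg.sd_gD)) if cfg.sd_gD > 0 else base.g_D
    g_Exc = (
        max(0.0, rng.normal(base.g_Exc, cfg.sd_gExc))
        if cfg.sd_gExc > 0
        else base.g_Exc
    )
    return base.with_overrides(g_D=g_D, g_Exc=g_Exc)


def draw_conductance_arrays(
    base: CellParams, cfg: NoiseConfig, rng: np.random.Generator, n_cells: int
) -> tuple[np.ndarray, np.ndarray]:
    """Conductance draws for one trial.

    ``per_trial`` (default): one g_D and one g_Exc draw shared by every cell
    — the whole chain is faster or slower together, as a shared excitability
    state would make it.  ``per_cell``: each cell draws independently; note
    that at the default SDs independent draws routinely push single cells
    below the wave-propagation boundary, so most long-chain trials stall
    (such trials are reported, not hidden).
    """
    n_draw = n_cells if cfg.draw_mode == "per_cell" else 1
    g_D = np.maximum(rng.normal(base.g_D, cfg.sd_gD, n_draw), 0.0) \
        if cfg.sd_gD > 0 else np.full(n_draw, base.g_D)
    g_Exc = np.maximum(rng.normal(base.g_Exc, cfg.sd_gExc, n_draw), 0.0) \
        if cfg.sd_gExc > 0 else np.full(n_draw, base.g_Exc)
    if n_draw == 1:
        g_D = np.full(n_cells, g_D[0])
        g_Exc = np.full(n_cells, g_Exc[0])
    return g_D, g_Exc


def poisson_train(
    rate_hz: float, t_end: float, rng: np.random.Generator
) -> np.ndarray:
    """Event times (ms, strictly increasing) of one Poisson unit on [0, t_end),
    generated by exponential inter-event sampling."""
    if rate_hz <= 0 or t_end <= 0:
        return np.empty(0)
    rate_per_ms = rate_hz / 1000.0
    # draw in blocks; expected count + 6 sigma headroom
    n_guess = int(rate_per_ms * t_end + 6.0 * np.sqrt(rate_per_ms * t_end) + 16)
    times = np.cumsum(rng.exponential(1.0 / rate_per_ms, n_guess))
    while times.size and times[-1] < t_end:
        extra = np.cumsum(rng.exponential(1.0 / rate_per_ms, n_guess)) + times[-1]
        times = np.concatenate([times, extra])
    return times[times < t_end]


def poisson_trains(
    cfg: NoiseConfig, t_end: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Independent event-time arrays for all n_presyn units."""
    return [poisson_train(cfg.rate_hz, t_end, rng) for _ in range(cfg.n_presyn)]


def noise_current(v: float, s_n: np.ndarray, cfg: NoiseConfig) -> float:
    """I_noise = (g_noise/n_presyn) * sum_n s_n * (v - E_Exc) with E_Exc = 0.

    ``s_n`` are the instantaneous synaptic variables of the presynaptic
    units (each in [0, 1]).
    """
    s_n = np.asarray(s_n, dtype=float)
    if np.any((s_n < 0) | (s_n > 1)):
        raise ValueError("synaptic variables must lie in [0, 1]")
    return float(cfg.g_noise / cfg.n_presyn * s_n.sum() * (v - 0.0))


def evaluate_s(train: np.ndarray, t: float, beta_n: float) -> float:
    """Synaptic variable of one unit at time t: jumps to 1 at each event,
    decays at beta_n between events."""
    past = train[train <= t]
    if past.size == 0:
        return 0.0
    return float(np.exp(-beta_n * (t - past[-1])))
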
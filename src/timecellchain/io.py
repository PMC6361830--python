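"""Flat key-value configuration, run manifests, and output tables.

The config format is one ``key = value`` per line, ``#`` comments allowed.
Keys cover the cell parameters, network settings and noise settings; any
unknown key is a hard error so a typo cannot silently fall back to a
default.  An empty file resolves to the published defaults.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from pathlib import Path

import pandas as pd

from .model_core import CellParams, IntegratorConfig
from .network import NetworkConfig
from .noise import NoiseConfig

__all__ = [
    "ResolvedConfig",
    "load_config",
    "dump_config",
    "write_outputs",
    "RunManifest",
    "default_config_path",
]


def default_config_path() -> Path:
    """The shipped defaults file (published parameter values, annotated)."""
    return Path(__file__).with_name("defaults.cfg")

_CELL_KEYS = set(CellParams.field_names())
_NETWORK_KEYS = {"n_cells", "persistent_period", "coupling", "stall_window", "seed"}
_NOISE_KEYS = {
    "sd_gD", "sd_gExc", "draw_mode", "poisson", "n_presyn", "rate_hz",
    "g_noise", "beta_n",
}
_INTEGRATOR_KEYS = {"dt"}
_BOOL_KEYS = {"poisson"}
_INT_KEYS = {"n_cells", "seed", "n_presyn"}
_STR_KEYS = {"coupling", "draw_mode"}


@dataclasses.dataclass(frozen=True)
class ResolvedConfig:
    """Fully resolved run configuration (defaults merged with overrides)."""

    network: NetworkConfig
    noise: NoiseConfig
    integrator: IntegratorConfig

    @property
    def params(self) -> CellParams:
        return self.network.params

    def as_flat_dict(self) -> dict:
        d = {}
        d.update(dataclasses.asdict(self.network.params))
        d["n_cells"] = self.network.n_cells
        d["persistent_period"] = self.network.persistent_period
        d["coupling"] = self.network.coupling
        d["stall_window"] = self.network.stall_window
        d["seed"] = self.network.seed
        for k in sorted(_NOISE_KEYS):
            d[k] = getattr(self.noise, k)
        d["dt"] = self.integrator.dt
        return d


def _parse_value(key: str, raw: str):
    raw = raw.strip()
    if key in _STR_KEYS:
        return raw
    if key in _BOOL_KEYS:
        if raw.lower() in ("true", "1", "yes", "on"):
            return True
        if raw.lower() in ("false", "0", "no", "off"):
            return False
        raise ValueError(f"non-boolean value for {key!r}: {raw!r}")
    try:
        return int(raw) if key in _INT_KEYS else float(raw)
    except ValueError as err:
        raise ValueError(f"non-numeric value for {key!r}: {raw!r}") from err


def load_config(path=None, overrides: dict | None = None) -> ResolvedConfig:
    """Merge a flat key-value file (and/or an overrides dict) over defaults.

    Unknown keys raise, naming the offender.
    """
    merged: dict = {}
    if path is not None:
        text = Path(path).read_text()
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, raw = (part.strip() for part in line.split("=", 1))
            merged[key] = _parse_value(key, raw)
    if overrides:
        merged.update(overrides)

    known = _CELL_KEYS | _NETWORK_KEYS | _NOISE_KEYS | _INTEGRATOR_KEYS
    unknown = set(merged) - known
    if unknown:
        raise KeyError(f"unknown configuration key(s): {sorted(unknown)}")

    cell_kwargs = {k: v for k, v in merged.items() if k in _CELL_KEYS}
    net_kwargs = {k: v for k, v in merged.items() if k in _NETWORK_KEYS}
    noise_kwargs = {k: v for k, v in merged.items() if k in _NOISE_KEYS}
    integ_kwargs = {k: v for k, v in merged.items() if k in _INTEGRATOR_KEYS}

    params = CellParams(**cell_kwargs)
    network = NetworkConfig(params=params, **net_kwargs)
    noise = NoiseConfig(seed=network.seed, **noise_kwargs)
    integrator = IntegratorConfig(**integ_kwargs)
    return ResolvedConfig(network=network, noise=noise, integrator=integrator)


def dump_config(config: ResolvedConfig, path) -> None:
    """Write a resolved configuration back out as a flat key-value file."""
    lines = [f"{k} = {v}" for k, v in config.as_flat_dict().items()]
    _atomic_write(Path(path), "\n".join(lines) + "\n")


@dataclasses.dataclass
class RunManifest:
    """Everything needed to reproduce a run: resolved parameters, seeds,
    protocol name, outputs written, and exclusion counts."""

    protocol: str
    config: dict
    base_seed: int
    outputs: list
    n_trials: int = 1
    n_excluded: int = 0
    version: str = "0.1.0"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _atomic_write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_outputs(
    out_dir,
    *,
    protocol: str,
    config: ResolvedConfig,
    base_seed: int,
    spikes: pd.DataFrame | None = None,
    stats: pd.DataFrame | None = None,
    extra: dict | None = None,
    n_trials: int = 1,
    n_excluded: int = 0,
) -> list:
    """Write spike table, stats table and manifest as delimited text.

    File names are deterministic; re-running overwrites atomically.
    Returns the list of paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _write_df(df: pd.DataFrame, name: str) -> None:
        path = out / name
        _atomic_write(path, df.to_csv(index=False, sep="\t"))
        written.append(str(path))

    if spikes is not None:
        _write_df(spikes, f"{protocol}_spikes.tsv")
    if stats is not None:
        _write_df(stats, f"{protocol}_stats.tsv")
    for name, df in (extra or {}).items():
        _write_df(df, f"{protocol}_{name}.tsv")
    manifest = RunManifest(
        protocol=protocol,
        config=config.as_flat_dict(),
        base_seed=base_seed,
        outputs=[str(Path(p).name) for p in written],
        n_trials=n_trials,
        n_excluded=n_excluded,
    )
    mpath = out / f"{protocol}_manifest.json"
    _atomic_write(mpath, manifest.to_json() + "\n")
    written.append(str(mpath))
    return written
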
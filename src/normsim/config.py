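"""Configuration loading and validation.

Config files are flat YAML (JSON is a YAML subset) whose keys mirror the
:class:`~normsim.model.SimulationParams` field names exactly, plus the sweep
keys (``alpha_values`` etc.), ``mode``, ``output_dir`` and ``log_level``.
Unknown keys are rejected by name.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .experiments import SweepSpec
from .model import SimulationParams

__all__ = ["RunConfig", "load_config", "save_config", "params_dict"]

PARAM_KEYS = tuple(f.name for f in fields(SimulationParams))
SWEEP_KEYS = ("alpha_values", "beta_values", "r_values", "rho_values", "n_replicates", "root_seed")
TOP_KEYS = ("mode", "output_dir", "log_level")
MODES = ("run", "sweep", "plot")


@dataclass
class RunConfig:
    """A fully resolved invocation: what to do, with which payload, where."""

    mode: str = "run"
    params: SimulationParams | None = None
    sweep: SweepSpec | None = None
    output_dir: str = "."
    log_level: str = "INFO"

    @property
    def payload(self) -> SimulationParams | SweepSpec:
        return self.sweep if self.sweep is not None else self.params


def _normalize(value):
    if isinstance(value, list):
        return tuple(value)
    return value


def params_dict(params: SimulationParams) -> dict:
    """Plain-python dict of all parameter fields (tuples become lists)."""
    out = {}
    for f in fields(SimulationParams):
        v = getattr(params, f.name)
        out[f.name] = list(v) if isinstance(v, tuple) else v
    return out


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a config file, applying documented defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"could not parse config file {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a key-value mapping")

    known = set(TOP_KEYS) | set(PARAM_KEYS) | set(SWEEP_KEYS)
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")

    mode = data.get("mode", "run")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")

    sweep_items = {k: _normalize(data[k]) for k in SWEEP_KEYS if k in data}
    if mode == "run" and sweep_items:
        raise ValueError(
            f"keys only valid in sweep/plot mode: {', '.join(sorted(sweep_items))}"
        )

    param_items = {k: _normalize(data[k]) for k in PARAM_KEYS if k in data}
    params = SimulationParams(**param_items)

    sweep = None
    if mode == "sweep" or (mode == "plot" and sweep_items):
        sweep = SweepSpec(base_params=params, **sweep_items)

    return RunConfig(
        mode=mode,
        params=None if sweep is not None else params,
        sweep=sweep,
        output_dir=str(data.get("output_dir", ".")),
        log_level=str(data.get("log_level", "INFO")),
    )


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config back to YAML so that :func:`load_config` round-trips it."""
    data: dict = {
        "mode": config.mode,
        "output_dir": config.output_dir,
        "log_level": config.log_level,
    }
    params = config.sweep.base_params if config.sweep is not None else config.params
    data.update(params_dict(params or SimulationParams()))
    if config.sweep is not None:
        s = config.sweep
        data.update(
            alpha_values=list(s.alpha_values),
            beta_values=list(s.beta_values),
            r_values=list(s.r_values),
            rho_values=list(s.rho_values),
            n_replicates=s.n_replicates,
            root_seed=s.root_seed,
        )
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
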
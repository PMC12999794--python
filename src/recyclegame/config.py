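"""Flat key-value run configuration shared by the CLI commands.

A config file is a YAML mapping of flat keys (no nesting); CLI flags
override file values. Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Any, Optional

import yaml

from .game import GameParameters, StrategyState
from .scenarios import BASELINE

__all__ = ["RunConfig", "ConfigError", "load_config_file", "resolve_config"]


class ConfigError(ValueError):
    """Malformed or unknown configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved settings for one pipeline run."""

    # game parameters (baseline defaults)
    s: float = BASELINE.s
    c1: float = BASELINE.c1
    c2: float = BASELINE.c2
    t1: float = BASELINE.t1
    t2: float = BASELINE.t2
    m: float = BASELINE.m
    # initial state
    initial_phi: float = 0.5
    initial_omega: float = 0.5
    # integrator settings
    horizon: float = 10.0
    rel_tol: float = 1e-12
    abs_tol: float = 1e-14
    eps: float = 1e-4
    # sweep / threshold settings
    sweep_name: Optional[str] = None
    sweep_values: Optional[tuple[float, ...]] = None
    lo: Optional[float] = None
    hi: Optional[float] = None
    resolution: float = 1.0
    # basin / scenario settings
    basin_resolution: int = 21
    n: int = 100
    seed: int = 0
    # output
    out_dir: str = "results"
    figure: bool = False

    def params(self) -> GameParameters:
        return GameParameters(s=self.s, c1=self.c1, c2=self.c2, t1=self.t1, t2=self.t2, m=self.m)

    def initial(self) -> StrategyState:
        return StrategyState(self.initial_phi, self.initial_omega)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for f in fields(self):
            value = getattr(self, f.name)
            if isinstance(value, tuple):
                value = list(value)
            out[f.name] = value
        return out


_FIELD_NAMES = {f.name for f in fields(RunConfig)}


def load_config_file(path: str | Path) -> dict[str, Any]:
    """Read a flat YAML config mapping, rejecting unknown keys."""
    with open(path) as handle:
        data = yaml.safe_load(handle)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a flat mapping")
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return data


def resolve_config(
    config_path: Optional[str | Path] = None, **overrides: Any
) -> RunConfig:
    """Merge defaults, an optional config file, and CLI overrides (in that order)."""
    values: dict[str, Any] = {}
    if config_path is not None:
        values.update(load_config_file(config_path))
    for key, value in overrides.items():
        if key not in _FIELD_NAMES:
            raise ConfigError(f"unknown config key: {key!r}")
        if value is not None:
            values[key] = value
    if "sweep_values" in values and values["sweep_values"] is not None:
        values["sweep_values"] = tuple(float(v) for v in values["sweep_values"])
    try:
        return RunConfig(**values)
    except TypeError as err:  # pragma: no cover - defensive
        raise ConfigError(str(err)) from err
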
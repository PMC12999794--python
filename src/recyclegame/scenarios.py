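"""Seeded parameter-scenario generation.

The published calibration of this game is a single point estimate obtained
from stakeholder interviews (s=670, c1=120, c2=260, t1=46, t2=15, m=80) with
no distributional information, so scenario batches are sampled uniformly
and independently per parameter over explicit boxes. The default box is
[0.5x, 1.5x] of each baseline value, wide enough to cross every stability
boundary the one-parameter sensitivity scans visit.

Sampling is fully reproducible: a batch is a pure function of
(seed, n, ranges, regime_filter).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .game import GameParameters, PARAM_NAMES, validate_parameters
from .sweeps import REGIME_LABELS, regime_classification

__all__ = [
    "ScenarioBatch",
    "SamplingError",
    "baseline_scenario",
    "default_ranges",
    "sample_parameters",
    "regime_census",
    "save_batch",
    "load_batch",
]

#: rejection-sampling cap, per requested scenario
MAX_DRAWS_PER_SCENARIO = 10_000

BASELINE = GameParameters(s=670.0, c1=120.0, c2=260.0, t1=46.0, t2=15.0, m=80.0)


class SamplingError(RuntimeError):
    """Rejection sampling exhausted its draw budget."""


@dataclass(frozen=True)
class ScenarioBatch:
    """A reproducible batch of sampled game instances with regime tags."""

    seed: int
    ranges: dict[str, tuple[float, float]]
    scenarios: tuple[GameParameters, ...]
    regimes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.scenarios)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for index, (params, regime) in enumerate(zip(self.scenarios, self.regimes)):
            row = {"seed": self.seed, "index": index}
            row.update(params.as_dict())
            row["regime"] = regime
            rows.append(row)
        return pd.DataFrame(rows)


def baseline_scenario() -> GameParameters:
    """The interview-calibrated baseline instance of the recycling game."""
    return BASELINE


def default_ranges() -> dict[str, tuple[float, float]]:
    """Uniform sampling boxes: [0.5x, 1.5x] of each baseline value."""
    return {
        name: (0.5 * value, 1.5 * value) for name, value in BASELINE.as_dict().items()
    }


def _check_ranges(ranges: dict[str, tuple[float, float]]) -> None:
    unknown = set(ranges) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameters in ranges: {sorted(unknown)}")
    missing = set(PARAM_NAMES) - set(ranges)
    if missing:
        raise ValueError(f"ranges missing parameters: {sorted(missing)}")
    for name, (lo, hi) in ranges.items():
        if lo < 0 or hi < lo:
            raise ValueError(f"range for {name} must satisfy 0 <= lo <= hi (got {lo}, {hi})")


def sample_parameters(
    seed: int,
    n: int,
    ranges: Optional[dict[str, tuple[float, float]]] = None,
    regime_filter: Optional[str] = None,
) -> ScenarioBatch:
    """Draw ``n`` valid game instances uniformly over per-parameter boxes.

    Each parameter is drawn independently and uniformly over its range
    (a zero-width range is a point mass). Draws failing parameter
    validation are rejected, as are — when ``regime_filter`` is set — draws
    whose stability regime differs from the requested one; rejection
    sampling is capped at ``MAX_DRAWS_PER_SCENARIO * n`` total draws.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1 (got {n!r})")
    if regime_filter is not None and regime_filter not in REGIME_LABELS:
        raise ValueError(f"unknown regime {regime_filter!r}; expected one of {REGIME_LABELS}")
    ranges = default_ranges() if ranges is None else dict(ranges)
    _check_ranges(ranges)

    rng = np.random.default_rng(seed)
    scenarios: list[GameParameters] = []
    regimes: list[str] = []
    budget = MAX_DRAWS_PER_SCENARIO * n
    draws = 0
    while len(scenarios) < n:
        if draws >= budget:
            raise SamplingError(
                f"exhausted {budget} draws while sampling regime "
                f"{regime_filter!r} over ranges {ranges}; the regime may be "
                "infeasible on this box"
            )
        draws += 1
        values = {
            name: float(rng.uniform(lo, hi)) if hi > lo else float(lo)
            for name, (lo, hi) in ((k, ranges[k]) for k in PARAM_NAMES)
        }
        candidate = GameParameters(**values)
        if not validate_parameters(candidate).ok:
            continue
        regime = regime_classification(candidate)
        if regime_filter is not None and regime != regime_filter:
            continue
        scenarios.append(candidate)
        regimes.append(regime)
    return ScenarioBatch(
        seed=seed,
        ranges={k: tuple(v) for k, v in ranges.items()},
        scenarios=tuple(scenarios),
        regimes=tuple(regimes),
    )


def regime_census(batch: ScenarioBatch) -> dict[str, int]:
    """Scenario counts per stability regime (all four labels, zero-filled)."""
    if len(batch) == 0:
        raise ValueError("empty batch")
    counts = {label: 0 for label in REGIME_LABELS}
    for regime in batch.regimes:
        counts[regime] += 1
    return counts


def save_batch(batch: ScenarioBatch, path: str | Path) -> None:
    """Write a batch as CSV (columns: seed, index, s..m, regime).

    Floats are written with 17 significant digits so a reload is
    bit-for-bit identical.
    """
    batch.to_frame().to_csv(path, index=False, float_format="%.17g")


def load_batch(path: str | Path) -> ScenarioBatch:
    """Reload a batch written by :func:`save_batch`.

    Sampling ranges are not stored in the CSV; the reloaded batch carries
    an empty ranges mapping.
    """
    # round_trip parsing: the default fast parser is not correctly rounded
    frame = pd.read_csv(path, float_precision="round_trip")
    scenarios = tuple(
        GameParameters(**{name: float(row[name]) for name in PARAM_NAMES})
        for _, row in frame.iterrows()
    )
    seeds = frame["seed"].unique()
    if len(seeds) != 1:
        raise ValueError(f"batch file mixes seeds: {seeds.tolist()}")
    return ScenarioBatch(
        seed=int(seeds[0]),
        ranges={},
        scenarios=scenarios,
        regimes=tuple(frame["regime"].tolist()),
    )
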
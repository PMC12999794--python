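"""One-parameter sensitivity sweeps and attractor-switch thresholds.

Two distinct notions of a "critical" parameter value coexist for this game
and are deliberately kept separate:

* the *operational* threshold — the value at which the attractor reached
  from a fixed initial state (default (0.5, 0.5)) switches, located here by
  bisection over full trajectory integrations; and
* the *structural* boundary — the value at which the set of evolutionarily
  stable corners changes (e.g. E1 loses stability when ``s - c1 - c2 - m``
  crosses 0).

The two differ whenever the game is bistable: an ESS can exist yet not be
reached from the chosen initial state. Sweeps report both the reached
attractor and the instance's ESS set side by side.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .game import GameParameters, StrategyState, PARAM_NAMES, validate_parameters
from .equilibria import enumerate_equilibria
from .dynamics import (
    DEFAULT_EPS,
    DEFAULT_HORIZON,
    NumericalError,
    integrate_trajectory,
)

__all__ = [
    "REGIME_LABELS",
    "SweepRow",
    "SweepResult",
    "ThresholdReport",
    "BracketError",
    "sweep_parameter",
    "find_threshold",
    "regime_classification",
]

REGIME_LABELS = ("E1-only", "E3-only", "bistable-E1-E3", "no-ESS")

DEFAULT_INITIAL = StrategyState(0.5, 0.5)


class BracketError(ValueError):
    """Both bracket endpoints reach the same attractor."""


@dataclass(frozen=True)
class SweepRow:
    """Outcome of one swept parameter value."""

    value: float
    valid: bool
    attractor: str = "none"
    phi_final: float = math.nan
    omega_final: float = math.nan
    t_converge: float = math.nan
    ess_set: tuple[str, ...] = ()
    non_hyperbolic: tuple[str, ...] = ()
    regime: str = ""
    note: str = ""


@dataclass(frozen=True)
class SweepResult:
    """A full one-parameter sweep with shared base parameters and initial state."""

    name: str
    base: GameParameters
    initial: StrategyState
    rows: tuple[SweepRow, ...] = field(default=())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": self.name,
                    "value": r.value,
                    "valid": r.valid,
                    "attractor": r.attractor,
                    "phi_final": r.phi_final,
                    "omega_final": r.omega_final,
                    "t_converge": r.t_converge,
                    "ess_set": "+".join(r.ess_set),
                    "non_hyperbolic": "+".join(r.non_hyperbolic),
                    "regime": r.regime,
                    "note": r.note,
                }
                for r in self.rows
            ]
        )


@dataclass(frozen=True)
class ThresholdReport:
    """A critical parameter value at which the reached attractor switches."""

    name: str
    lo: float
    hi: float
    critical: float
    achieved_resolution: float
    attractor_below: str
    attractor_above: str
    initial: StrategyState

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "lo": self.lo,
            "hi": self.hi,
            "critical": self.critical,
            "achieved_resolution": self.achieved_resolution,
            "attractor_below": self.attractor_below,
            "attractor_above": self.attractor_above,
            "initial_phi": self.initial.phi,
            "initial_omega": self.initial.omega,
        }


def regime_classification(params: GameParameters, strict: bool = True) -> str:
    """Stability regime from the ESS set.

    For strictly positive parameters mutual defection E3 is always an ESS
    (its corner eigenvalues are -c1 and -t2), so only ``E3-only`` and
    ``bistable-E1-E3`` actually occur there; the other two labels cover
    degenerate boundary instances.
    """
    ess = {
        r.label
        for r in enumerate_equilibria(params, strict=strict)
        if r.admissible and r.is_ess
    }
    if ess == {"E1", "E3"}:
        return "bistable-E1-E3"
    if ess == {"E3"}:
        return "E3-only"
    if ess == {"E1"}:
        return "E1-only"
    if not ess:
        return "no-ESS"
    raise AssertionError(f"unexpected ESS set {sorted(ess)}")  # structurally impossible


def sweep_parameter(
    base: GameParameters,
    name: str,
    values: Sequence[float],
    initial: StrategyState = DEFAULT_INITIAL,
    horizon: float = DEFAULT_HORIZON,
    eps: float = DEFAULT_EPS,
    strict: bool = True,
) -> SweepResult:
    """Integrate from ``initial`` for each substituted value of ``name``.

    Rows whose substituted instance fails validation are flagged invalid and
    the sweep continues. ``values`` must be strictly monotone so the result
    table reads as a well-ordered scan.
    """
    if name not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {name!r}; expected one of {PARAM_NAMES}")
    vals = [float(v) for v in values]
    if len(vals) > 1:
        diffs = [b - a for a, b in zip(vals, vals[1:])]
        if not (all(d > 0 for d in diffs) or all(d < 0 for d in diffs)):
            raise ValueError("swept values must be strictly monotone")

    rows: list[SweepRow] = []
    for value in vals:
        instance = base.replace(**{name: value})
        report = validate_parameters(instance, strict=strict)
        if not report.ok:
            rows.append(SweepRow(value=value, valid=False, note="; ".join(report.violations)))
            continue
        equilibria = enumerate_equilibria(instance, strict=strict)
        ess = tuple(r.label for r in equilibria if r.admissible and r.is_ess)
        nonhyp = tuple(
            r.label for r in equilibria if r.admissible and r.classification == "non-hyperbolic"
        )
        try:
            traj = integrate_trajectory(
                instance, initial, horizon=horizon, eps=eps, strict=strict
            )
        except NumericalError as err:
            rows.append(
                SweepRow(
                    value=value,
                    valid=True,
                    ess_set=ess,
                    non_hyperbolic=nonhyp,
                    regime=regime_classification(instance, strict=strict),
                    note=f"integration failed: {err}",
                )
            )
            continue
        rows.append(
            SweepRow(
                value=value,
                valid=True,
                attractor=traj.attractor_label,
                phi_final=traj.final_state.phi,
                omega_final=traj.final_state.omega,
                t_converge=traj.converge_time,
                ess_set=ess,
                non_hyperbolic=nonhyp,
                regime=regime_classification(instance, strict=strict),
            )
        )
    return SweepResult(name=name, base=base, initial=initial, rows=tuple(rows))


def _attractor_at(
    base: GameParameters,
    name: str,
    value: float,
    initial: StrategyState,
    horizon: float,
    eps: float,
    strict: bool,
) -> str:
    instance = base.replace(**{name: value})
    return integrate_trajectory(
        instance, initial, horizon=horizon, eps=eps, strict=strict
    ).attractor_label


def find_threshold(
    base: GameParameters,
    name: str,
    lo: float,
    hi: float,
    resolution: float = 1.0,
    initial: StrategyState = DEFAULT_INITIAL,
    horizon: float = DEFAULT_HORIZON,
    eps: float = DEFAULT_EPS,
    prescan: int = 8,
    strict: bool = True,
) -> ThresholdReport:
    """Bisection for the parameter value where the reached attractor switches.

    Requires the attractors at ``lo`` and ``hi`` to differ; bisects until the
    bracketing interval is at most ``resolution`` and reports the midpoint.
    A coarse pre-scan warns when the bracket appears to contain more than one
    switch (bisection then localises only one of them).
    """
    if not resolution > 0:
        raise ValueError(f"resolution must be > 0 (got {resolution!r})")
    if not lo < hi:
        raise ValueError(f"need lo < hi (got {lo!r}, {hi!r})")

    def attractor(v: float) -> str:
        return _attractor_at(base, name, v, initial, horizon, eps, strict)

    a_lo = attractor(lo)
    a_hi = attractor(hi)
    if a_lo == a_hi:
        raise BracketError(
            f"attractor is {a_lo!r} at both {name}={lo} and {name}={hi}; "
            "widen the bracket until the endpoints reach different attractors"
        )

    if prescan >= 2:
        grid = [lo + (hi - lo) * k / (prescan - 1) for k in range(prescan)]
        scan = [attractor(v) for v in grid]
        switches = sum(1 for a, b in zip(scan, scan[1:]) if a != b)
        if switches > 1:
            warnings.warn(
                f"{switches} attractor switches detected in [{lo}, {hi}] for {name}; "
                "bisection localises only one",
                stacklevel=2,
            )

    left, right = lo, hi
    while right - left > resolution:
        mid = 0.5 * (left + right)
        if attractor(mid) == a_lo:
            left = mid
        else:
            right = mid
    return ThresholdReport(
        name=name,
        lo=lo,
        hi=hi,
        critical=0.5 * (left + right),
        achieved_resolution=right - left,
        attractor_below=a_lo,
        attractor_above=a_hi,
        initial=initial,
    )
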
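"""Two-party evolutionary game of joint expired-drug recycling.

The model couples two populations — drugstores, which decide whether to run
an expired-drug recycling programme, and residents, which decide whether to
participate in it. Each population is characterised by the fraction playing
the cooperative strategy: ``phi`` for drugstores ("drugs recycling") and
``omega`` for residents ("participating in recycling").

Six nonnegative scalars parameterise one game instance:

==========  =============================================================
``s``       socioeconomic performance a drugstore gains from running the
            programme (reputation, footfall, extra sales)
``c1``      promotional cost the drugstore pays to inform residents
``c2``      recycling cost (manpower, storage, handling)
``t1``      resident time loss when both sides cooperate
``t2``      resident time loss when the resident shows up but the
            drugstore does not recycle
``m``       reward handed to a participating resident (vouchers, small
            gifts); a cost to the drugstore, a gain to the resident
==========  =============================================================

All six are dimensionless "utility units" (yuan-equivalent). The payoff
bimatrix of the stage game and the resulting replicator dynamics

    dphi/dt   = phi (1 - phi) [ omega (s - c2 - m) - c1 ]
    domega/dt = omega (1 - omega) [ phi (m - t1 + t2) - t2 ]

live in this module. The brackets are each party's payoff advantage of the
cooperative strategy over abstaining, given the opponent's current mix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal

__all__ = [
    "PARAM_NAMES",
    "GameParameters",
    "StrategyState",
    "PayoffCell",
    "PayoffMatrix",
    "ExpectedUtilities",
    "Velocity",
    "ValidationReport",
    "ParameterError",
    "DomainError",
    "build_payoff_matrix",
    "expected_utilities",
    "replicator_field",
    "validate_parameters",
    "require_valid",
    "validate_state",
]

PARAM_NAMES: tuple[str, ...] = ("s", "c1", "c2", "t1", "t2", "m")

#: absolute tolerance when checking that a state lies in the unit square;
#: absorbs floating-point drift from adaptive integrators
STATE_TOL = 1e-12

Party = Literal["drugstore", "resident"]


class ParameterError(ValueError):
    """A game-parameter invariant is violated."""


class DomainError(ValueError):
    """A strategy state lies outside the closed unit square."""


@dataclass(frozen=True)
class GameParameters:
    """The six payoff/cost scalars defining one game instance."""

    s: float
    c1: float
    c2: float
    t1: float
    t2: float
    m: float

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    def replace(self, **changes: float) -> "GameParameters":
        return replace(self, **changes)

    def scaled(self, k: float) -> "GameParameters":
        """All six parameters multiplied by ``k`` (a pure time rescaling)."""
        return GameParameters(**{n: k * v for n, v in self.as_dict().items()})

    # The two payoff-advantage brackets of the replicator system. They are
    # used throughout: the vector field, the Jacobian and the interior
    # equilibrium are all expressed in terms of them.
    def drugstore_gain(self, omega: float) -> float:
        """Drugstore's payoff advantage of recycling at resident mix ``omega``."""
        return omega * (self.s - self.c2 - self.m) - self.c1

    def resident_gain(self, phi: float) -> float:
        """Resident's payoff advantage of participating at drugstore mix ``phi``."""
        return phi * (self.m - self.t1 + self.t2) - self.t2


@dataclass(frozen=True)
class StrategyState:
    """Population strategy mix: P(drugstore recycles), P(resident participates)."""

    phi: float
    omega: float

    def as_tuple(self) -> tuple[float, float]:
        return (self.phi, self.omega)

    def clamped(self) -> "StrategyState":
        return StrategyState(min(max(self.phi, 0.0), 1.0), min(max(self.omega, 0.0), 1.0))

    def distance_to(self, other: "StrategyState") -> float:
        return math.hypot(self.phi - other.phi, self.omega - other.omega)


@dataclass(frozen=True)
class PayoffCell:
    """Payoff pair for one action profile (resident first, drugstore second)."""

    resident: float
    drugstore: float


@dataclass(frozen=True)
class PayoffMatrix:
    """The 2x2 bimatrix of the stage game.

    Cells are indexed by (drugstore recycles?, resident participates?).
    """

    recycle_participate: PayoffCell
    recycle_abstain: PayoffCell
    norecycle_participate: PayoffCell
    norecycle_abstain: PayoffCell

    def cell(self, drugstore_recycles: bool, resident_participates: bool) -> PayoffCell:
        if drugstore_recycles:
            return self.recycle_participate if resident_participates else self.recycle_abstain
        return self.norecycle_participate if resident_participates else self.norecycle_abstain

    def cells(self) -> Iterator[tuple[bool, bool, PayoffCell]]:
        for d in (True, False):
            for r in (True, False):
                yield d, r, self.cell(d, r)


@dataclass(frozen=True)
class ExpectedUtilities:
    """Expected utilities of one party at a given population state."""

    party: Party
    u_play: float
    u_abstain: float
    u_mean: float


@dataclass(frozen=True)
class Velocity:
    """The replicator vector field (dphi/dt, domega/dt) at one state."""

    dphi_dt: float
    domega_dt: float

    def as_tuple(self) -> tuple[float, float]:
        return (self.dphi_dt, self.domega_dt)

    @property
    def speed(self) -> float:
        return math.hypot(self.dphi_dt, self.domega_dt)


@dataclass(frozen=True)
class ValidationReport:
    """List of violated parameter invariants; empty iff the instance is valid."""

    violations: tuple[str, ...] = field(default=())

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_parameters(params: GameParameters, strict: bool = True) -> ValidationReport:
    """Check parameter invariants and return a report of violations.

    All six parameters must be finite and nonnegative. With ``strict=True``
    (the default) additionally ``c1 > 0`` and ``t2 > 0`` — the regime
    structure of the game (which corners can be evolutionarily stable) is
    derived under these strict inequalities. Pass ``strict=False`` to study
    the degenerate boundary cases.
    """
    violations: list[str] = []
    for name in PARAM_NAMES:
        value = getattr(params, name)
        if not math.isfinite(value):
            violations.append(f"{name} must be finite (got {value!r})")
        elif value < 0:
            violations.append(f"{name} must be >= 0 (got {value!r})")
    if strict:
        if math.isfinite(params.c1) and params.c1 <= 0:
            violations.append("c1 must be > 0 in standard regime")
        if math.isfinite(params.t2) and params.t2 <= 0:
            violations.append("t2 must be > 0 in standard regime")
    return ValidationReport(tuple(violations))


def require_valid(params: GameParameters, strict: bool = True) -> None:
    """Raise :class:`ParameterError` naming every violated bound."""
    report = validate_parameters(params, strict=strict)
    if not report.ok:
        raise ParameterError("; ".join(report.violations))


def validate_state(state: StrategyState, tol: float = STATE_TOL) -> None:
    """Raise :class:`DomainError` unless the state is in the closed unit square.

    An absolute tolerance ``tol`` absorbs integrator round-off just outside
    the square.
    """
    for name, value in (("phi", state.phi), ("omega", state.omega)):
        if not math.isfinite(value) or value < -tol or value > 1.0 + tol:
            raise DomainError(f"{name}={value!r} outside the closed unit square")


def build_payoff_matrix(params: GameParameters, strict: bool = True) -> PayoffMatrix:
    """The stage-game bimatrix.

    Mutual cooperation pays the resident the reward net of time spent,
    ``m - t1``, and pays the drugstore its socioeconomic gain net of all
    programme costs, ``s - c1 - c2 - m``. A resident who shows up at a
    non-recycling drugstore loses ``t2``; a drugstore that promotes a
    programme nobody uses loses ``c1``; mutual abstention pays nothing.
    """
    require_valid(params, strict=strict)
    return PayoffMatrix(
        recycle_participate=PayoffCell(
            resident=params.m - params.t1,
            drugstore=params.s - params.c1 - params.c2 - params.m,
        ),
        recycle_abstain=PayoffCell(resident=0.0, drugstore=-params.c1),
        norecycle_participate=PayoffCell(resident=-params.t2, drugstore=0.0),
        norecycle_abstain=PayoffCell(resident=0.0, drugstore=0.0),
    )


def expected_utilities(
    params: GameParameters,
    state: StrategyState,
    party: Party,
    strict: bool = True,
) -> ExpectedUtilities:
    """Expected utilities of the focal party against the opponent's mix.

    The cooperative strategy's utility is the expectation of the party's
    bimatrix row (column) under the *opponent's* mixed strategy — for
    drugstores ``omega (s - c1 - c2 - m) + (1 - omega)(-c1)``, which
    simplifies to ``omega (s - c2 - m) - c1``; for residents
    ``phi (m - t1) + (1 - phi)(-t2)``. Abstaining always yields 0, and the
    population mean mixes the two with the focal party's own strategy
    probability.
    """
    require_valid(params, strict=strict)
    validate_state(state)
    if party == "drugstore":
        u_play = params.drugstore_gain(state.omega)
        u_mean = state.phi * u_play
    elif party == "resident":
        # phi(m-t1) + (1-phi)(-t2) rearranged
        u_play = params.resident_gain(state.phi)
        u_mean = state.omega * u_play
    else:
        raise ValueError(f"unknown party {party!r}")
    return ExpectedUtilities(party=party, u_play=u_play, u_abstain=0.0, u_mean=u_mean)


def replicator_field(
    params: GameParameters, state: StrategyState, strict: bool = True
) -> Velocity:
    """The replicator vector field at ``state``.

    Each strategy share grows at a rate proportional to its payoff advantage
    over the population average; the four corners of the unit square are
    always fixed points because the logistic factors vanish there.
    """
    require_valid(params, strict=strict)
    validate_state(state)
    phi, omega = state.phi, state.omega
    return Velocity(
        dphi_dt=phi * (1.0 - phi) * params.drugstore_gain(omega),
        domega_dt=omega * (1.0 - omega) * params.resident_gain(phi),
    )


def field_rhs(params: GameParameters):
    """Unvalidated right-hand side ``f(t, y)`` for ODE integrators."""
    s_c2_m = params.s - params.c2 - params.m
    m_t1_t2 = params.m - params.t1 + params.t2
    c1, t2 = params.c1, params.t2

    def rhs(t, y):
        phi, omega = y
        return (
            phi * (1.0 - phi) * (omega * s_c2_m - c1),
            omega * (1.0 - omega) * (phi * m_t1_t2 - t2),
        )

    return rhs
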
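"""Equilibrium enumeration and local stability of the replicator system.

The replicator dynamics of the recycling game always fix the four corners
of the unit square:

    E1 = (1, 1)  full cooperation          E2 = (0, 1)  residents only
    E3 = (0, 0)  full defection            E4 = (1, 0)  drugstores only

and, when both payoff-advantage brackets can vanish inside the square, a
mixed interior point

    E5 = ( t2 / (m - t1 + t2),  c1 / (s - c2 - m) )

at which each party is indifferent between its two actions.

Stability is classified by Lyapunov's indirect method: the eigenvalues of
the Jacobian of the vector field at the fixed point. A corner with both
eigenvalues strictly negative is an evolutionarily stable strategy (ESS) of
the game. At the corners the Jacobian is diagonal, so the eigenvalues are
closed forms in the parameters:

    E1: -(s - c1 - c2 - m), -(m - t1)       E2: s - c1 - c2 - m,  t2
    E3: -c1, -t2                            E4: c1,  m - t1

Consequences for strictly positive ``c1`` and ``t2``: E3 is *always* an
ESS (mutual defection is self-reinforcing), E2 and E4 are never ESS, and E1
is an ESS exactly when ``s - c1 - c2 - m > 0`` and ``m > t1``. An admissible
interior E5 always has zero trace and non-positive determinant, hence is a
saddle (or non-hyperbolic), never an attractor.

The closed-form determinant/trace "stability conditions" circulating for
this game contain sign slips for E2 and E5; this module evaluates those
printed conditions verbatim for cross-reference, but the verdict it reports
is always the eigenvalue one.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, replace
from typing import Optional

import pandas as pd

from .game import (
    DomainError,
    GameParameters,
    StrategyState,
    replicator_field,
    require_valid,
    validate_state,
)

__all__ = [
    "CORNER_LABELS",
    "JacobianMatrix",
    "EquilibriumReport",
    "CornerConditions",
    "jacobian_at",
    "interior_equilibrium",
    "enumerate_equilibria",
    "classify_equilibrium",
    "symbolic_stability_conditions",
    "ess_set",
    "equilibria_to_frame",
]

CORNER_LABELS = ("E1", "E2", "E3", "E4")

CORNER_STATES: dict[str, StrategyState] = {
    "E1": StrategyState(1.0, 1.0),
    "E2": StrategyState(0.0, 1.0),
    "E3": StrategyState(0.0, 0.0),
    "E4": StrategyState(1.0, 0.0),
}

#: |Re(lambda)| below this is treated as zero: the point sits on a
#: bifurcation boundary and linearisation cannot decide stability
NONHYPERBOLIC_TOL = 1e-9

#: margin for "strictly inside (0,1)" when testing E5 admissibility
E5_MARGIN = 1e-12

#: residual bound under which a state is accepted as a fixed point
EQUILIBRIUM_RESIDUAL_TOL = 1e-9


@dataclass(frozen=True)
class JacobianMatrix:
    """Jacobian of the replicator field at one state, with its invariants."""

    j11: float
    j12: float
    j21: float
    j22: float

    @property
    def det(self) -> float:
        return self.j11 * self.j22 - self.j12 * self.j21

    @property
    def trace(self) -> float:
        return self.j11 + self.j22

    @property
    def eigenvalues(self) -> tuple[complex, complex]:
        """Roots of lambda^2 - trace*lambda + det, via the quadratic formula."""
        tr, det = self.trace, self.det
        disc = cmath.sqrt(complex(tr * tr - 4.0 * det))
        return ((tr - disc) / 2.0, (tr + disc) / 2.0)


@dataclass(frozen=True)
class EquilibriumReport:
    """One equilibrium point with its linearisation and stability verdict."""

    label: str
    coordinates: StrategyState
    admissible: bool
    jacobian: Optional[JacobianMatrix] = None
    classification: Optional[str] = None
    table2_condition_met: Optional[bool] = None

    @property
    def is_ess(self) -> bool:
        return self.classification == "ESS"


@dataclass(frozen=True)
class CornerConditions:
    """Printed closed-form stability condition vs. the eigenvalue one."""

    label: str
    printed: bool
    eigenvalue: bool
    agree: bool


def jacobian_at(
    params: GameParameters, state: StrategyState, strict: bool = True
) -> JacobianMatrix:
    """Closed-form Jacobian of the replicator field at ``state``."""
    require_valid(params, strict=strict)
    validate_state(state)
    phi, omega = state.phi, state.omega
    s_c2_m = params.s - params.c2 - params.m
    m_t1_t2 = params.m - params.t1 + params.t2
    return JacobianMatrix(
        j11=(1.0 - 2.0 * phi) * params.drugstore_gain(omega),
        j12=phi * (1.0 - phi) * s_c2_m,
        j21=omega * (1.0 - omega) * m_t1_t2,
        j22=(1.0 - 2.0 * omega) * params.resident_gain(phi),
    )


def interior_equilibrium(params: GameParameters) -> Optional[StrategyState]:
    """The mixed fixed point E5, or ``None`` when a denominator vanishes.

    The returned state may lie outside the unit square; admissibility is
    judged by :func:`enumerate_equilibria`.
    """
    d_res = params.m - params.t1 + params.t2  # resident bracket slope
    d_drug = params.s - params.c2 - params.m  # drugstore bracket slope
    if d_res == 0.0 or d_drug == 0.0:
        return None
    return StrategyState(phi=params.t2 / d_res, omega=params.c1 / d_drug)


def _classification(jac: JacobianMatrix) -> str:
    res = [ev.real for ev in jac.eigenvalues]
    if any(abs(r) < NONHYPERBOLIC_TOL for r in res):
        return "non-hyperbolic"
    if all(r < 0 for r in res):
        return "ESS"
    if all(r > 0 for r in res):
        return "source"
    return "saddle"


def _printed_condition(label: str, p: GameParameters) -> bool:
    """The corner's closed-form Det/Tr stability condition as commonly printed.

    Evaluated verbatim for cross-reference; the E2 trace condition omits the
    reward term, so it can disagree with the eigenvalue verdict.
    """
    net = p.s - p.c1 - p.c2 - p.m
    if label == "E1":
        return net * (p.m - p.t1) > 0 and (p.t1 - p.m - p.s + p.c1 + p.c2) < 0
    if label == "E2":
        return net * p.t2 > 0 and (p.s + p.t2 - p.c2 - p.c1) < 0
    if label == "E3":
        return p.t2 - p.c1 < 0
    if label == "E4":
        return p.m > p.t1 and (p.m + p.c1 - p.t1) < 0
    raise ValueError(f"no printed condition for {label!r}")


def _eigen_condition(label: str, p: GameParameters) -> bool:
    """Corner asymptotic stability from the diagonal Jacobian eigenvalues."""
    net = p.s - p.c1 - p.c2 - p.m
    eigs = {
        "E1": (-net, -(p.m - p.t1)),
        "E2": (net, p.t2),
        "E3": (-p.c1, -p.t2),
        "E4": (p.c1, p.m - p.t1),
    }[label]
    return all(e < 0 for e in eigs)


def classify_equilibrium(
    params: GameParameters, point: EquilibriumReport, strict: bool = True
) -> EquilibriumReport:
    """Fill in the Jacobian and the Lyapunov (eigenvalue) stability class.

    The point must actually be a fixed point of the replicator field
    (residual below ``EQUILIBRIUM_RESIDUAL_TOL``); corner points also get
    the printed closed-form condition recorded in ``table2_condition_met``.
    """
    require_valid(params, strict=strict)
    try:
        validate_state(point.coordinates)
    except DomainError:
        if point.admissible:
            raise
        return replace(point, jacobian=None, classification=None)
    residual = replicator_field(params, point.coordinates, strict=strict).speed
    if residual >= EQUILIBRIUM_RESIDUAL_TOL:
        raise ValueError(
            f"{point.label} at {point.coordinates} is not an equilibrium: "
            f"field residual {residual:.3e} >= {EQUILIBRIUM_RESIDUAL_TOL:.0e}"
        )
    jac = jacobian_at(params, point.coordinates, strict=strict)
    printed = _printed_condition(point.label, params) if point.label in CORNER_LABELS else None
    return replace(
        point,
        jacobian=jac,
        classification=_classification(jac),
        table2_condition_met=printed,
    )


def enumerate_equilibria(
    params: GameParameters, classify: bool = True, strict: bool = True
) -> list[EquilibriumReport]:
    """All fixed points of the replicator system for this instance.

    The four corners are always returned. E5 is appended whenever its
    defining denominators are nonzero; it is flagged ``admissible`` only if
    both coordinates lie strictly inside (0, 1) — an E5 on or outside the
    boundary duplicates (or lies beyond) a corner and does not count as a
    fifth equilibrium in the unit square. Inadmissible E5 points are
    reported unclassified.
    """
    require_valid(params, strict=strict)
    reports = [
        EquilibriumReport(label=label, coordinates=CORNER_STATES[label], admissible=True)
        for label in CORNER_LABELS
    ]
    e5 = interior_equilibrium(params)
    if e5 is not None:
        admissible = (
            E5_MARGIN < e5.phi < 1.0 - E5_MARGIN and E5_MARGIN < e5.omega < 1.0 - E5_MARGIN
        )
        reports.append(EquilibriumReport(label="E5", coordinates=e5, admissible=admissible))
    if classify:
        reports = [classify_equilibrium(params, r, strict=strict) for r in reports]
    return reports


def ess_set(params: GameParameters, strict: bool = True) -> tuple[str, ...]:
    """Labels of the asymptotically stable equilibria, in E1..E5 order."""
    return tuple(
        r.label for r in enumerate_equilibria(params, strict=strict) if r.admissible and r.is_ess
    )


def symbolic_stability_conditions(
    params: GameParameters, strict: bool = True
) -> dict[str, CornerConditions]:
    """Per-corner comparison of the printed condition with the eigenvalue one."""
    require_valid(params, strict=strict)
    out: dict[str, CornerConditions] = {}
    for label in CORNER_LABELS:
        printed = _printed_condition(label, params)
        eigen = _eigen_condition(label, params)
        out[label] = CornerConditions(
            label=label, printed=printed, eigenvalue=eigen, agree=printed == eigen
        )
    return out


def equilibria_to_frame(reports: list[EquilibriumReport]) -> pd.DataFrame:
    """Flat table of equilibrium reports (one row per point)."""
    rows = []
    for r in reports:
        jac = r.jacobian
        eigs = jac.eigenvalues if jac is not None else (complex("nan"), complex("nan"))
        rows.append(
            {
                "label": r.label,
                "phi": r.coordinates.phi,
                "omega": r.coordinates.omega,
                "admissible": r.admissible,
                "det": jac.det if jac is not None else math.nan,
                "trace": jac.trace if jac is not None else math.nan,
                "eig1_re": eigs[0].real,
                "eig1_im": eigs[0].imag,
                "eig2_re": eigs[1].real,
                "eig2_im": eigs[1].imag,
                "classification": r.classification,
                "table2_condition_met": r.table2_condition_met,
            }
        )
    return pd.DataFrame(rows)
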
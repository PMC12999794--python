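"""Numerical integration of the replicator dynamics and basin mapping.

Trajectories of the recycling game are solutions of a smooth planar ODE on
the closed unit square. The square is forward-invariant (the logistic
factors vanish on the boundary), so any numerical excursion outside it is
pure round-off; we integrate with an adaptive stiff-capable solver (LSODA),
clamp the state back onto the square after every accepted step, and stop
early once the field magnitude falls below a small threshold — at that
point the state is numerically pinned to an attractor.

Convergence is judged against the four corner fixed points only: an
admissible interior equilibrium is a saddle of this system and cannot be
reached from generic initial states.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import LSODA

from .game import (
    GameParameters,
    StrategyState,
    field_rhs,
    replicator_field,
    require_valid,
    validate_state,
)
from .equilibria import CORNER_LABELS, CORNER_STATES

__all__ = [
    "TrajectoryRecord",
    "BasinMap",
    "NumericalError",
    "integrate_trajectory",
    "detect_convergence",
    "basin_map",
]

logger = logging.getLogger(__name__)

#: default integration horizon in native evolutionary-time units; baseline
#: payoff magnitudes (~1e2) make convergence happen well before t = 1
DEFAULT_HORIZON = 10.0
#: tight enough that accepted steps stay within ~1e-13 of the unit square,
#: preserving forward invariance to well below the clamping tolerance
DEFAULT_RTOL = 1e-12
DEFAULT_ATOL = 1e-14
#: field magnitude under which the trajectory is declared stationary
SPEED_TOL = 1e-10
#: Euclidean distance within which a final state is matched to a corner
DEFAULT_EPS = 1e-4


class NumericalError(RuntimeError):
    """Integrator failure (e.g. step-size underflow); carries the last state."""

    def __init__(self, message: str, last_state: StrategyState, last_time: float):
        super().__init__(message)
        self.last_state = last_state
        self.last_time = last_time


@dataclass
class TrajectoryRecord:
    """A time-indexed solution path of the replicator system."""

    params: GameParameters
    times: np.ndarray
    states: np.ndarray  # shape (n, 2): columns phi, omega
    converged: bool
    attractor_label: str  # E1..E4 or "none"
    final_state: StrategyState
    boundary_excursion: float  # max distance outside [0,1]^2 before clamping
    converge_time: float  # time the field magnitude first dropped below SPEED_TOL (nan if never)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "phi": self.states[:, 0], "omega": self.states[:, 1]}
        )


@dataclass
class BasinMap:
    """Grid estimate of the basins of attraction on the unit square."""

    params: GameParameters
    resolution: int
    centers: np.ndarray  # the shared per-axis cell-center coordinates
    labels: np.ndarray  # shape (resolution, resolution), labels[i, j] for (phi=centers[i], omega=centers[j])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"phi0": self.centers[i], "omega0": self.centers[j], "label": self.labels[i, j]}
            for i in range(self.resolution)
            for j in range(self.resolution)
        ]
        return pd.DataFrame(rows)

    def label_counts(self) -> dict[str, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))


def detect_convergence(trajectory: TrajectoryRecord, eps: float = DEFAULT_EPS) -> str:
    """Label of the unique corner the trajectory ended at, or ``"none"``.

    The final state must lie within ``eps`` of exactly one corner, and the
    vector field there must be no faster than the corner's linearised decay
    allows at that distance (``eps`` times the corner's spectral scale) —
    proximity with an inconsistent field magnitude is a fly-by, not
    convergence. The guard is scaled by the Jacobian eigenvalues because
    the raw field magnitude near a corner is proportional to them: payoff
    units, not a dimensionless small number.
    """
    if trajectory.times.size == 0:
        raise ValueError("empty trajectory")
    from .equilibria import jacobian_at  # deferred: equilibria imports game only

    final = trajectory.final_state
    near = [
        label
        for label in CORNER_LABELS
        if final.distance_to(CORNER_STATES[label]) < eps
    ]
    if len(near) != 1:
        return "none"
    label = near[0]
    jac = jacobian_at(trajectory.params, CORNER_STATES[label], strict=False)
    spectral_scale = max(1.0, *(abs(ev) for ev in jac.eigenvalues))
    speed = replicator_field(trajectory.params, final, strict=False).speed
    if speed >= eps * spectral_scale:
        return "none"
    return label


def integrate_trajectory(
    params: GameParameters,
    initial: StrategyState,
    horizon: float = DEFAULT_HORIZON,
    rel_tol: float = DEFAULT_RTOL,
    abs_tol: float = DEFAULT_ATOL,
    eps: float = DEFAULT_EPS,
    strict: bool = True,
) -> TrajectoryRecord:
    """Integrate the replicator dynamics from ``initial`` up to ``horizon``.

    Uses LSODA with per-step clamping onto the unit square (tolerance-level
    round-off only) and early stopping once the field magnitude drops below
    ``SPEED_TOL``. Returns the full path of accepted steps; the convergence
    verdict is :func:`detect_convergence` at the end state.
    """
    require_valid(params, strict=strict)
    validate_state(initial)
    if not horizon > 0:
        raise ValueError(f"horizon must be > 0 (got {horizon!r})")

    rhs = field_rhs(params)
    y = np.clip(np.array(initial.as_tuple(), dtype=float), 0.0, 1.0)
    times = [0.0]
    states = [y.copy()]
    excursion = 0.0
    converge_time = math.nan

    def speed_of(arr: np.ndarray) -> float:
        return math.hypot(*rhs(0.0, arr))

    if speed_of(y) >= SPEED_TOL:
        solver = LSODA(rhs, 0.0, y, t_bound=horizon, rtol=rel_tol, atol=abs_tol)
        while solver.status == "running":
            solver.step()
            if solver.status == "failed":
                last = StrategyState(*np.clip(states[-1], 0.0, 1.0).tolist())
                raise NumericalError(
                    f"LSODA failed at t={solver.t:.6g}", last_state=last, last_time=times[-1]
                )
            y = solver.y.copy()
            excursion = max(excursion, float(np.max(y - 1.0)), float(np.max(-y)))
            # clamp round-off excursions back into the OPEN square: landing
            # exactly on a boundary would make that invariant edge absorbing
            # and could strand the trajectory on a saddle corner it should
            # only graze
            clipped = np.clip(y, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
            if not np.array_equal(clipped, y):
                # restart the solver from the clamped state so its internal
                # history never references a point outside the square
                y = clipped
                if solver.status == "running":
                    solver = LSODA(
                        rhs, solver.t, y, t_bound=horizon, rtol=rel_tol, atol=abs_tol
                    )
            times.append(solver.t)
            states.append(y.copy())
            if speed_of(y) < SPEED_TOL:
                converge_time = solver.t
                break
    else:
        converge_time = 0.0

    record = TrajectoryRecord(
        params=params,
        times=np.asarray(times),
        states=np.asarray(states),
        converged=False,
        attractor_label="none",
        final_state=StrategyState(*states[-1].tolist()),
        boundary_excursion=max(excursion, 0.0),
        converge_time=converge_time,
    )
    record.attractor_label = detect_convergence(record, eps=eps)
    record.converged = record.attractor_label != "none"
    return record


def basin_map(
    params: GameParameters,
    resolution: int = 21,
    horizon: float = DEFAULT_HORIZON,
    eps: float = DEFAULT_EPS,
    rel_tol: float = DEFAULT_RTOL,
    abs_tol: float = DEFAULT_ATOL,
    strict: bool = True,
) -> BasinMap:
    """Brute-force basin-of-attraction map on a ``resolution``-per-axis grid.

    Cell centers are at ``(i + 1) / (resolution + 1)``, strictly inside the
    square; each is integrated and labelled with the corner it reaches.
    Per-cell integrator failures are logged and labelled ``"none"``.
    """
    require_valid(params, strict=strict)
    if resolution < 3:
        raise ValueError(f"resolution must be >= 3 (got {resolution!r})")
    centers = np.arange(1, resolution + 1) / (resolution + 1)
    labels = np.empty((resolution, resolution), dtype=object)
    for i, phi0 in enumerate(centers):
        for j, omega0 in enumerate(centers):
            try:
                traj = integrate_trajectory(
                    params,
                    StrategyState(phi0, omega0),
                    horizon=horizon,
                    rel_tol=rel_tol,
                    abs_tol=abs_tol,
                    eps=eps,
                    strict=strict,
                )
                labels[i, j] = traj.attractor_label
            except NumericalError as err:
                logger.warning("basin cell (%g, %g): %s", phi0, omega0, err)
                labels[i, j] = "none"
    return BasinMap(params=params, resolution=resolution, centers=centers, labels=labels)
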
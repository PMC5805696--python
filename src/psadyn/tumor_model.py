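"""Three-compartment switched-linear model of PSA dynamics under androgen suppression.

The tumor is represented by three cell populations whose serum PSA
contributions (ng/ml) add up to the measured PSA: androgen-dependent (AD)
cells ``x1``, castration-resistant cells arising through reversible changes
``x2``, and castration-resistant cells arising through irreversible changes
such as mutations ``x3``.  Two linear systems govern the dynamics — one
while hormone therapy is applied, one while it is withheld — and a
treatment schedule switches between them:

* on-treatment: AD cells are suppressed and leak into both resistant
  compartments, so the daily multiplier matrix is lower triangular;
* off-treatment: reversibly resistant cells may revert to AD cells, giving
  a single super-diagonal coupling, while irreversibly resistant cells
  evolve in isolation.

Fitting and simulation work on the Euler discretisation with a time step of
exactly one day, so the canonical parameterisation is the pair of daily
multiplier matrices (:class:`DailyTransition`).  The equivalent
continuous-time rates (:class:`RateMatrices`) are related entry-wise by
``w_ij = d_ij`` off the diagonal and ``w_ii = d_ii - 1`` on it; the
rate form is what the patient-type classification operates on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "CellState",
    "DailyTransition",
    "RateMatrices",
    "ExplicitSchedule",
    "BlockSchedule",
    "ThresholdRule",
    "TreatmentSchedule",
    "Trajectory",
    "to_continuous",
    "to_daily",
    "step",
    "simulate",
    "resolve_schedule",
]


@dataclass(frozen=True)
class CellState:
    """PSA contributions (ng/ml) of the three tumor-cell compartments."""

    x1: float
    x2: float
    x3: float

    @property
    def psa(self) -> float:
        """Total serum PSA, the sum of the three contributions."""
        return self.x1 + self.x2 + self.x3

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3], dtype=float)

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "CellState":
        a = np.asarray(arr, dtype=float)
        if a.shape != (3,):
            raise ValueError(f"cell state needs exactly 3 components, got shape {a.shape}")
        return cls(float(a[0]), float(a[1]), float(a[2]))


# (row, col) positions of the structurally nonzero entries
_ON_PATTERN = ((0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2))
_OFF_PATTERN = ((0, 0), (0, 1), (1, 1), (2, 2))


@dataclass(frozen=True)
class DailyTransition:
    """Daily multiplier matrices of the discretised on/off dynamics.

    The ten structurally nonzero entries are dimensionless per-day
    multipliers.  On-treatment the matrix is lower triangular; off-treatment
    the only off-diagonal entry sits at row 1, column 2 (reversion of
    reversibly resistant cells to AD cells).
    """

    d1_11: float
    d1_21: float
    d1_22: float
    d1_31: float
    d1_32: float
    d1_33: float
    d0_11: float
    d0_12: float
    d0_22: float
    d0_33: float

    def on_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.d1_11, 0.0, 0.0],
                [self.d1_21, self.d1_22, 0.0],
                [self.d1_31, self.d1_32, self.d1_33],
            ]
        )

    def off_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.d0_11, self.d0_12, 0.0],
                [0.0, self.d0_22, 0.0],
                [0.0, 0.0, self.d0_33],
            ]
        )

    def as_vector(self) -> np.ndarray:
        """The ten free entries, on-treatment first (row-major within each)."""
        return np.array(
            [
                self.d1_11, self.d1_21, self.d1_22, self.d1_31, self.d1_32,
                self.d1_33, self.d0_11, self.d0_12, self.d0_22, self.d0_33,
            ]
        )

    @classmethod
    def from_vector(cls, v: Sequence[float]) -> "DailyTransition":
        v = np.asarray(v, dtype=float)
        if v.shape != (10,):
            raise ValueError("expected 10 daily-transition entries")
        if not np.all(np.isfinite(v)):
            raise ValueError("daily-transition entries must be finite")
        return cls(*(float(x) for x in v))

    @classmethod
    def from_matrices(cls, on: np.ndarray, off: np.ndarray) -> "DailyTransition":
        on = np.asarray(on, dtype=float)
        off = np.asarray(off, dtype=float)
        return cls(
            on[0, 0], on[1, 0], on[1, 1], on[2, 0], on[2, 1], on[2, 2],
            off[0, 0], off[0, 1], off[1, 1], off[2, 2],
        )


@dataclass(frozen=True)
class RateMatrices:
    """Continuous-time growth/transition rates (per day) of the on/off systems.

    Shares the structural-zero pattern of :class:`DailyTransition` and
    round-trips exactly through :func:`to_daily` / :func:`to_continuous`.
    """

    w1_11: float
    w1_21: float
    w1_22: float
    w1_31: float
    w1_32: float
    w1_33: float
    w0_11: float
    w0_12: float
    w0_22: float
    w0_33: float

    def on_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.w1_11, 0.0, 0.0],
                [self.w1_21, self.w1_22, 0.0],
                [self.w1_31, self.w1_32, self.w1_33],
            ]
        )

    def off_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.w0_11, self.w0_12, 0.0],
                [0.0, self.w0_22, 0.0],
                [0.0, 0.0, self.w0_33],
            ]
        )

    def as_vector(self) -> np.ndarray:
        return np.array(
            [
                self.w1_11, self.w1_21, self.w1_22, self.w1_31, self.w1_32,
                self.w1_33, self.w0_11, self.w0_12, self.w0_22, self.w0_33,
            ]
        )

    @classmethod
    def from_vector(cls, v: Sequence[float]) -> "RateMatrices":
        v = np.asarray(v, dtype=float)
        if v.shape != (10,):
            raise ValueError("expected 10 rate entries")
        return cls(*(float(x) for x in v))


def to_continuous(d: DailyTransition) -> RateMatrices:
    """Convert daily multipliers to continuous rates.

    Off-diagonal entries are copied; each diagonal entry maps as
    ``w_ii = d_ii - 1``.
    """
    v = d.as_vector().copy()
    for i in (0, 2, 5, 6, 8, 9):  # diagonal positions in the 10-vector
        v[i] -= 1.0
    return RateMatrices.from_vector(v)


def to_daily(w: RateMatrices) -> DailyTransition:
    """Inverse of :func:`to_continuous`: ``d_ii = w_ii + 1``, off-diagonals copied."""
    v = w.as_vector().copy()
    for i in (0, 2, 5, 6, 8, 9):
        v[i] += 1.0
    return DailyTransition.from_vector(v)


# ---------------------------------------------------------------------------
# Treatment schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExplicitSchedule:
    """Binary on/off value per day index (0-based).

    The value at day ``t`` selects the multiplier advancing the state from
    day ``t`` to ``t + 1``.
    """

    on: tuple

    def __init__(self, on: Iterable[int]):
        object.__setattr__(self, "on", tuple(int(bool(v)) for v in on))

    def resolve(self, horizon: int) -> np.ndarray:
        if horizon > len(self.on):
            raise ValueError(
                f"explicit schedule covers {len(self.on)} days, horizon is {horizon}"
            )
        return np.asarray(self.on[:horizon], dtype=np.int8)


@dataclass(frozen=True)
class BlockSchedule:
    """On/off assignment per fixed-length block of days; last block may be cut."""

    block_days: int
    blocks: tuple

    def __init__(self, block_days: int, blocks: Iterable[int]):
        if block_days <= 0:
            raise ValueError("block length must be positive")
        object.__setattr__(self, "block_days", int(block_days))
        object.__setattr__(self, "blocks", tuple(int(bool(v)) for v in blocks))

    def resolve(self, horizon: int) -> np.ndarray:
        covered = self.block_days * len(self.blocks)
        if horizon > covered:
            raise ValueError(f"block schedule covers {covered} days, horizon is {horizon}")
        daily = np.repeat(np.asarray(self.blocks, dtype=np.int8), self.block_days)
        return daily[:horizon]


@dataclass(frozen=True)
class ThresholdRule:
    """PSA-threshold-triggered intermittent suppression.

    Therapy starts on.  It is stopped on the first day on which the current
    on-period has lasted at least ``min_on_days`` days *and* total PSA is
    below ``lower``; it is resumed on the first day total PSA reaches
    ``upper`` or more.  Defaults follow the conventional protocol:
    0.1 ng/ml lower threshold, 1 ng/ml restart threshold, 40-week
    (280-day) minimum on-period.
    """

    lower: float = 0.1
    upper: float = 1.0
    min_on_days: int = 280


TreatmentSchedule = Union[ExplicitSchedule, BlockSchedule, ThresholdRule]


def resolve_schedule(schedule: TreatmentSchedule, horizon: int) -> np.ndarray | None:
    """Daily binary vector over ``horizon`` days, or None for online threshold rules."""
    if isinstance(schedule, ThresholdRule):
        return None
    return schedule.resolve(horizon)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trajectory:
    """A simulated path: per-day states including day 0, PSA, and the resolved schedule.

    ``states`` has shape ``(horizon + 1, 3)``; ``on`` has length ``horizon``
    (day ``t``'s value governed the transition ``t -> t + 1``).
    """

    states: np.ndarray
    psa: np.ndarray
    on: np.ndarray

    @property
    def horizon(self) -> int:
        return len(self.states) - 1

    def state_at(self, day: int) -> CellState:
        return CellState.from_array(self.states[day])

    def to_frame(self):
        """Export as a DataFrame with columns day, x1, x2, x3, psa, on_treatment."""
        import pandas as pd

        on = np.append(self.on, -1) if self.horizon else np.array([-1])
        return pd.DataFrame(
            {
                "day": np.arange(self.horizon + 1),
                "x1": self.states[:, 0],
                "x2": self.states[:, 1],
                "x3": self.states[:, 2],
                "psa": self.psa,
                "on_treatment": on,
            }
        )


def step(state: CellState, d: DailyTransition, on: bool) -> CellState:
    """Advance the state by one day under the on- or off-treatment matrix."""
    m = d.on_matrix() if on else d.off_matrix()
    return CellState.from_array(m @ state.as_array())


def _as_state_array(x0) -> np.ndarray:
    if isinstance(x0, CellState):
        return x0.as_array()
    a = np.asarray(x0, dtype=float)
    if a.shape != (3,):
        raise ValueError("initial state must have 3 components")
    return a.copy()


def simulate(
    d: DailyTransition,
    x0,
    schedule: TreatmentSchedule,
    horizon: int,
) -> Trajectory:
    """Iterate the daily dynamics under a schedule for ``horizon`` days.

    Threshold rules are resolved online from the simulated PSA; explicit and
    block schedules are resolved up front.  Simulated PSA is never clipped:
    divergence is meaningful (it represents relapse).
    """
    horizon = int(horizon)
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    m_on = d.on_matrix()
    m_off = d.off_matrix()
    states = np.empty((horizon + 1, 3))
    states[0] = _as_state_array(x0)

    on_vec = np.empty(horizon, dtype=np.int8)
    resolved = resolve_schedule(schedule, horizon)
    if resolved is not None:
        on_vec[:] = resolved
        for t in range(horizon):
            states[t + 1] = (m_on if on_vec[t] else m_off) @ states[t]
    else:
        rule: ThresholdRule = schedule  # type: ignore[assignment]
        on = True
        days_in_on = 0
        for t in range(horizon):
            psa_t = states[t].sum()
            if on and days_in_on >= rule.min_on_days and psa_t < rule.lower:
                on = False
            elif not on and psa_t >= rule.upper:
                on = True
                days_in_on = 0
            on_vec[t] = 1 if on else 0
            states[t + 1] = (m_on if on else m_off) @ states[t]
            if on:
                days_in_on += 1
    return Trajectory(states=states, psa=states.sum(axis=1), on=on_vec)
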
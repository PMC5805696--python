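"""Treatment protocols and the robust schedule search.

Three concrete protocols are provided: continuous suppression (CAS,
all-on), the conventional threshold-triggered intermittent protocol
(therapy stopped once PSA falls below 0.1 ng/ml after at least 40 weeks on,
resumed at 1 ng/ml), and explicit block schedules where therapy is assigned
in fixed blocks of 24 weeks over a 3-year horizon.

The optimizer enumerates every block assignment (2^n candidates for n
blocks, the last block truncated to the horizon) and, for each, simulates
every accepted bootstrap member forward from its end-of-fitting-window
state, scoring the candidate by the *maximum* total PSA at the horizon
across members.  Minimising this worst case yields a schedule that is
robust to the estimation uncertainty captured by the ensemble; because the
search is exhaustive, the returned optimum is exact for the given ensemble
and horizon.  A mean-dynamics variant — averaging the ensemble first and
optimising that single system — is provided for comparison; it discards the
parameter uncertainty and is systematically more optimistic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .psa_fitting import BootstrapEnsemble, FitResult
from .tumor_model import (
    BlockSchedule,
    CellState,
    DailyTransition,
    ExplicitSchedule,
    ThresholdRule,
    Trajectory,
    TreatmentSchedule,
    resolve_schedule,
    simulate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScheduleSearchConfig",
    "OptimizedSchedule",
    "cas",
    "conventional_ias",
    "worst_case_objective",
    "optimize_schedule",
    "optimize_mean_dynamics",
    "time_under_threshold",
    "accepted_members",
]


@dataclass(frozen=True)
class ScheduleSearchConfig:
    """Horizon, block length, and thresholds of the schedule search.

    Defaults: 1080-day (36-month) horizon split into 168-day (24-week)
    blocks — seven blocks, the last truncated to 72 days, 128 candidate
    schedules; 100 ng/ml relapse threshold; 5 ng/ml end-of-fit acceptance
    filter for ensemble members.
    """

    horizon: int = 1080
    block_days: int = 168
    relapse_threshold: float = 100.0
    accept_threshold: float = 5.0
    max_blocks: int = 20

    def __post_init__(self):
        if self.horizon <= 0 or self.block_days <= 0:
            raise ValueError("horizon and block length must be positive")

    @property
    def n_blocks(self) -> int:
        return -(-self.horizon // self.block_days)


@dataclass(frozen=True)
class OptimizedSchedule:
    """Result of the exhaustive search: block assignment and worst-case PSA."""

    blocks: tuple
    block_days: int
    horizon: int
    worst_case_psa: float
    n_evaluated: int
    mean_dynamics: bool = False

    def schedule(self) -> BlockSchedule:
        return BlockSchedule(self.block_days, self.blocks)


def cas(d: DailyTransition, x0, horizon: int) -> Trajectory:
    """Continuous androgen suppression: simulate with the all-on schedule."""
    return simulate(d, x0, ExplicitSchedule(np.ones(horizon, dtype=np.int8)), horizon)


def conventional_ias(
    d: DailyTransition, x0, horizon: int, rule: ThresholdRule = ThresholdRule()
) -> Trajectory:
    """Threshold-triggered intermittent suppression (starts on-treatment)."""
    return simulate(d, x0, rule, horizon)


def accepted_members(
    ensemble: BootstrapEnsemble,
    config: Optional[ScheduleSearchConfig] = None,
    fallback: bool = True,
) -> Tuple[FitResult, ...]:
    """Members passing the end-of-fit error filter.

    When none passes and ``fallback`` is set, the single member with the
    smallest end-of-fit error is used instead (with a logged warning) so
    the patient is not silently dropped.
    """
    if ensemble.B == 0:
        raise ValueError("empty ensemble")
    members = ensemble.accepted_members()
    if members:
        return members
    if not fallback:
        return ()
    best = min(ensemble.members, key=lambda m: m.end_error)
    logger.warning(
        "patient %s: no ensemble member within the acceptance threshold; "
        "falling back to the best member (error %.2f ng/ml)",
        ensemble.patient_id,
        best.end_error,
    )
    return (best,)


def _member_arrays(members: Sequence[FitResult]):
    m_on = np.stack([m.d.on_matrix() for m in members])
    m_off = np.stack([m.d.off_matrix() for m in members])
    x = np.stack([m.end_state.as_array() for m in members])
    return m_on, m_off, x


def _propagate(
    members: Sequence[FitResult],
    schedule: TreatmentSchedule,
    horizon: int,
    track_max_crossing: Optional[float] = None,
):
    """Batched day-stepping of all members from their end-of-window states.

    Returns (final PSA per member, first day max-PSA >= threshold or None).
    Threshold rules are resolved online per member from that member's own
    simulated PSA.
    """
    m_on, m_off, x = _member_arrays(members)
    n = len(members)
    resolved = resolve_schedule(schedule, horizon)
    crossing = None
    if resolved is None:
        rule: ThresholdRule = schedule  # type: ignore[assignment]
        on = np.ones(n, dtype=bool)
        days_in_on = np.zeros(n, dtype=int)
        for t in range(horizon):
            psa_t = x.sum(axis=1)
            if track_max_crossing is not None and crossing is None and psa_t.max() >= track_max_crossing:
                crossing = t
            stop = on & (days_in_on >= rule.min_on_days) & (psa_t < rule.lower)
            resume = ~on & (psa_t >= rule.upper)
            on = (on & ~stop) | resume
            days_in_on = np.where(resume, 0, days_in_on)
            mats = np.where(on[:, None, None], m_on, m_off)
            x = np.einsum("sij,sj->si", mats, x)
            days_in_on = np.where(on, days_in_on + 1, days_in_on)
    else:
        for t in range(horizon):
            if track_max_crossing is not None and crossing is None and x.sum(axis=1).max() >= track_max_crossing:
                crossing = t
            x = np.einsum("sij,sj->si", m_on if resolved[t] else m_off, x)
    final_psa = x.sum(axis=1)
    if track_max_crossing is not None and crossing is None and final_psa.max() >= track_max_crossing:
        crossing = horizon
    return final_psa, crossing


def worst_case_objective(
    schedule: TreatmentSchedule,
    ensemble: BootstrapEnsemble,
    config: Optional[ScheduleSearchConfig] = None,
) -> float:
    """Maximum total PSA at the horizon across accepted members under a schedule.

    Each accepted member is simulated forward from its own
    end-of-fitting-window state; the worst (largest) horizon PSA is the
    robust objective the schedule search minimises.
    """
    config = config or ScheduleSearchConfig()
    members = accepted_members(ensemble, config)
    final_psa, _ = _propagate(members, schedule, config.horizon)
    return float(final_psa.max())


def _enumerate_blocks(n_blocks: int):
    return itertools.product((0, 1), repeat=n_blocks)


def optimize_schedule(
    ensemble: BootstrapEnsemble,
    config: Optional[ScheduleSearchConfig] = None,
) -> OptimizedSchedule:
    """Exhaustive robust schedule search over all 2^n block assignments.

    Ties in the worst-case objective break toward the schedule with more
    on-blocks, then toward the lexicographically smallest block tuple.
    Raises for more than ``max_blocks`` blocks to guard against an
    accidental exponential blow-up.
    """
    config = config or ScheduleSearchConfig()
    n = config.n_blocks
    if n > config.max_blocks:
        raise ValueError(f"{n} blocks would need 2^{n} evaluations; raise max_blocks to allow")
    members = accepted_members(ensemble, config)

    best = None
    n_eval = 0
    for blocks in _enumerate_blocks(n):
        sched = BlockSchedule(config.block_days, blocks)
        final_psa, _ = _propagate(members, sched, config.horizon)
        objective = float(final_psa.max())
        n_eval += 1
        key = (objective, -sum(blocks), blocks)
        if best is None or key < best[0]:
            best = (key, blocks, objective)
    _, blocks, objective = best
    return OptimizedSchedule(
        blocks=blocks,
        block_days=config.block_days,
        horizon=config.horizon,
        worst_case_psa=objective,
        n_evaluated=n_eval,
    )


def _mean_member(members: Sequence[FitResult]) -> FitResult:
    d_mean = DailyTransition.from_vector(
        np.mean([m.d.as_vector() for m in members], axis=0)
    )
    end_mean = CellState.from_array(
        np.mean([m.end_state.as_array() for m in members], axis=0)
    )
    ref = members[0]
    return FitResult(
        d=d_mean,
        x0=ref.x0,
        cost=float(np.mean([m.cost for m in members])),
        end_error=float(np.mean([m.end_error for m in members])),
        end_state=end_mean,
        replicate=-1,
        seed=ref.seed,
        converged=all(m.converged for m in members),
    )


def optimize_mean_dynamics(
    ensemble: BootstrapEnsemble,
    config: Optional[ScheduleSearchConfig] = None,
) -> OptimizedSchedule:
    """Schedule search against the ensemble-averaged system.

    Averages the daily multipliers and end-of-window states over accepted
    members and optimises that single system (its own horizon PSA, no
    worst case).  Ignoring the ensemble spread this way is known to be
    over-optimistic; the op exists for that comparison.
    """
    config = config or ScheduleSearchConfig()
    members = accepted_members(ensemble, config)
    mean_ensemble = BootstrapEnsemble(
        patient_id=ensemble.patient_id,
        members=(_mean_member(members),),
        accepted=(True,),
        accept_threshold=float("inf"),
    )
    result = optimize_schedule(mean_ensemble, config)
    return OptimizedSchedule(
        blocks=result.blocks,
        block_days=result.block_days,
        horizon=result.horizon,
        worst_case_psa=result.worst_case_psa,
        n_evaluated=result.n_evaluated,
        mean_dynamics=True,
    )


def time_under_threshold(
    ensemble: BootstrapEnsemble,
    schedule: TreatmentSchedule,
    config: Optional[ScheduleSearchConfig] = None,
) -> Tuple[int, bool]:
    """First day the maximum PSA across accepted members reaches the relapse threshold.

    Returns ``(day, censored)``: the day (0-based from the end of the
    fitting window) on which the ensemble's maximum total PSA first reaches
    the relapse threshold (default 100 ng/ml), or ``(horizon, True)`` if it
    never does within the horizon.
    """
    config = config or ScheduleSearchConfig()
    members = accepted_members(ensemble, config)
    _, crossing = _propagate(
        members, schedule, config.horizon, track_max_crossing=config.relapse_threshold
    )
    if crossing is None:
        return config.horizon, True
    return int(crossing), False
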
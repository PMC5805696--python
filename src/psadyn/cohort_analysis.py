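"""Cohort-level statistics: cross-tabulations, Fisher's exact test, and
time-under-threshold curves.

Patient types are cross-tabulated against clinical status, Gleason-like
grade, or a second classification method, with integer row percentages
(round half up) as in the published tables.  Association in a collapsed
2x2 table is quantified by Fisher's exact test: the odds ratio is the
conditional maximum-likelihood estimate under the non-central
hypergeometric model and the two-sided p-value sums the probabilities of
outcomes no more likely than the observed one — the conventions of R's
``fisher.test``, delegated to scipy.

Strategy comparisons use per-patient threshold-crossing times: for each
patient the first day (after the fitting window) on which the maximum PSA
across accepted bootstrap members reaches 100 ng/ml, censored at the
scheduling horizon.  The resulting step curves are compared with a
log-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scheduling import ScheduleSearchConfig, time_under_threshold

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "FisherResult",
    "ThresholdSurvivalCurve",
    "CurveComparison",
    "build_contingency",
    "fisher_exact_2x2",
    "threshold_survival",
    "compare_curves",
    "concordance_table",
]


def round_half_up(x) -> np.ndarray:
    """Integer rounding with halves away from zero, as in the printed tables."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-tabulated counts with rendered row percentages."""

    counts: pd.DataFrame

    def row_percent(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts.div(totals.replace(0, np.nan), axis=0)
        return pct.fillna(0.0).apply(round_half_up)

    def with_totals(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["Total"] = out.sum(axis=1)
        out.loc["Total"] = out.sum(axis=0)
        return out

    def to_json_dict(self) -> dict:
        return {
            "counts": {str(r): [int(v) for v in row] for r, row in self.counts.iterrows()},
            "columns": [str(c) for c in self.counts.columns],
            "row_percent": {
                str(r): [int(v) for v in row] for r, row in self.row_percent().iterrows()
            },
        }


def build_contingency(
    rows: Sequence,
    cols: Sequence,
    row_labels: Optional[Sequence] = None,
    col_labels: Optional[Sequence] = None,
) -> ContingencyTable:
    """Cross-tabulate per-patient row labels (e.g. modal types) against column labels."""
    rows = list(rows)
    cols = list(cols)
    if len(rows) != len(cols):
        raise ValueError("rows and cols must have equal length")
    row_labels = list(row_labels) if row_labels is not None else sorted(set(rows))
    col_labels = list(col_labels) if col_labels is not None else sorted(set(cols))
    counts = pd.DataFrame(0, index=row_labels, columns=col_labels, dtype=int)
    for r, c in zip(rows, cols):
        counts.loc[r, c] += 1
    return ContingencyTable(counts=counts)


@dataclass(frozen=True)
class FisherResult:
    """Conditional-MLE odds ratio and two-sided exact p-value for a 2x2 table."""

    odds_ratio: float
    p_value: float
    defined: bool  # False when a zero marginal leaves the odds ratio undefined


def fisher_exact_2x2(table) -> FisherResult:
    """Fisher's exact test on a 2x2 count table.

    The odds ratio is the conditional MLE under the non-central
    hypergeometric model (infinite when a cross cell is empty); a zero row
    or column marginal yields an undefined-odds-ratio flag rather than an
    error, with p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("expected a 2x2 table of non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return FisherResult(odds_ratio=float("nan"), p_value=1.0, defined=False)
    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    or_ = float(stats.contingency.odds_ratio(t, kind="conditional").statistic)
    return FisherResult(odds_ratio=or_, p_value=p, defined=bool(np.isfinite(or_)))


@dataclass(frozen=True)
class ThresholdSurvivalCurve:
    """Per-patient threshold-crossing times and the derived step curve.

    ``event_days[i]`` is patient i's first day with ensemble-maximum PSA at
    or above the relapse threshold; ``censored[i]`` marks patients whose
    ensemble stayed below it for the whole horizon.  The curve starts at 1,
    is non-increasing, and steps only at event times.
    """

    label: str
    event_days: np.ndarray
    censored: np.ndarray
    horizon: int

    def __post_init__(self):
        object.__setattr__(self, "event_days", np.asarray(self.event_days, dtype=int))
        object.__setattr__(self, "censored", np.asarray(self.censored, dtype=bool))

    @property
    def n(self) -> int:
        return len(self.event_days)

    def step_curve(self):
        """(times, fraction-still-under-threshold) arrays, starting at (0, 1)."""
        events = np.sort(self.event_days[~self.censored])
        times = [0]
        surv = [1.0]
        n = self.n
        for t in np.unique(events):
            times.append(int(t))
            surv.append(float(np.sum(self.event_days[~self.censored] > t) / n
                             + np.sum(self.censored) / n))
        return np.asarray(times), np.asarray(surv)

    def to_frame(self) -> pd.DataFrame:
        times, surv = self.step_curve()
        return pd.DataFrame({"day": times, "fraction_under_threshold": surv})


def threshold_survival(
    ensembles: Sequence,
    schedules,
    config: Optional[ScheduleSearchConfig] = None,
    label: str = "",
) -> ThresholdSurvivalCurve:
    """Threshold-crossing curve for a cohort under one strategy.

    ``schedules`` is either a single schedule applied to every patient (CAS
    or the conventional rule) or a mapping from patient id to that
    patient's schedule (the optimized case).  Patients whose ensembles hold
    no members at all are skipped with a logged warning.
    """
    config = config or ScheduleSearchConfig()
    days, cens = [], []
    for ens in ensembles:
        if ens.B == 0:
            logger.warning("patient %s: empty ensemble skipped", ens.patient_id)
            continue
        sched = schedules[ens.patient_id] if isinstance(schedules, dict) else schedules
        day, censored = time_under_threshold(ens, sched, config)
        days.append(day)
        cens.append(censored)
    return ThresholdSurvivalCurve(
        label=label,
        event_days=np.asarray(days, dtype=int),
        censored=np.asarray(cens, dtype=bool),
        horizon=config.horizon,
    )


@dataclass(frozen=True)
class CurveComparison:
    test: str
    statistic: float
    p_value: float
    reliable: bool  # False with fewer than 2 events in total


def compare_curves(a: ThresholdSurvivalCurve, b: ThresholdSurvivalCurve) -> CurveComparison:
    """Two-sided log-rank comparison of two threshold-crossing curves."""
    from lifelines.statistics import logrank_test

    n_events = int(np.sum(~a.censored) + np.sum(~b.censored))
    if n_events == 0:
        return CurveComparison(test="log-rank", statistic=0.0, p_value=1.0, reliable=False)
    res = logrank_test(
        a.event_days,
        b.event_days,
        event_observed_A=~a.censored,
        event_observed_B=~b.censored,
    )
    return CurveComparison(
        test="log-rank",
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        reliable=n_events >= 2,
    )


def concordance_table(types_a: Sequence, types_b: Sequence) -> ContingencyTable:
    """3x3 cross-tabulation of two classification methods over the same patients."""
    labels = ["type-i", "type-ii", "type-iii"]

    def norm(ts):
        return [t.label if hasattr(t, "label") else str(t) for t in ts]

    return build_contingency(norm(types_a), norm(types_b), labels, labels)
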
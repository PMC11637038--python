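"""Estimation of care-event rates and durations from censored work sampling.

The observational design watches one randomly chosen nurse at a time over
10-minute intervals.  Care events that straddle an interval boundary are
only partially observed: a segment whose true start precedes the window is
*left-censored* (its start is not seen), one whose end follows the window
is *right-censored*.  Because starts and ends are missed symmetrically,
the arithmetic mean of observed starts and observed ends is an unbiased
estimate of the number of care events intersecting the windows.

The per-cell estimator chain, per (shift, respiratory type):

1. events      = (n_starts + n_ends) / 2
2. per-nurse   = events / observed_minutes              (events per nurse-min)
3. unit-level  = per-nurse * avg_nurses_on_duty          (events per min)
4. per-infant  = unit-level / avg_patients_of_type       (the arrival rate)
5. duration    = observed_care_minutes / events          (mean minutes/event)

All chaining is done at full precision; rounding happens only when
printing (rates to 3 decimals, durations to 2).  Only ``direct`` care
segments contribute; indirect/administrative/other activities are carried
through I/O but excluded from every estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mix import RESPIRATORY_TYPES, SHIFT_LABELS, RateTable

__all__ = [
    "CareSegment",
    "ObservationInterval",
    "CellTally",
    "InestimableCellError",
    "tally",
    "estimate_event_count",
    "estimate_arrival_rate",
    "estimate_mean_duration",
    "estimate_rate_table",
]

CATEGORIES = ("direct", "indirect", "administrative", "other")


class InestimableCellError(ValueError):
    """A (shift, type) cell has observed care time but zero estimated events."""


@dataclass(frozen=True)
class CareSegment:
    """One observed stretch of care within an observation interval.

    ``start_min``/``end_min`` are minutes from the interval start.  The
    censoring flags mark whether the segment's true start/end fell outside
    the window (in which case the recorded endpoint is the window edge).
    """

    patient_type: str
    start_min: float
    end_min: float
    left_censored: bool = False
    right_censored: bool = False
    category: str = "direct"
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.patient_type not in RESPIRATORY_TYPES:
            raise ValueError(f"unknown respiratory type {self.patient_type!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown activity category {self.category!r}")
        if self.end_min < self.start_min:
            raise ValueError("segment must have end >= start")

    @property
    def duration(self) -> float:
        return self.end_min - self.start_min


@dataclass
class ObservationInterval:
    """One sampled nurse-observation window plus its unit context."""

    day: int
    shift: str
    nurse_id: str
    length_min: float
    segments: list[CareSegment] = field(default_factory=list)
    nurses_on_duty: float = 1.0
    patients: dict[str, float] = field(default_factory=dict)
    start_min: float = 0.0

    def __post_init__(self) -> None:
        if self.shift not in SHIFT_LABELS:
            raise ValueError(f"unknown shift {self.shift!r}")
        if self.length_min <= 0:
            raise ValueError("interval length must be positive")
        if self.nurses_on_duty < 1:
            raise ValueError("nurses_on_duty must be >= 1")
        self.validate_segments()

    def validate_segments(self) -> None:
        eps = 1e-9
        direct = []
        for seg in self.segments:
            if seg.start_min < -eps or seg.end_min > self.length_min + eps:
                raise ValueError(
                    f"segment [{seg.start_min}, {seg.end_min}] outside "
                    f"interval of length {self.length_min}"
                )
            if seg.category == "direct" and seg.duration > 0:
                direct.append(seg)
        # one nurse serves one care event at a time
        direct.sort(key=lambda s: s.start_min)
        for a, b in zip(direct, direct[1:]):
            if b.start_min < a.end_min - eps:
                raise ValueError(
                    "overlapping direct-care segments for one nurse are invalid"
                )


@dataclass
class CellTally:
    """Observed-quantity tallies for one (shift, respiratory type) cell.

    ``observed_minutes`` and ``avg_nurses`` are shift-level (shared by all
    four type cells of a shift); starts/ends/care minutes and the average
    patient count are type-specific.
    """

    n_starts: int = 0
    n_ends: int = 0
    observed_minutes: float = 0.0
    care_minutes: float = 0.0
    avg_nurses: float = 0.0
    avg_patients: float = 0.0


def tally(intervals: list[ObservationInterval]) -> dict[tuple[str, str], CellTally]:
    """Accumulate per-cell tallies over observation intervals.

    A start is counted iff the segment is not left-censored; an end iff not
    right-censored.  Zero-duration segments are dropped.  Observed minutes
    accumulate the full interval length per shift regardless of activity.
    Returns a tally for every (shift, type) combination of shifts that were
    observed at all.
    """
    if not intervals:
        raise ValueError("no observation intervals supplied")
    shift_minutes: dict[str, float] = {}
    shift_nurse_sum: dict[str, float] = {}
    shift_n_intervals: dict[str, int] = {}
    shift_patient_sum: dict[tuple[str, str], float] = {}
    cells: dict[tuple[str, str], CellTally] = {}

    for iv in intervals:
        iv.validate_segments()
        s = iv.shift
        shift_minutes[s] = shift_minutes.get(s, 0.0) + iv.length_min
        shift_nurse_sum[s] = shift_nurse_sum.get(s, 0.0) + iv.nurses_on_duty
        shift_n_intervals[s] = shift_n_intervals.get(s, 0) + 1
        for t in RESPIRATORY_TYPES:
            shift_patient_sum[(s, t)] = shift_patient_sum.get((s, t), 0.0) + float(
                iv.patients.get(t, 0.0)
            )
        for seg in iv.segments:
            if seg.category != "direct" or seg.duration == 0.0:
                continue
            cell = cells.setdefault((s, seg.patient_type), CellTally())
            if not seg.left_censored:
                cell.n_starts += 1
            if not seg.right_censored:
                cell.n_ends += 1
            cell.care_minutes += seg.duration

    for s, minutes in shift_minutes.items():
        n = shift_n_intervals[s]
        for t in RESPIRATORY_TYPES:
            cell = cells.setdefault((s, t), CellTally())
            cell.observed_minutes = minutes
            cell.avg_nurses = shift_nurse_sum[s] / n
            cell.avg_patients = shift_patient_sum[(s, t)] / n
    return cells


def estimate_event_count(n_starts: int, n_ends: int) -> float:
    """Unbiased event-count estimate: the mean of observed starts and ends."""
    if n_starts < 0 or n_ends < 0:
        raise ValueError("counts must be non-negative")
    return 0.5 * (n_starts + n_ends)


def estimate_arrival_rate(
    events: float,
    observed_minutes: float,
    avg_nurses: float,
    avg_patients_of_type: float,
) -> float:
    """Per-infant arrival rate (events per minute).

    events / observed_minutes gives the rate seen by one observed nurse;
    scaling by the average number of nurses on duty yields the unit-level
    rate, and dividing by the average number of patients of the type gives
    the per-infant rate.
    """
    if observed_minutes <= 0:
        raise ValueError("observed_minutes must be positive")
    if events == 0:
        return 0.0
    if avg_patients_of_type <= 0:
        raise InestimableCellError(
            "events observed for a type with zero average patients present"
        )
    return events / observed_minutes * avg_nurses / avg_patients_of_type


def estimate_mean_duration(care_minutes: float, events: float) -> float:
    """Mean care-event duration: cumulated observed care minutes per event."""
    if care_minutes < 0:
        raise ValueError("care_minutes must be non-negative")
    if events <= 0:
        if care_minutes > 0:
            raise InestimableCellError(
                "care minutes observed but zero events estimated"
            )
        raise InestimableCellError("no events observed; duration inestimable")
    return care_minutes / events


def estimate_rate_table(
    intervals: list[ObservationInterval],
) -> RateTable:
    """Full work-sampling pipeline: tallies -> 12-cell rate table.

    Cells with no estimable events (or shifts never observed) are flagged
    in the returned table's ``missing_cells`` and carried as NaN.
    """
    cells = tally(intervals)
    records = []
    missing = set()
    for shift in SHIFT_LABELS:
        for rtype in RESPIRATORY_TYPES:
            cell = cells.get((shift, rtype))
            if cell is None or cell.observed_minutes == 0:
                records.append((shift, rtype, math.nan, math.nan))
                missing.add((shift, rtype))
                continue
            events = estimate_event_count(cell.n_starts, cell.n_ends)
            try:
                rate = estimate_arrival_rate(
                    events, cell.observed_minutes, cell.avg_nurses, cell.avg_patients
                )
                duration = estimate_mean_duration(cell.care_minutes, events)
            except InestimableCellError:
                records.append((shift, rtype, math.nan, math.nan))
                missing.add((shift, rtype))
                continue
            records.append((shift, rtype, rate, duration))
    frame = pd.DataFrame(
        records, columns=["shift", "respiratory_type", *RateTable.COLUMNS]
    ).set_index(["shift", "respiratory_type"])
    return RateTable(frame, missing_cells=frozenset(missing))
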
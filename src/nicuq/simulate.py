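"""Synthetic data: unit simulation, census series, and observation studies.

This module generates everything the underlying field study would have
provided, since the original observational data are not openly available:

* :func:`simulate_unit` — a discrete-event simulation of the pooled-nurse
  ward (per-patient Poisson care-event arrivals, exponential durations,
  ``c`` nurses serving first-come-first-served).  Its empirical mean wait
  doubles as an independent oracle for the analytic TUCA formulas.
* :func:`generate_census` — a day-linked series of patient mixes whose
  day-to-day turnover emulates admissions/discharges while each day's
  occupancy follows a prescribed distribution exactly.
* :func:`generate_observation_study` — censored work-sampling records
  matching the field design: per day one randomly chosen shift, a 3-hour
  observation block of twelve 10-minute intervals with 5-minute breaks,
  one randomly chosen nurse per interval, and left/right censoring of care
  segments clipped at window edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mix import (
    RESPIRATORY_TYPES,
    SHIFTS,
    SHIFT_LABELS,
    MixDistribution,
    PatientMix,
    RateTable,
)

__all__ = [
    "StudyDesign",
    "CareEvent",
    "simulate_unit",
    "waiting_times",
    "mean_wait_ci",
    "generate_census",
    "generate_observation_study",
]

#: Status-quo nurses per shift used when generating observation studies.
DEFAULT_STAFFING = {"early": 5, "late": 5, "night": 4}


@dataclass(frozen=True)
class StudyDesign:
    """Work-sampling design parameters.

    Defaults reproduce the field design: 84 observation days, one 3-hour
    block per day of 12 ten-minute intervals separated by 5-minute breaks,
    with shifts sampled at the study's realised registration frequencies.
    ``warmup_min`` of simulated ward time precede each shift so observation
    windows see the queue in (approximate) steady state.
    """

    n_days: int = 84
    intervals_per_block: int = 12
    interval_length: float = 10.0
    break_length: float = 5.0
    shift_start_probs: tuple[float, float, float] = (0.3333, 0.4524, 0.2143)
    truncation_prob: float = 0.0
    warmup_min: float = 300.0

    def __post_init__(self) -> None:
        if self.n_days < 0 or self.intervals_per_block < 1:
            raise ValueError("invalid study-design sizes")
        if self.interval_length <= 0 or self.break_length < 0:
            raise ValueError("invalid interval geometry")
        total = sum(self.shift_start_probs)
        if not math.isclose(total, 1.0, abs_tol=1e-3):
            raise ValueError("shift_start_probs must sum to 1")
        if not 0.0 <= self.truncation_prob <= 1.0:
            raise ValueError("truncation_prob must be a probability")

    @property
    def block_span(self) -> float:
        """Minutes from block start to end of the last interval."""
        n = self.intervals_per_block
        return n * self.interval_length + (n - 1) * self.break_length

    @property
    def observed_minutes_per_day(self) -> float:
        return self.intervals_per_block * self.interval_length


@dataclass(frozen=True)
class CareEvent:
    """One realised care event: who needed care, when, and who served it."""

    patient_type: str
    patient_index: int
    arrival: float
    start: float
    end: float
    nurse: int

    @property
    def wait(self) -> float:
        return self.start - self.arrival


def simulate_unit(
    mix: PatientMix,
    c: int,
    table: RateTable,
    horizon: float,
    rng: np.random.Generator,
) -> list[CareEvent]:
    """Simulate the pooled-nurse ward over ``horizon`` minutes from empty.

    Each patient of type ``t`` issues care events as a Poisson process at
    the per-infant rate of the (shift, type) rate-table cell; durations are
    exponential with the cell's mean.  The ``c`` nurses serve in FCFS
    order; when several nurses are idle the serving nurse is chosen
    uniformly at random, so each nurse handles a 1/c share of events in the
    long run (this symmetry is what the work-sampling estimator relies on).
    """
    if c < 1:
        raise ValueError("need at least one nurse")
    lams, durs = table.shift_arrays(mix.shift)
    counts = np.asarray(mix.counts, dtype=float)
    type_rates = counts * lams
    total_rate = float(type_rates.sum())
    if total_rate == 0.0 or horizon <= 0.0:
        return []
    p_type = type_rates / total_rate

    # pre-draw arrivals/marks in bulk for speed
    n_expected = int(total_rate * horizon * 1.1 + 10 * math.sqrt(total_rate * horizon) + 20)
    arrivals: list[float] = []
    t = 0.0
    while True:
        gaps = rng.exponential(1.0 / total_rate, size=n_expected)
        times = t + np.cumsum(gaps)
        inside = times[times < horizon]
        arrivals.extend(inside.tolist())
        if len(inside) < len(times) or len(times) == 0:
            break
        t = float(times[-1])
        n_expected = max(n_expected // 4, 64)
    n = len(arrivals)
    if n == 0:
        return []
    types = rng.choice(len(RESPIRATORY_TYPES), size=n, p=p_type)
    services = rng.exponential(durs[types])
    patient_idx = np.empty(n, dtype=int)
    for k in range(len(RESPIRATORY_TYPES)):
        mask = types == k
        m = int(mask.sum())
        if m and counts[k] > 0:
            patient_idx[mask] = rng.integers(0, int(counts[k]), size=m)

    free = [0.0] * c
    events: list[CareEvent] = []
    for i in range(n):
        arr = arrivals[i]
        idle = [j for j in range(c) if free[j] <= arr]
        if idle:
            nurse = idle[0] if len(idle) == 1 else int(idle[int(rng.integers(len(idle)))])
            start = arr
        else:
            nurse = int(np.argmin(free))
            start = free[nurse]
        end = start + float(services[i])
        free[nurse] = end
        events.append(
            CareEvent(
                patient_type=RESPIRATORY_TYPES[int(types[i])],
                patient_index=int(patient_idx[i]),
                arrival=arr,
                start=start,
                end=end,
                nurse=nurse,
            )
        )
    return events


def waiting_times(events: list[CareEvent], discard: float = 0.0) -> np.ndarray:
    """Waits of events arriving after ``discard`` minutes (warm-up removal)."""
    return np.array([e.wait for e in events if e.arrival >= discard])


def mean_wait_ci(
    waits: np.ndarray, n_batches: int = 20, level: float = 0.99
) -> tuple[float, float, float]:
    """Batch-means confidence interval for the steady-state mean wait.

    Splits the (autocorrelated) wait sequence into ``n_batches`` contiguous
    batches and forms a Student-t interval from the batch means — the
    standard output analysis for steady-state discrete-event simulations.
    Returns (mean, lower, upper).
    """
    waits = np.asarray(waits, dtype=float)
    if len(waits) < n_batches * 2:
        raise ValueError("too few observations for batch means")
    usable = len(waits) - len(waits) % n_batches
    batches = waits[:usable].reshape(n_batches, -1).mean(axis=1)
    mean = float(batches.mean())
    se = float(batches.std(ddof=1) / math.sqrt(n_batches))
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, df=n_batches - 1))
    return mean, mean - tcrit * se, mean + tcrit * se


def generate_census(
    n_days: int,
    dist: MixDistribution,
    turnover_per_day: float = 1.1,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Day-linked census series with Poisson patient turnover.

    Day 1 is drawn from ``dist``.  Each subsequent day draws a Poisson
    number ``r`` of patient arrival/departure moves; occupancy then takes a
    Metropolis-Hastings step targeting the occupancy pmf (proposal: the pmf
    restricted to a +/-r window), so every day's occupancy is marginally
    distributed exactly as ``dist`` while consecutive days remain linked.
    Net occupancy changes plus paired replacements consume the moves;
    replaced/added patients draw fresh types from the type probabilities.
    With zero turnover the mix is constant.

    Returns a DataFrame with one row per day: per-type counts, occupancy,
    and the number of turnover moves.
    """
    rng = np.random.default_rng() if rng is None else rng
    if n_days < 1:
        raise ValueError("need at least one day")
    pmf = dist.occupancy_pmf
    cap = dist.capacity

    counts = np.array(
        dist.sample_mix("early", rng).counts, dtype=int
    )  # shift label irrelevant for the census
    rows = []
    for day in range(n_days):
        r = 0
        if day > 0:
            r = int(rng.poisson(turnover_per_day))
            if r > 0:
                k = int(counts.sum())
                lo, hi = max(0, k - r), min(cap, k + r)
                window = pmf[lo : hi + 1]
                w_k = float(window.sum())
                if w_k > 0.0:
                    proposal = int(rng.choice(np.arange(lo, hi + 1), p=window / w_k))
                    lo2, hi2 = max(0, proposal - r), min(cap, proposal + r)
                    w_prop = float(pmf[lo2 : hi2 + 1].sum())
                    accept = rng.random() < min(1.0, w_k / w_prop)
                    k_new = proposal if accept else k
                else:
                    k_new = k
                net = k_new - k
                departures = max(0, -net) + (r - abs(net)) // 2
                arrivals = max(0, net) + (r - abs(net)) // 2
                departures = min(departures, int(counts.sum()))
                for _ in range(departures):
                    present = np.flatnonzero(counts)
                    t = int(rng.choice(present, p=counts[present] / counts.sum()))
                    counts[t] -= 1
                for _ in range(arrivals):
                    counts[dist.sample_type(rng)] += 1
        rows.append(
            {
                "day": day,
                **{t: int(counts[i]) for i, t in enumerate(RESPIRATORY_TYPES)},
                "occupancy": int(counts.sum()),
                "turnover_events": r,
            }
        )
    return pd.DataFrame(rows).set_index("day")


def _sample_shift(design: StudyDesign, rng: np.random.Generator) -> str:
    probs = np.asarray(design.shift_start_probs, dtype=float)
    return SHIFT_LABELS[int(rng.choice(len(SHIFT_LABELS), p=probs / probs.sum()))]


def generate_observation_study(
    table: RateTable,
    design: StudyDesign,
    census: pd.DataFrame,
    staffing: dict[str, int] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate censored work-sampling records for an observation study.

    For each day: sample a shift by the design's start probabilities, place
    the observation block uniformly so it lies completely inside the shift,
    simulate the ward for that day's mix under ``staffing``, and for each
    interval watch one uniformly chosen nurse.  That nurse's direct-care
    events are clipped to the window with censoring flags set whenever the
    true start/end falls outside.  Intervals with no care activity still
    produce a (segment-less) row so observed time is fully accounted.

    Returns ``(observations, context)`` DataFrames using the observation
    CSV schemas (one observation row per segment or empty interval; one
    context row per day with on-duty nurse and per-type patient counts).
    """
    staffing = dict(DEFAULT_STAFFING if staffing is None else staffing)
    rng = np.random.default_rng() if rng is None else rng
    if len(census) < design.n_days:
        raise ValueError("census must cover every observation day")
    shift_by_label = {s.label: s for s in SHIFTS}

    obs_rows: list[dict] = []
    ctx_rows: list[dict] = []
    for day in range(design.n_days):
        shift_label = _sample_shift(design, rng)
        shift = shift_by_label[shift_label]
        c = int(staffing[shift_label])
        row = census.iloc[day]
        mix = PatientMix(
            shift_label, tuple(int(row[t]) for t in RESPIRATORY_TYPES)
        )
        shift_min = shift.duration_min
        span = design.block_span
        if span > shift_min:
            raise ValueError("observation block does not fit inside the shift")
        block_start = float(rng.uniform(0.0, shift_min - span))
        horizon = design.warmup_min + shift_min
        events = simulate_unit(mix, c, table, horizon, rng)

        n_intervals = design.intervals_per_block
        if design.truncation_prob > 0.0 and rng.random() < design.truncation_prob:
            n_intervals = int(rng.integers(1, design.intervals_per_block))

        ctx_rows.append(
            {
                "day": day,
                "shift": shift_label,
                "nurses_on_duty": c,
                **{f"n_{t}": int(row[t]) for t in RESPIRATORY_TYPES},
            }
        )
        for i in range(n_intervals):
            w0 = design.warmup_min + block_start + i * (
                design.interval_length + design.break_length
            )
            w1 = w0 + design.interval_length
            nurse = int(rng.integers(c))
            base = {
                "day": day,
                "shift": shift_label,
                "nurse_id": f"n{nurse}",
                "interval_start": round(w0 - design.warmup_min, 4),
                "interval_len_min": design.interval_length,
            }
            emitted = False
            for ev in events:
                if ev.nurse != nurse or ev.end <= w0 or ev.start >= w1:
                    continue
                seg_start = max(ev.start, w0) - w0
                seg_end = min(ev.end, w1) - w0
                obs_rows.append(
                    {
                        **base,
                        "segment_start": round(seg_start, 6),
                        "segment_end": round(seg_end, 6),
                        "patient_id": f"{ev.patient_type[:4]}-{ev.patient_index}",
                        "patient_type": ev.patient_type,
                        "category": "direct",
                        "left_censored": ev.start < w0,
                        "right_censored": ev.end > w1,
                    }
                )
                emitted = True
            if not emitted:
                obs_rows.append(
                    {
                        **base,
                        "segment_start": np.nan,
                        "segment_end": np.nan,
                        "patient_id": "",
                        "patient_type": "",
                        "category": "",
                        "left_censored": False,
                        "right_censored": False,
                    }
                )
    obs_cols = [
        "day",
        "shift",
        "nurse_id",
        "interval_start",
        "interval_len_min",
        "segment_start",
        "segment_end",
        "patient_id",
        "patient_type",
        "category",
        "left_censored",
        "right_censored",
    ]
    observations = pd.DataFrame(obs_rows, columns=obs_cols)
    context = pd.DataFrame(
        ctx_rows,
        columns=["day", "shift", "nurses_on_duty"]
        + [f"n_{t}" for t in RESPIRATORY_TYPES],
    )
    return observations, context
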
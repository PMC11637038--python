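"""Patient mixes, per-type care rates, and the mix distribution.

A *patient mix* is the vector of patient counts per respiratory-support
type present during one shift.  Respiratory support (mechanical
ventilation, nCPAP, high-flow cannula, or none) serves as a dynamic,
easily observable proxy for care intensity.  Per-patient care-event
arrival rates and mean durations are tabulated per (shift, type) in a
:class:`RateTable`; a mix aggregates to a unit-level queue load via

    lambda = sum_p lambda_p
    1/mu   = sum_p (lambda_p / mu_p) / lambda

i.e. the unit arrival rate is the sum of per-patient rates and the unit
mean duration is the per-type duration weighted by arrival rate.

The probability model for mixes factorises as an occupancy distribution
over the number of occupied beds times a multinomial split of occupied
beds over the four respiratory types (types independent across patients
given occupancy, no overdispersion).
"""

from __future__ import annotations

import importlib.resources
import itertools
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .queueing import QueueLoad

__all__ = [
    "RESPIRATORY_TYPES",
    "Shift",
    "EARLY",
    "LATE",
    "NIGHT",
    "SHIFTS",
    "SHIFT_LABELS",
    "DEFAULT_CAPACITY",
    "REGULAR_CAPACITY",
    "RateTable",
    "load_reference_rates",
    "PatientMix",
    "aggregate",
    "enumerate_mixes",
    "MixDistribution",
    "mix_probability",
    "fit_mix_distribution",
    "default_mix_distribution",
]

#: The four respiratory-support categories, in canonical order.
RESPIRATORY_TYPES: tuple[str, ...] = (
    "mechanical",
    "ncpap",
    "high_flow",
    "miscellaneous",
)

#: Maximum bed capacity of the modelled unit (11 regular + 2 surge beds).
DEFAULT_CAPACITY = 13
REGULAR_CAPACITY = 11


@dataclass(frozen=True)
class Shift:
    """A nursing shift with its staffed duration in hours.

    Default durations come from the ward clock times (early 6:30-14:30,
    late 13:30-21:30, night 21:00-7:00); the one-hour early/late and
    half-hour late/night overlaps are ignored for nurse-hour accounting.
    """

    label: str
    duration_hours: float

    def __post_init__(self) -> None:
        if self.duration_hours <= 0:
            raise ValueError("shift duration must be positive")

    @property
    def duration_min(self) -> float:
        return self.duration_hours * 60.0


EARLY = Shift("early", 8.0)
LATE = Shift("late", 8.0)
NIGHT = Shift("night", 10.0)
SHIFTS: tuple[Shift, ...] = (EARLY, LATE, NIGHT)
SHIFT_LABELS: tuple[str, ...] = tuple(s.label for s in SHIFTS)


class RateTable:
    """Per (shift, respiratory type) care-event arrival rate and mean duration.

    Backed by a pandas DataFrame indexed by (shift, respiratory_type) with
    columns ``arrival_rate_per_min`` and ``mean_duration_min``.  All 12
    cells must be present; cells flagged as missing (from an inestimable
    work-sampling cell) are carried as NaN and tracked in
    :attr:`missing_cells`.
    """

    COLUMNS = ("arrival_rate_per_min", "mean_duration_min")

    def __init__(self, frame: pd.DataFrame, missing_cells: frozenset = frozenset()):
        frame = frame.copy()
        if set(frame.columns) != set(self.COLUMNS):
            raise ValueError(f"rate table needs columns {self.COLUMNS}")
        expected = pd.MultiIndex.from_product(
            [SHIFT_LABELS, RESPIRATORY_TYPES], names=["shift", "respiratory_type"]
        )
        try:
            frame = frame.reindex(expected)
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"malformed rate-table index: {exc}") from exc
        self.missing_cells = frozenset(missing_cells)
        for (shift, rtype), row in frame.iterrows():
            if (shift, rtype) in self.missing_cells:
                continue
            lam, dur = row[self.COLUMNS[0]], row[self.COLUMNS[1]]
            if pd.isna(lam) or pd.isna(dur):
                raise ValueError(f"missing rate-table cell ({shift}, {rtype})")
            if lam < 0:
                raise ValueError(f"negative arrival rate in cell ({shift}, {rtype})")
            if dur <= 0:
                raise ValueError(f"non-positive duration in cell ({shift}, {rtype})")
        self.frame = frame[list(self.COLUMNS)]

    def cell(self, shift: str, respiratory_type: str) -> tuple[float, float]:
        """(arrival rate per infant per minute, mean duration in minutes)."""
        if respiratory_type not in RESPIRATORY_TYPES or shift not in SHIFT_LABELS:
            raise KeyError(f"unknown rate-table cell ({shift}, {respiratory_type})")
        row = self.frame.loc[(shift, respiratory_type)]
        return float(row.iloc[0]), float(row.iloc[1])

    def shift_arrays(self, shift: str) -> tuple[np.ndarray, np.ndarray]:
        """Arrival rates and durations for one shift, in canonical type order."""
        sub = self.frame.loc[shift].reindex(list(RESPIRATORY_TYPES))
        return sub.iloc[:, 0].to_numpy(float), sub.iloc[:, 1].to_numpy(float)

    @classmethod
    def from_records(cls, records) -> "RateTable":
        frame = pd.DataFrame(
            records, columns=["shift", "respiratory_type", *cls.COLUMNS]
        ).set_index(["shift", "respiratory_type"])
        return cls(frame)

    @classmethod
    def from_csv(cls, path) -> "RateTable":
        raw = pd.read_csv(path)
        required = {"shift", "respiratory_type", *cls.COLUMNS}
        if not required.issubset(raw.columns):
            raise ValueError(f"rate-table CSV must have columns {sorted(required)}")
        if len(raw) != len(SHIFT_LABELS) * len(RESPIRATORY_TYPES):
            raise ValueError(
                f"rate-table CSV must have exactly 12 cells, got {len(raw)}"
            )
        return cls(raw.set_index(["shift", "respiratory_type"]))

    def to_csv(self, path) -> None:
        self.frame.reset_index().to_csv(path, index=False)

    def __eq__(self, other) -> bool:
        return isinstance(other, RateTable) and self.frame.equals(other.frame)

    def __repr__(self) -> str:  # pragma: no cover
        return f"RateTable(\n{self.frame}\n)"


def load_reference_rates() -> RateTable:
    """Load the packaged 12-cell rate table estimated in the underlying field study."""
    ref = importlib.resources.files("nicuq.data") / "rate_table.csv"
    with importlib.resources.as_file(ref) as path:
        return RateTable.from_csv(path)


@dataclass(frozen=True)
class PatientMix:
    """Counts of patients per respiratory type present during one shift."""

    shift: str
    counts: tuple[int, ...]
    capacity: int = DEFAULT_CAPACITY

    def __post_init__(self) -> None:
        if self.shift not in SHIFT_LABELS:
            raise ValueError(f"unknown shift {self.shift!r}")
        if len(self.counts) != len(RESPIRATORY_TYPES):
            raise ValueError("counts must have one entry per respiratory type")
        if any(int(c) != c or c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if self.total > self.capacity:
            raise ValueError(
                f"{self.total} patients exceed capacity {self.capacity}"
            )

    @property
    def total(self) -> int:
        return sum(self.counts)

    def as_dict(self) -> dict[str, int]:
        return dict(zip(RESPIRATORY_TYPES, self.counts))

    def with_counts(self, counts) -> "PatientMix":
        return PatientMix(self.shift, tuple(counts), self.capacity)


def aggregate(mix: PatientMix, table: RateTable) -> QueueLoad:
    """Unit-level queue load of a mix: summed rates, rate-weighted durations.

    An empty unit aggregates to the zero-load sentinel ``QueueLoad(0, 0)``
    (no events, so downstream waiting times are zero by definition).
    """
    lams, durs = table.shift_arrays(mix.shift)
    counts = np.asarray(mix.counts, dtype=float)
    lam = float(np.dot(counts, lams))
    if lam == 0.0:
        return QueueLoad(0.0, 0.0)
    mean_service = float(np.dot(counts * lams, durs) / lam)
    return QueueLoad(lam, mean_service)


def enumerate_mixes(
    capacity: int = DEFAULT_CAPACITY,
    shift: str = "early",
    n_types: int = len(RESPIRATORY_TYPES),
) -> list[PatientMix]:
    """All patient-mix states with 0..capacity patients over ``n_types`` types.

    For 13 beds and 4 types this is the full state space of 2380 situations
    from the empty unit up to 13 patients of a single type.  Types beyond
    the canonical four are not supported (they would have no rate cells).
    """
    if capacity < 0:
        raise ValueError("capacity must be >= 0")
    if n_types != len(RESPIRATORY_TYPES):
        raise ValueError("n_types must equal the number of respiratory types")
    mixes = []
    for total in range(capacity + 1):
        for cut in itertools.combinations(range(total + n_types - 1), n_types - 1):
            counts = []
            prev = -1
            for c in cut:
                counts.append(c - prev - 1)
                prev = c
            counts.append(total + n_types - 2 - prev)
            mixes.append(PatientMix(shift, tuple(counts), capacity))
    return mixes


@dataclass
class MixDistribution:
    """Occupancy pmf over bed counts times a multinomial respiratory-type split."""

    occupancy_pmf: np.ndarray
    type_probs: np.ndarray

    def __post_init__(self) -> None:
        self.occupancy_pmf = np.asarray(self.occupancy_pmf, dtype=float)
        self.type_probs = np.asarray(self.type_probs, dtype=float)
        if len(self.type_probs) != len(RESPIRATORY_TYPES):
            raise ValueError("type_probs must have one entry per respiratory type")
        if np.any(self.occupancy_pmf < 0) or np.any(self.type_probs < 0):
            raise ValueError("probabilities must be non-negative")
        if not math.isclose(self.occupancy_pmf.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("occupancy_pmf must sum to 1")
        if not math.isclose(self.type_probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("type_probs must sum to 1")

    @property
    def capacity(self) -> int:
        return len(self.occupancy_pmf) - 1

    def sample_mix(self, shift: str, rng: np.random.Generator) -> PatientMix:
        k = int(rng.choice(len(self.occupancy_pmf), p=self.occupancy_pmf))
        counts = rng.multinomial(k, self.type_probs)
        return PatientMix(shift, tuple(int(c) for c in counts), self.capacity)

    def sample_type(self, rng: np.random.Generator) -> int:
        return int(rng.choice(len(self.type_probs), p=self.type_probs))

    def to_json(self, path) -> None:
        payload = {
            "occupancy_pmf": {str(k): float(p) for k, p in enumerate(self.occupancy_pmf)},
            "type_probs": {t: float(p) for t, p in zip(RESPIRATORY_TYPES, self.type_probs)},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MixDistribution":
        with open(path) as fh:
            payload = json.load(fh)
        occ = payload["occupancy_pmf"]
        capacity = max(int(k) for k in occ)
        pmf = np.zeros(capacity + 1)
        for k, p in occ.items():
            pmf[int(k)] = p
        probs = np.array([payload["type_probs"][t] for t in RESPIRATORY_TYPES])
        return cls(pmf, probs)


def mix_probability(mix: PatientMix, dist: MixDistribution) -> float:
    """P(mix) = occupancy_pmf(total) * Multinomial(counts | total, type_probs)."""
    k = mix.total
    if k > dist.capacity:
        return 0.0
    p_occ = float(dist.occupancy_pmf[k])
    if p_occ == 0.0:
        return 0.0
    if k == 0:
        return p_occ
    p_split = float(stats.multinomial.pmf(mix.counts, n=k, p=dist.type_probs))
    return p_occ * p_split


def fit_mix_distribution(daily_census: list[PatientMix] | pd.DataFrame) -> MixDistribution:
    """Empirical occupancy pmf and pooled type frequencies from a daily census.

    The occupancy pmf is the frequency of occupied-bed counts over days; the
    type probabilities pool patient-days over the whole census (one global
    vector, since the multinomial split is modelled as shift-invariant).
    """
    if isinstance(daily_census, pd.DataFrame):
        counts = daily_census[list(RESPIRATORY_TYPES)].to_numpy(int)
        capacity = DEFAULT_CAPACITY
        mixes_counts = counts
    else:
        if len(daily_census) == 0:
            raise ValueError("census must be non-empty")
        capacity = max(m.capacity for m in daily_census)
        mixes_counts = np.array([m.counts for m in daily_census], dtype=int)
    if len(mixes_counts) == 0:
        raise ValueError("census must be non-empty")
    totals = mixes_counts.sum(axis=1)
    capacity = max(capacity, int(totals.max()))
    pmf = np.bincount(totals, minlength=capacity + 1).astype(float)
    pmf /= pmf.sum()
    patient_days = mixes_counts.sum(axis=0).astype(float)
    if patient_days.sum() == 0:
        raise ValueError("census contains no patients; type split is undefined")
    type_probs = patient_days / patient_days.sum()
    return MixDistribution(pmf, type_probs)


def default_mix_distribution(capacity: int = DEFAULT_CAPACITY) -> MixDistribution:
    """Synthetic-plausible mix distribution for a busy 11-to-13-bed unit.

    The field study's fitted distribution is not published; this stand-in
    concentrates occupancy on 11 beds (range 8-13) and splits types so a
    typical 11-bed day holds roughly 2-3 mechanically ventilated infants
    and 7 on noninvasive support, matching the study's qualitative
    description of the most frequent situations.
    """
    pmf = np.zeros(capacity + 1)
    for k, p in {8: 0.05, 9: 0.10, 10: 0.20, 11: 0.35, 12: 0.20, 13: 0.10}.items():
        pmf[k] = p
    type_probs = np.array([0.24, 0.50, 0.14, 0.12])
    return MixDistribution(pmf, type_probs)
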
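"""Fixed and flexible staffing policies evaluated by expected TUCA.

A *fixed* policy staffs a constant nurse count per shift (the ward's
status quo is 5 early, 5 late, 4 night).  A *flexible* policy adapts the
count to the anticipated patient mix: starting from the smallest stable
staffing, nurses are added while the marginal TUCA reduction of one more
nurse, dTUCA(c) = TUCA(c) - TUCA(c+1), is at least a threshold
dTUCA_min.  Because TUCA is convex and non-increasing in the nurse count,
this marginal-value rule is an efficient allocation: no alternative
policy consumes the same expected number of nurses with a lower expected
TUCA.  Sweeping the threshold traces an efficiency frontier in the
(expected nurse-hours, expected TUCA) plane.

Night shifts default to the Kingman G/G/c approximation with both
coefficients of variation equal to 1 (which reproduces near-Markov
behaviour but keeps the CVs configurable, since the empirical night-shift
CVs were never published); early and late shifts use the exact M/M/c
formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .mix import (
    DEFAULT_CAPACITY,
    RESPIRATORY_TYPES,
    SHIFTS,
    SHIFT_LABELS,
    MixDistribution,
    PatientMix,
    RateTable,
    aggregate,
    enumerate_mixes,
    mix_probability,
)
from .queueing import QueueLoad, VariabilityParams, delta_tuca, tuca, tuca_kingman

__all__ = [
    "PolicyConfig",
    "EvaluationResult",
    "StaffingPlan",
    "FixedPlan",
    "FlexiblePlan",
    "ConstrainedPlan",
    "TabularPlan",
    "STATUS_QUO",
    "shift_tuca",
    "flexible_staff_for_mix",
    "evaluate_policy",
    "capped_allocation",
    "constrained_policy",
    "efficiency_frontier",
    "InfeasibleStaffingError",
]


class InfeasibleStaffingError(ValueError):
    """No staffing level within the allowed range stabilises the load."""


@dataclass(frozen=True)
class PolicyConfig:
    """Tunable parameters of policy construction and evaluation.

    threshold_min : minimum TUCA reduction (minutes) that justifies one
        additional nurse in the flexible rule.
    min_staff / max_staff : hard bounds on nurses per shift.
    night_model : ``"kingman"`` (default) evaluates night shifts with the
        G/G/c approximation under ``variability``; ``"exact"`` uses M/M/c.
    tuca_weighting : ``"by_probability"`` averages TUCA over mix scenarios
        by their probability; ``"by_event_rate"`` weights scenarios by
        their care-event volume (an event's-eye view of the wait).
    tuca_cap : finite stand-in (minutes) for the infinite wait of an
        overloaded scenario when averaging; ``None`` propagates infinity.
    """

    threshold_min: float = 1.0
    min_staff: int = 1
    max_staff: int = 13
    night_model: str = "kingman"
    variability: VariabilityParams = field(default_factory=VariabilityParams)
    tuca_weighting: str = "by_probability"
    tuca_cap: float | None = 60.0
    capacity: int = DEFAULT_CAPACITY

    def __post_init__(self) -> None:
        if self.threshold_min <= 0:
            raise ValueError("threshold_min must be positive")
        if self.min_staff < 1 or self.max_staff < self.min_staff:
            raise ValueError("need 1 <= min_staff <= max_staff")
        if self.night_model not in ("kingman", "exact"):
            raise ValueError("night_model must be 'kingman' or 'exact'")
        if self.tuca_weighting not in ("by_probability", "by_event_rate"):
            raise ValueError("unknown tuca_weighting")

    def wait_model(self, shift: str) -> str:
        return "kingman" if (shift == "night" and self.night_model == "kingman") else "mmc"


def _wait(load: QueueLoad, c: int, model: str, var: VariabilityParams) -> float:
    if model == "kingman":
        return tuca_kingman(c, load, var, unstable="inf")
    return tuca(c, load, unstable="inf")


def shift_tuca(
    mix: PatientMix, c: int, table: RateTable, config: PolicyConfig
) -> float:
    """Expected TUCA (minutes) of one mix under ``c`` nurses; inf if unstable."""
    load = aggregate(mix, table)
    if load.arrival_rate == 0.0:
        return 0.0
    return _wait(load, c, config.wait_model(mix.shift), config.variability)


def _min_stable_staff(load: QueueLoad, config: PolicyConfig) -> int:
    """Smallest c in [min_staff, max_staff] with rho < 1."""
    if load.arrival_rate == 0.0:
        return config.min_staff
    c = max(config.min_staff, int(math.floor(load.offered_load)) + 1)
    if c > config.max_staff or load.utilization(c) >= 1.0:
        c = max(c, config.min_staff)
        while c <= config.max_staff and load.utilization(c) >= 1.0:
            c += 1
        if c > config.max_staff:
            raise InfeasibleStaffingError(
                f"offered load {load.offered_load:.3g} cannot be stabilised "
                f"with at most {config.max_staff} nurses"
            )
    return c


def flexible_staff_for_mix(
    mix: PatientMix, table: RateTable, config: PolicyConfig
) -> int:
    """Threshold rule: add nurses while one more saves >= threshold_min TUCA.

    Starts at the smallest stable staffing (at least ``min_staff``) and
    returns the smallest c with dTUCA(c) < threshold_min, capped at
    ``max_staff``.  An empty mix staffs ``min_staff``.
    """
    load = aggregate(mix, table)
    if load.arrival_rate == 0.0:
        return config.min_staff
    model = config.wait_model(mix.shift)
    c = _min_stable_staff(load, config)
    while c < config.max_staff:
        gain = _wait(load, c, model, config.variability) - _wait(
            load, c + 1, model, config.variability
        )
        if gain < config.threshold_min:
            break
        c += 1
    return c


class StaffingPlan:
    """A rule mapping (shift, anticipated patient mix) to a nurse count."""

    def staff_for(self, shift: str, mix: PatientMix) -> int:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class FixedPlan(StaffingPlan):
    """Constant nurses per shift, e.g. the 5-5-4 status quo."""

    per_shift: dict[str, int]

    def __post_init__(self) -> None:
        for s in SHIFT_LABELS:
            if s not in self.per_shift:
                raise ValueError(f"fixed plan misses shift {s!r}")
            if self.per_shift[s] < 1:
                raise ValueError("nurse counts must be >= 1")

    def staff_for(self, shift: str, mix: PatientMix) -> int:
        return self.per_shift[shift]


STATUS_QUO = FixedPlan({"early": 5, "late": 5, "night": 4})


@dataclass
class FlexiblePlan(StaffingPlan):
    """Threshold-rule flexible staffing (memoised per (shift, counts))."""

    table: RateTable
    config: PolicyConfig
    _cache: dict = field(default_factory=dict, repr=False)

    def staff_for(self, shift: str, mix: PatientMix) -> int:
        key = (shift, mix.counts)
        if key not in self._cache:
            self._cache[key] = flexible_staff_for_mix(
                mix if mix.shift == shift else PatientMix(shift, mix.counts, mix.capacity),
                self.table,
                self.config,
            )
        return self._cache[key]


@dataclass
class ConstrainedPlan(StaffingPlan):
    """Flexible staffing clipped to a +/-k window around a base fixed plan."""

    base: FixedPlan
    deviation_cap: int
    table: RateTable
    config: PolicyConfig

    def __post_init__(self) -> None:
        if self.deviation_cap < 0:
            raise ValueError("deviation cap must be >= 0")

    def staff_for(self, shift: str, mix: PatientMix) -> int:
        base_c = self.base.per_shift[shift]
        lo = max(self.config.min_staff, base_c - self.deviation_cap)
        hi = min(self.config.max_staff, base_c + self.deviation_cap)
        window_config = replace(self.config, min_staff=lo, max_staff=hi)
        try:
            return flexible_staff_for_mix(
                mix if mix.shift == shift else PatientMix(shift, mix.counts, mix.capacity),
                self.table,
                window_config,
            )
        except InfeasibleStaffingError:
            return hi  # best effort inside the window; TUCA will be capped


@dataclass
class TabularPlan(StaffingPlan):
    """Explicit (shift, counts) -> nurse-count mapping (from greedy allocation)."""

    assignment: dict[tuple[str, tuple[int, ...]], int]
    fallback: StaffingPlan | None = None

    def staff_for(self, shift: str, mix: PatientMix) -> int:
        key = (shift, mix.counts)
        if key in self.assignment:
            return self.assignment[key]
        if self.fallback is not None:
            return self.fallback.staff_for(shift, mix)
        raise KeyError(f"no staffing assignment for {key}")


@dataclass
class EvaluationResult:
    """Expected performance of one staffing plan over the mix distribution."""

    expected_tuca: float
    expected_nurse_hours: float
    per_shift: dict[str, dict[str, float]]
    capped_probability: float = 0.0
    relative_tuca: float | None = None
    relative_hours: float | None = None
    threshold_min: float | None = None

    def relative_to(self, reference: "EvaluationResult") -> "EvaluationResult":
        self.relative_tuca = self.expected_tuca / reference.expected_tuca
        self.relative_hours = self.expected_nurse_hours / reference.expected_nurse_hours
        return self


def _scenario_space(
    dist: MixDistribution, shift: str, config: PolicyConfig
) -> list[tuple[PatientMix, float]]:
    mixes = enumerate_mixes(dist.capacity, shift)
    out = []
    for m in mixes:
        p = mix_probability(m, dist)
        if p > 0.0:
            out.append((m, p))
    return out


def evaluate_policy(
    plan: StaffingPlan,
    dist: MixDistribution,
    table: RateTable,
    config: PolicyConfig,
    reference: EvaluationResult | None = None,
) -> EvaluationResult:
    """Expected TUCA and expected nurse-hours of a plan over the mix space.

    Per shift the expectation runs over every mix with positive
    probability; shifts are combined as a plain average of per-shift
    expected TUCA under ``by_probability`` weighting, or weighted by each
    shift's expected care-event volume under ``by_event_rate``.  Nurse
    hours sum shift duration times expected nurse count.  Overloaded
    scenarios contribute the configured cap (their total probability is
    reported as ``capped_probability``).
    """
    per_shift: dict[str, dict[str, float]] = {}
    total_hours = 0.0
    capped_p = 0.0
    shift_event_rates = {}
    for shift in SHIFTS:
        scenarios = _scenario_space(dist, shift.label, config)
        tuca_sum = 0.0
        weight_sum = 0.0
        nurses_sum = 0.0
        event_rate_sum = 0.0
        for m, p in scenarios:
            c = plan.staff_for(shift.label, m)
            w = shift_tuca(m, c, table, config)
            if math.isinf(w):
                capped_p += p / len(SHIFTS)
                if config.tuca_cap is None:
                    w = math.inf
                else:
                    w = config.tuca_cap
            load = aggregate(m, table)
            weight = p * load.arrival_rate if config.tuca_weighting == "by_event_rate" else p
            tuca_sum += weight * w
            weight_sum += weight
            nurses_sum += p * c
            event_rate_sum += p * load.arrival_rate
        exp_tuca = tuca_sum / weight_sum if weight_sum > 0 else 0.0
        per_shift[shift.label] = {
            "expected_tuca": exp_tuca,
            "expected_nurses": nurses_sum,
            "nurse_hours": shift.duration_hours * nurses_sum,
            "expected_event_rate": event_rate_sum,
        }
        total_hours += shift.duration_hours * nurses_sum
        shift_event_rates[shift.label] = event_rate_sum
    if config.tuca_weighting == "by_event_rate":
        num = sum(
            per_shift[s]["expected_tuca"] * shift_event_rates[s] for s in SHIFT_LABELS
        )
        den = sum(shift_event_rates.values())
        overall = num / den if den > 0 else 0.0
    else:
        overall = float(np.mean([per_shift[s]["expected_tuca"] for s in SHIFT_LABELS]))
    result = EvaluationResult(
        expected_tuca=overall,
        expected_nurse_hours=total_hours,
        per_shift=per_shift,
        capped_probability=capped_p,
    )
    if reference is not None:
        result.relative_to(reference)
    return result


def capped_allocation(
    dist: MixDistribution,
    table: RateTable,
    budget: float,
    config: PolicyConfig,
    scenarios: list[tuple[str, PatientMix, float]] | None = None,
) -> TabularPlan:
    """Greedy marginal allocation under an expected-nurse budget.

    Every (shift, mix) situation starts at its smallest stable staffing;
    the probability-weighted expected nurse count of that base must not
    exceed ``budget``.  Nurses are then added one at a time to the
    situation with the highest marginal TUCA reduction (ties broken by
    shift order, then lexicographic mix) as long as the addition keeps the
    expected count within budget.  By convexity of TUCA in the nurse count
    this greedy rule attains the lowest expected TUCA achievable at the
    consumed expected nurse count.

    ``scenarios`` may supply an explicit list of (shift label, mix,
    probability) situations — probabilities per shift should sum to 1 —
    otherwise the full enumerated mix space of ``dist`` is used.
    """
    if scenarios is None:
        scenarios = [
            (shift.label, m, p)
            for shift in SHIFTS
            for (m, p) in _scenario_space(dist, shift.label, config)
        ]
    shift_order = {s: i for i, s in enumerate(SHIFT_LABELS)}
    items = []
    base_cost = 0.0
    for shift, m, p in scenarios:
        load = aggregate(m, table)
        c = _min_stable_staff(load, config)
        base_cost += p * c
        items.append(
            {
                "shift": shift,
                "mix": m,
                "p": p,
                "load": load,
                "c": c,
                "model": config.wait_model(shift),
            }
        )
    if base_cost > budget + 1e-9:
        raise InfeasibleStaffingError(
            f"budget {budget:.4g} below minimum stable expected staffing "
            f"{base_cost:.4g}"
        )

    def gain(item) -> float:
        if item["c"] >= config.max_staff or item["load"].arrival_rate == 0.0:
            return -1.0
        w_now = _wait(item["load"], item["c"], item["model"], config.variability)
        w_next = _wait(item["load"], item["c"] + 1, item["model"], config.variability)
        if math.isinf(w_now):
            return math.inf
        return w_now - w_next

    cost = base_cost
    gains = [gain(it) for it in items]
    while True:
        best = -1
        best_key = None
        for i, it in enumerate(items):
            if gains[i] <= 0.0:
                continue
            if cost + it["p"] > budget + 1e-9:
                continue
            key = (-gains[i], shift_order[it["shift"]], it["mix"].counts)
            if best_key is None or key < best_key:
                best, best_key = i, key
        if best < 0:
            break
        items[best]["c"] += 1
        cost += items[best]["p"]
        gains[best] = gain(items[best])

    assignment = {(it["shift"], it["mix"].counts): it["c"] for it in items}
    return TabularPlan(assignment)


def constrained_policy(
    base: FixedPlan, deviation_cap: int, table: RateTable, config: PolicyConfig
) -> ConstrainedPlan:
    """Flexible staffing that may deviate from ``base`` by at most +/-k nurses."""
    return ConstrainedPlan(base, deviation_cap, table, config)


def efficiency_frontier(
    dist: MixDistribution,
    table: RateTable,
    config: PolicyConfig,
    thresholds: np.ndarray | list[float] | None = None,
    reference: EvaluationResult | None = None,
    deviation_cap: int | None = None,
    base: FixedPlan = STATUS_QUO,
) -> list[EvaluationResult]:
    """Evaluate the flexible threshold policy over a grid of thresholds.

    The default grid spans 0.65 to 3.60 minutes in 0.05-minute steps (60
    points).  Results are returned in the grid's order and each carries its
    threshold; with ``deviation_cap`` set, the policy is additionally
    constrained to +/-cap nurses around ``base``.
    """
    if thresholds is None:
        thresholds = default_threshold_grid()

    # Precompute, per (shift, mix): probability, event rate, and the wait
    # at every staffing level once; each threshold then only replays the
    # cheap threshold rule.  Numbers are identical to evaluate_policy with
    # a FlexiblePlan/ConstrainedPlan at the same threshold.
    shift_scen = []
    for shift in SHIFTS:
        rows = []
        for m, p in _scenario_space(dist, shift.label, config):
            load = aggregate(m, table)
            if deviation_cap is None:
                lo_bound, hi_bound = config.min_staff, config.max_staff
            else:
                base_c = base.per_shift[shift.label]
                lo_bound = max(config.min_staff, base_c - deviation_cap)
                hi_bound = min(config.max_staff, base_c + deviation_cap)
            if load.arrival_rate == 0.0:
                rows.append((p, 0.0, lo_bound, {lo_bound: 0.0}))
                continue
            model = config.wait_model(shift.label)
            try:
                window_cfg = replace(config, min_staff=lo_bound, max_staff=hi_bound)
                c_min = _min_stable_staff(load, window_cfg)
            except InfeasibleStaffingError:
                c_min = hi_bound
            waits = {
                c: _wait(load, c, model, config.variability)
                for c in range(c_min, hi_bound + 2)
            }
            rows.append((p, load.arrival_rate, c_min, waits, hi_bound))
        shift_scen.append((shift, rows))

    results = []
    for t in thresholds:
        t = float(t)
        per_shift: dict[str, dict[str, float]] = {}
        total_hours = 0.0
        capped_p = 0.0
        for shift, rows in shift_scen:
            tuca_sum = weight_sum = nurses_sum = event_rate_sum = 0.0
            for row in rows:
                if len(row) == 4:  # empty mix
                    p, lam, c, _ = row
                    w = 0.0
                else:
                    p, lam, c_min, waits, hi_bound = row
                    c = c_min
                    while c < hi_bound and waits[c] - waits[c + 1] >= t:
                        c += 1
                    w = waits[c]
                if math.isinf(w):
                    capped_p += p / len(SHIFTS)
                    w = config.tuca_cap if config.tuca_cap is not None else math.inf
                weight = p * lam if config.tuca_weighting == "by_event_rate" else p
                tuca_sum += weight * w
                weight_sum += weight
                nurses_sum += p * c
                event_rate_sum += p * lam
            exp_tuca = tuca_sum / weight_sum if weight_sum > 0 else 0.0
            per_shift[shift.label] = {
                "expected_tuca": exp_tuca,
                "expected_nurses": nurses_sum,
                "nurse_hours": shift.duration_hours * nurses_sum,
                "expected_event_rate": event_rate_sum,
            }
            total_hours += shift.duration_hours * nurses_sum
        if config.tuca_weighting == "by_event_rate":
            num = sum(
                per_shift[s]["expected_tuca"] * per_shift[s]["expected_event_rate"]
                for s in SHIFT_LABELS
            )
            den = sum(per_shift[s]["expected_event_rate"] for s in SHIFT_LABELS)
            overall = num / den if den > 0 else 0.0
        else:
            overall = float(
                np.mean([per_shift[s]["expected_tuca"] for s in SHIFT_LABELS])
            )
        res = EvaluationResult(
            expected_tuca=overall,
            expected_nurse_hours=total_hours,
            per_shift=per_shift,
            capped_probability=capped_p,
            threshold_min=t,
        )
        if reference is not None:
            res.relative_to(reference)
        results.append(res)
    return results


def default_threshold_grid() -> np.ndarray:
    """The canonical 0.65..3.60 min grid in 0.05-min steps (60 points)."""
    return np.round(np.arange(0.65, 3.60 + 1e-9, 0.05), 10)
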
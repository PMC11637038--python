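"""Monte-Carlo robustness of flexible staffing under patient-mix errors.

Flexible staffing assumes the patient mix of the coming shift is known.
This module relaxes that: per repetition a *planned* mix is drawn from the
mix distribution and the flexible rule staffs against it, but the ward
then faces a *realized* mix perturbed in two ways —

* with probability ``p`` the patient count is off by one (one higher or
  one lower, ``p/2`` each; at an empty or full unit the direction is
  re-sampled towards the feasible side so the +/-1 symmetry holds
  conditional on feasibility);
* ``n`` randomly chosen patients have their respiratory type re-drawn
  from the empirical type distribution (a redraw may return the original
  type, so these patients are only *potentially* mis-specified).

The fixed baseline staffs its constant plan regardless of the planned mix
and is evaluated on the *same* realized mixes (common random numbers), so
flexible-vs-fixed comparisons are paired.  Realized mixes that overload
the planned staffing would have infinite TUCA; their wait is capped at a
configurable value (default 60 minutes) so Monte-Carlo means stay finite,
and the capping frequency is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mix import MixDistribution, PatientMix, RateTable, SHIFT_LABELS, SHIFTS
from .policy import (
    STATUS_QUO,
    FixedPlan,
    FlexiblePlan,
    PolicyConfig,
    StaffingPlan,
    shift_tuca,
)

__all__ = [
    "RobustnessScenario",
    "RobustnessResult",
    "perturb_mix",
    "run_scenario",
]


@dataclass(frozen=True)
class RobustnessScenario:
    """One mis-specification scenario: count-error probability and type redraws."""

    p_count_error: float = 0.0
    n_type_errors: int = 0
    reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_count_error <= 1.0:
            raise ValueError("p_count_error must be a probability")
        if self.n_type_errors < 0:
            raise ValueError("n_type_errors must be >= 0")
        if self.reps < 1:
            raise ValueError("need at least one repetition")


@dataclass
class RobustnessResult:
    """Paired Monte-Carlo estimates for flexible and fixed staffing."""

    scenario: RobustnessScenario
    tuca_flexible: float
    tuca_fixed: float
    se_flexible: float
    se_fixed: float
    se_difference: float
    capped_fraction_flexible: float
    capped_fraction_fixed: float
    reps: int
    trace_flexible: np.ndarray | None = None
    trace_fixed: np.ndarray | None = None

    @property
    def difference(self) -> float:
        """Mean paired difference flexible - fixed (negative favours flexible)."""
        return self.tuca_flexible - self.tuca_fixed


def perturb_mix(
    planned: PatientMix,
    scenario: RobustnessScenario,
    dist: MixDistribution,
    rng: np.random.Generator,
) -> PatientMix:
    """Draw the realized mix given the planned one.

    First the count perturbation (probability ``p_count_error``), then
    ``n_type_errors`` patients chosen uniformly at random get their type
    re-drawn from the distribution's type probabilities.  The result never
    leaves [0, capacity].
    """
    counts = list(planned.counts)
    capacity = planned.capacity
    # fixed draw order so scenarios sharing a seed are coupled across
    # p (the count error occurs for a superset of uniform draws) and n
    u_occurs = rng.random()
    u_add = rng.random() < 0.5
    if u_occurs < scenario.p_count_error:
        total = sum(counts)
        add = u_add
        if total == 0:
            add = True
        elif total >= capacity:
            add = False
        if add:
            counts[dist.sample_type(rng)] += 1
        else:
            present = [i for i, c in enumerate(counts) for _ in range(c)]
            victim = present[int(rng.integers(len(present)))]
            counts[victim] -= 1
    total = sum(counts)
    n_redraw = min(scenario.n_type_errors, total)
    if total > 0:
        # a uniformly random patient order plus one fresh type per patient;
        # only the first n are applied, coupling scenarios across n
        patients = [i for i, c in enumerate(counts) for _ in range(c)]
        order = rng.permutation(total)
        new_types = [dist.sample_type(rng) for _ in range(total)]
        for j in range(n_redraw):
            old = patients[int(order[j])]
            counts[old] -= 1
            counts[new_types[j]] += 1
    return PatientMix(planned.shift, tuple(counts), capacity)


def run_scenario(
    planned_dist: MixDistribution,
    scenario: RobustnessScenario,
    table: RateTable,
    config: PolicyConfig,
    flexible_plan: StaffingPlan | None = None,
    fixed_plan: FixedPlan = STATUS_QUO,
    keep_traces: bool = False,
) -> RobustnessResult:
    """Paired Monte-Carlo evaluation of flexible vs fixed staffing.

    Per repetition and shift: draw the planned mix, staff the flexible
    plan against it, perturb to the realized mix, and evaluate both
    policies' TUCA on the realized mix; the repetition's value is the mean
    over the three shifts.  One root seed drives deterministic per-rep
    substreams, and both policies see identical realized mixes.
    """
    if flexible_plan is None:
        flexible_plan = FlexiblePlan(table, config)
    cap = config.tuca_cap if config.tuca_cap is not None else math.inf
    root = np.random.SeedSequence(scenario.seed)
    children = root.spawn(scenario.reps)

    flex = np.empty(scenario.reps)
    fixed = np.empty(scenario.reps)
    n_capped_flex = 0
    n_capped_fixed = 0
    n_cells = scenario.reps * len(SHIFT_LABELS)
    for rep in range(scenario.reps):
        # separate planned/perturbation substreams per shift: scenarios
        # sharing a root seed see identical planned mixes (common random
        # numbers) no matter how much randomness the perturbation consumes
        streams = children[rep].spawn(2 * len(SHIFT_LABELS))
        f_vals = []
        x_vals = []
        for i, shift in enumerate(SHIFT_LABELS):
            rng_plan = np.random.default_rng(streams[2 * i])
            rng_pert = np.random.default_rng(streams[2 * i + 1])
            planned = planned_dist.sample_mix(shift, rng_plan)
            c_flex = flexible_plan.staff_for(shift, planned)
            realized = perturb_mix(planned, scenario, planned_dist, rng_pert)
            w_flex = shift_tuca(realized, c_flex, table, config)
            if not w_flex < cap:
                if math.isinf(w_flex) or w_flex > cap:
                    w_flex = cap
                    n_capped_flex += 1
            c_fix = fixed_plan.staff_for(shift, realized)
            w_fix = shift_tuca(realized, c_fix, table, config)
            if not w_fix < cap:
                if math.isinf(w_fix) or w_fix > cap:
                    w_fix = cap
                    n_capped_fixed += 1
            f_vals.append(w_flex)
            x_vals.append(w_fix)
        flex[rep] = np.mean(f_vals)
        fixed[rep] = np.mean(x_vals)

    diff = flex - fixed
    return RobustnessResult(
        scenario=scenario,
        tuca_flexible=float(flex.mean()),
        tuca_fixed=float(fixed.mean()),
        se_flexible=float(flex.std(ddof=1) / math.sqrt(scenario.reps)),
        se_fixed=float(fixed.std(ddof=1) / math.sqrt(scenario.reps)),
        se_difference=float(diff.std(ddof=1) / math.sqrt(scenario.reps)),
        capped_fraction_flexible=n_capped_flex / n_cells,
        capped_fraction_fixed=n_capped_fixed / n_cells,
        reps=scenario.reps,
        trace_flexible=flex if keep_traces else None,
        trace_fixed=fixed if keep_traces else None,
    )
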
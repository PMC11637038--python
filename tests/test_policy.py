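"""Staffing policies: threshold rule, greedy allocation, frontier structure."""

import itertools
import math

import numpy as np
import pytest

import nicuq
from nicuq import (
    STATUS_QUO,
    ConstrainedPlan,
    FixedPlan,
    FlexiblePlan,
    InfeasibleStaffingError,
    MixDistribution,
    PatientMix,
    PolicyConfig,
    aggregate,
    capped_allocation,
    constrained_policy,
    default_threshold_grid,
    efficiency_frontier,
    evaluate_policy,
    flexible_staff_for_mix,
    shift_tuca,
    tuca,
    tuca_kingman,
)
from nicuq.policy import _min_stable_staff, _wait


def degenerate_dist(counts, capacity=13):
    """A MixDistribution putting all mass on one homogeneous-ish mix.

    Only exactly representable for single-type mixes; used for the
    single-scenario sanity checks.
    """
    pmf = np.zeros(capacity + 1)
    pmf[sum(counts)] = 1.0
    probs = np.zeros(4)
    probs[next(i for i, c in enumerate(counts) if c > 0)] = 1.0
    return MixDistribution(pmf, probs)


class TestShiftTuca:
    def test_empty_mix_no_waiting(self, table, config):
        assert shift_tuca(PatientMix("early", (0, 0, 0, 0)), 3, table, config) == 0.0

    def test_day_shift_uses_exact_formula(self, table, config):
        mix = PatientMix("early", (0, 7, 0, 0))
        load = aggregate(mix, table)
        assert shift_tuca(mix, 2, table, config) == pytest.approx(
            tuca(2, load), rel=1e-14
        )

    def test_night_shift_uses_kingman(self, table, config):
        mix = PatientMix("night", (3, 4, 2, 2))
        load = aggregate(mix, table)
        assert shift_tuca(mix, 4, table, config) == pytest.approx(
            tuca_kingman(4, load), rel=1e-14
        )
        exact_cfg = nicuq.PolicyConfig(night_model="exact")
        assert shift_tuca(mix, 4, table, exact_cfg) == pytest.approx(
            tuca(4, load), rel=1e-14
        )

    def test_unstable_staffing_is_infinite(self, table, config):
        mix = PatientMix("early", (0, 0, 0, 13))  # offered load ~6.6
        assert shift_tuca(mix, 5, table, config) == math.inf


class TestFlexibleRule:
    def test_huge_threshold_gives_minimum_stable_staffing(self, table):
        config = PolicyConfig(threshold_min=1e9)
        mix = PatientMix("early", (3, 5, 2, 1))
        load = aggregate(mix, table)
        assert flexible_staff_for_mix(mix, table, config) == _min_stable_staff(
            load, config
        )

    def test_tiny_threshold_staffs_to_the_cap(self, table):
        config = PolicyConfig(threshold_min=1e-12, max_staff=9)
        mix = PatientMix("early", (3, 5, 2, 1))
        assert flexible_staff_for_mix(mix, table, config) == 9

    def test_result_is_first_c_below_threshold(self, table, config):
        mix = PatientMix("late", (4, 4, 2, 2))
        load = aggregate(mix, table)
        c = flexible_staff_for_mix(mix, table, config)
        gain_at_c = _wait(load, c, "mmc", config.variability) - _wait(
            load, c + 1, "mmc", config.variability
        )
        assert gain_at_c < config.threshold_min
        if c > _min_stable_staff(load, config):
            gain_before = _wait(load, c - 1, "mmc", config.variability) - _wait(
                load, c, "mmc", config.variability
            )
            assert gain_before >= config.threshold_min

    def test_empty_mix_staffs_minimum(self, table, config):
        assert (
            flexible_staff_for_mix(PatientMix("night", (0, 0, 0, 0)), table, config)
            == config.min_staff
        )

    def test_infeasible_load_raises(self, table):
        config = PolicyConfig(max_staff=3)
        mix = PatientMix("early", (0, 0, 0, 13))
        with pytest.raises(InfeasibleStaffingError):
            flexible_staff_for_mix(mix, table, config)


class TestEvaluatePolicy:
    def test_degenerate_distribution_single_mix(self, table, config):
        dist = degenerate_dist((0, 8, 0, 0))
        result = evaluate_policy(STATUS_QUO, dist, table, config)
        expected = np.mean(
            [
                shift_tuca(PatientMix(s, (0, 8, 0, 0)), STATUS_QUO.per_shift[s], table, config)
                for s in ("early", "late", "night")
            ]
        )
        assert result.expected_tuca == pytest.approx(float(expected), rel=1e-12)
        assert result.expected_nurse_hours == pytest.approx(8 * 5 + 8 * 5 + 10 * 4)

    def test_nurse_hours_are_duration_weighted_counts(self, table, config, dist):
        result = evaluate_policy(STATUS_QUO, dist, table, config)
        by_hand = sum(
            shift.duration_hours * STATUS_QUO.per_shift[shift.label]
            for shift in nicuq.SHIFTS
        )
        assert result.expected_nurse_hours == pytest.approx(by_hand)

    def test_flexible_beats_fixed_at_equal_expected_nurses(self, table, config):
        """Adapting staffing to the mix can only help at equal resources:
        checked against the best fixed plan of the same expected size."""
        pmf = np.zeros(14)
        pmf[6], pmf[11] = 0.5, 0.5
        dist = MixDistribution(pmf, np.array([0.3, 0.4, 0.2, 0.1]))
        flex = FlexiblePlan(table, config)
        res_flex = evaluate_policy(flex, dist, table, config)
        nurses_flex = {
            s: res_flex.per_shift[s]["expected_nurses"] for s in ("early", "late", "night")
        }
        # fixed plan with at least the same per-shift expected nurses
        fixed = FixedPlan({s: math.ceil(nurses_flex[s] - 1e-9) for s in nurses_flex})
        res_fixed = evaluate_policy(fixed, dist, table, config)
        assert res_flex.expected_tuca <= res_fixed.expected_tuca + 1e-9

    def test_relative_fields_are_one_for_reference_itself(self, table, config, dist):
        ref = evaluate_policy(STATUS_QUO, dist, table, config)
        again = evaluate_policy(STATUS_QUO, dist, table, config, reference=ref)
        assert again.relative_tuca == pytest.approx(1.0)
        assert again.relative_hours == pytest.approx(1.0)

    def test_event_rate_weighting_differs_and_is_finite(self, table, dist):
        by_event = PolicyConfig(tuca_weighting="by_event_rate")
        res = evaluate_policy(STATUS_QUO, dist, table, by_event)
        assert 0.0 < res.expected_tuca < 60.0


class TestCappedAllocation:
    def two_scenario_instance(self, table):
        # the marginal-value dilemma: one situation gains little from an
        # extra nurse, the other gains a lot
        s1 = ("early", PatientMix("early", (1, 2, 0, 0)), 0.5)
        s2 = ("early", PatientMix("early", (3, 6, 2, 1)), 0.5)
        return [s1, s2]

    def test_extra_nurse_goes_to_higher_gain_scenario(self, table, config):
        scenarios = self.two_scenario_instance(table)
        base = {
            s[1].counts: _min_stable_staff(aggregate(s[1], table), config)
            for s in [(sh, m, p) for sh, m, p in scenarios]
        }
        gains = {
            m.counts: nicuq.delta_tuca(base[m.counts], aggregate(m, table))
            for _, m, _ in scenarios
        }
        lo, hi = sorted(gains, key=gains.get)
        budget = sum(0.5 * base[c] for c in base) + 0.5  # room for one nurse
        plan = capped_allocation(None, table, budget, config, scenarios=scenarios)
        assert plan.assignment[("early", hi)] == base[hi] + 1
        assert plan.assignment[("early", lo)] == base[lo]

    def test_budget_at_minimum_returns_minimum_stable_plan(self, table, config):
        scenarios = self.two_scenario_instance(table)
        base_cost = sum(
            p * _min_stable_staff(aggregate(m, table), config)
            for _, m, p in scenarios
        )
        plan = capped_allocation(None, table, base_cost, config, scenarios=scenarios)
        for _, m, _ in scenarios:
            assert plan.assignment[("early", m.counts)] == _min_stable_staff(
                aggregate(m, table), config
            )

    def test_budget_below_feasibility_rejected(self, table, config):
        scenarios = self.two_scenario_instance(table)
        with pytest.raises(InfeasibleStaffingError):
            capped_allocation(None, table, 0.5, config, scenarios=scenarios)

    def test_threshold_duality_with_flexible_rule(self, table):
        """The greedy plan at the budget a threshold policy consumes equals
        that threshold policy's staffing, scenario by scenario."""
        config = PolicyConfig(threshold_min=1.0, max_staff=10)
        mixes = [
            PatientMix("early", (2, 3, 1, 0)),
            PatientMix("early", (1, 6, 2, 2)),
            PatientMix("early", (4, 4, 3, 1)),
        ]
        scenarios = [("early", m, 1 / 3) for m in mixes]
        flex_counts = {
            m.counts: flexible_staff_for_mix(m, table, config) for m in mixes
        }
        budget = sum(flex_counts[m.counts] for m in mixes) / 3
        plan = capped_allocation(None, table, budget, config, scenarios=scenarios)
        for m in mixes:
            assert plan.assignment[("early", m.counts)] == flex_counts[m.counts]

    def test_greedy_matches_exhaustive_optimum(self, table):
        """Marginal-value greedy equals brute-force search over all
        staffing vectors on small instances (convexity of the wait)."""
        config = PolicyConfig(max_staff=8)
        instances = [
            (
                [
                    ("early", PatientMix("early", (2, 1, 0, 0)), 0.25),
                    ("early", PatientMix("early", (0, 3, 0, 0)), 0.25),
                    ("early", PatientMix("early", (1, 1, 1, 1)), 0.25),
                    ("early", PatientMix("early", (0, 0, 2, 5)), 0.25),
                ],
                [0.5, 1.25],
            ),
            (
                [
                    ("early", PatientMix("early", (5, 5, 0, 0)), 0.5),
                    ("night", PatientMix("night", (3, 4, 2, 2)), 0.5),
                ],
                [0.5, 1.5],
            ),
        ]
        for scenarios, extras in instances:
            items = []
            for shift, m, p in scenarios:
                load = aggregate(m, table)
                items.append((shift, m, p, load, _min_stable_staff(load, config)))
            base_cost = sum(p * cmin for _, _, p, _, cmin in items)
            for extra in extras:
                budget = base_cost + extra
                plan = capped_allocation(None, table, budget, config, scenarios=scenarios)
                greedy_tuca = sum(
                    p
                    * _wait(
                        load,
                        plan.assignment[(shift, m.counts)],
                        config.wait_model(shift),
                        config.variability,
                    )
                    for shift, m, p, load, _ in items
                )
                best = math.inf
                ranges = [
                    range(cmin, config.max_staff + 1) for *_, cmin in items
                ]
                for combo in itertools.product(*ranges):
                    cost = sum(p * c for (_, _, p, _, _), c in zip(items, combo))
                    if cost > budget + 1e-9:
                        continue
                    val = sum(
                        p * _wait(load, c, config.wait_model(shift), config.variability)
                        for (shift, _, p, load, _), c in zip(items, combo)
                    )
                    best = min(best, val)
                assert greedy_tuca == pytest.approx(best, abs=1e-9)


class TestConstrainedPolicy:
    def test_zero_cap_equals_base_plan(self, table, config, dist):
        plan = constrained_policy(STATUS_QUO, 0, table, config)
        for shift in ("early", "late", "night"):
            for counts in [(0, 8, 0, 0), (3, 5, 2, 1), (2, 6, 2, 3)]:
                mix = PatientMix(shift, counts)
                assert plan.staff_for(shift, mix) == STATUS_QUO.per_shift[shift]

    def test_huge_cap_equals_unconstrained_flexible(self, table, config):
        plan = constrained_policy(STATUS_QUO, 99, table, config)
        flex = FlexiblePlan(table, config)
        for shift in ("early", "late", "night"):
            for counts in [(0, 3, 0, 0), (3, 5, 2, 1), (4, 6, 2, 1)]:
                mix = PatientMix(shift, counts)
                assert plan.staff_for(shift, mix) == flex.staff_for(shift, mix)

    def test_one_nurse_cap_interpolates(self, table, config, dist):
        res_fixed = evaluate_policy(STATUS_QUO, dist, table, config)
        res_one = evaluate_policy(
            constrained_policy(STATUS_QUO, 1, table, config), dist, table, config
        )
        res_flex = evaluate_policy(FlexiblePlan(table, config), dist, table, config)
        assert res_flex.expected_tuca <= res_one.expected_tuca + 1e-9
        assert res_one.expected_tuca <= res_fixed.expected_tuca + 1e-9


class TestEfficiencyFrontier:
    def test_default_grid_has_sixty_points(self):
        grid = default_threshold_grid()
        assert len(grid) == 60
        assert grid[0] == pytest.approx(0.65) and grid[-1] == pytest.approx(3.60)

    def test_single_threshold_equals_direct_evaluation(self, table, config, dist):
        [res] = efficiency_frontier(dist, table, config, thresholds=[1.2])
        cfg = nicuq.PolicyConfig(threshold_min=1.2)
        direct = evaluate_policy(FlexiblePlan(table, cfg), dist, table, cfg)
        assert res.expected_tuca == pytest.approx(direct.expected_tuca, rel=1e-12)
        assert res.expected_nurse_hours == pytest.approx(
            direct.expected_nurse_hours, rel=1e-12
        )

    def test_frontier_monotone_and_undominated(self, table, config, dist):
        results = efficiency_frontier(
            dist, table, config, thresholds=np.arange(0.65, 3.61, 0.25)
        )
        pts = sorted(
            ((r.expected_nurse_hours, r.expected_tuca) for r in results),
        )
        for (h1, t1), (h2, t2) in zip(pts, pts[1:]):
            assert h1 <= h2
            assert t1 >= t2 - 1e-9  # more hours never buys worse care
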
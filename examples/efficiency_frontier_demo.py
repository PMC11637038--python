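"""Fixed vs flexible staffing: the efficiency frontier.

Evaluates the 5-5-4 status-quo fixed plan on a synthetic-plausible
patient-mix distribution, then sweeps the flexible threshold rule over
0.65-3.60 minutes and prints the frontier points bracketing the status
quo: better care at the same nurse-hours, and the same care at fewer
nurse-hours.
"""

from nicuq import (
    STATUS_QUO,
    PolicyConfig,
    default_mix_distribution,
    efficiency_frontier,
    evaluate_policy,
    load_reference_rates,
)

table = load_reference_rates()
dist = default_mix_distribution()
config = PolicyConfig()

sq = evaluate_policy(STATUS_QUO, dist, table, config)
print(f"status quo (5-5-4): TUCA {sq.expected_tuca:.3f} min, "
      f"{sq.expected_nurse_hours:.1f} nurse-hours/day")

frontier = efficiency_frontier(dist, table, config, reference=sq)
at_hours = min(
    (r for r in frontier if r.expected_nurse_hours <= sq.expected_nurse_hours),
    key=lambda r: r.expected_tuca,
)
at_tuca = min(
    (r for r in frontier if r.expected_tuca <= sq.expected_tuca),
    key=lambda r: r.expected_nurse_hours,
)
print(f"flexible, same hours : TUCA {at_hours.expected_tuca:.3f} min "
      f"({100 * (1 - at_hours.relative_tuca):.0f}% lower) at threshold "
      f"{at_hours.threshold_min:.2f} min")
print(f"flexible, same care  : {at_tuca.expected_nurse_hours:.1f} nurse-hours "
      f"({100 * at_tuca.relative_hours:.0f}% of status quo) at threshold "
      f"{at_tuca.threshold_min:.2f} min")
print()
print("Every threshold between these two points staffs fewer expected")
print("nurse-hours than the status quo AND delivers a lower expected wait.")
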
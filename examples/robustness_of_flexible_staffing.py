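"""How flexible staffing degrades when the planned patient mix is wrong.

Staffing flexibly requires anticipating the next shift's patient mix.
This example perturbs the realized mix — a 50% chance the patient count
is off by one, plus n patients whose respiratory type is re-drawn — and
compares flexible staffing (planned-mix based) against the fixed 5-5-4
rule on the same realized mixes.
"""

from nicuq import (
    PolicyConfig,
    RobustnessScenario,
    default_mix_distribution,
    load_reference_rates,
    run_scenario,
)

table = load_reference_rates()
dist = default_mix_distribution()
config = PolicyConfig(threshold_min=1.9)  # a frontier policy dominating 5-5-4

print(" n mis-typed   TUCA flexible   TUCA fixed   flexible - fixed")
for n in (0, 2, 4, 6, 8, 10, 13):
    scenario = RobustnessScenario(p_count_error=0.5, n_type_errors=n,
                                  reps=600, seed=7)
    r = run_scenario(dist, scenario, table, config)
    print(f"    {n:2d}          {r.tuca_flexible:6.3f}        {r.tuca_fixed:6.3f}"
          f"       {r.difference:+6.3f} (+-{r.se_difference:.3f})")
print()
print("Mild mis-specification leaves flexible staffing ahead; once most of")
print("the unit's respiratory types are uncertain, the fixed rule is more")
print("robust — forecast quality bounds how lean a flexible policy may be.")
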
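"""Expected time until care arrives (TUCA) and the value of one more nurse.

Builds a typical 11-patient early-shift mix from the packaged rate table,
aggregates it to a unit-level queue load, and shows how the expected wait
falls — convexly — as nurses are added.
"""

from nicuq import PatientMix, aggregate, delta_tuca, load_reference_rates, tuca

table = load_reference_rates()
# 3 mechanically ventilated, 5 nCPAP, 2 high-flow, 1 without support
mix = PatientMix("early", (3, 5, 2, 1))
load = aggregate(mix, table)

print(f"unit arrival rate  : {load.arrival_rate:.3f} care events/min")
print(f"mean care duration : {load.mean_service:.2f} min")
print(f"offered load       : {load.offered_load:.2f} busy nurses")
print()
print(" nurses   TUCA (min)   gain of next nurse (min)")
for c in range(4, 9):
    w = tuca(c, load)
    gain = delta_tuca(c, load)
    print(f"   {c}       {w:8.3f}          {gain:8.3f}")
print()
print("Each added nurse reduces the expected wait by less than the one")
print("before (convexity) — the marginal gains drive the staffing rule:")
print("add nurses while the gain exceeds a chosen threshold.")
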
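"""The work-sampling estimator chain on the published nCPAP/early-shift tallies.

Observers counted 131 care-event starts and 117 ends for nCPAP infants
over 2,847 observed minutes in early shifts, with on average 4.78 nurses
on duty and 7.04 nCPAP infants present, and 1,051 minutes of observed
direct care.  The chain below turns those tallies into the per-infant
arrival rate and mean care duration that parameterise the queueing model.
"""

from nicuq import (
    estimate_arrival_rate,
    estimate_event_count,
    estimate_mean_duration,
)

events = estimate_event_count(n_starts=131, n_ends=117)
print(f"estimated care events          : {events:.0f}")

per_nurse = events / 2847
print(f"events per nurse-minute        : {per_nurse:.4f}  (~{per_nurse:.2f})")

unit_level = per_nurse * 4.78
print(f"events per minute, whole unit  : {unit_level:.4f}  (~{unit_level:.2f})")

rate = estimate_arrival_rate(events, observed_minutes=2847,
                             avg_nurses=4.78, avg_patients_of_type=7.04)
print(f"events per minute per infant   : {rate:.4f}  (~{rate:.2f})")

duration = estimate_mean_duration(care_minutes=1051, events=events)
print(f"mean care-event duration (min) : {duration:.2f}")

print()
print("One nCPAP infant in an early shift generates ~0.03 care events per")
print("minute, each lasting ~8.5 minutes — one cell of the 12-cell rate table.")
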
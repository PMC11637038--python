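# Methods

This note records the model, the estimation procedure, the synthetic-data
design, and the numerical and design choices behind `nicuq`.

## Queueing model

The unit of demand is a care event. Per patient of respiratory-support
type `t` during shift `s`, events arrive as a Poisson process with rate
λₜₛ (events per minute) and take exponentially distributed service times
with mean 1/μₜₛ (minutes); rates are stationary within a shift and switch
at shift boundaries. A patient mix — the count vector over the four
respiratory types present in a shift — aggregates to a unit-level load
with arrival rate λ = Σ nₜλₜ and rate-weighted mean duration
1/μ = Σ nₜλₜ(1/μₜ) / λ. With `c` pooled nurses serving FCFS the unit is an
M/M/c queue and the performance measure is the expected queueing delay,

TUCA(c, λ, μ) = C(c, a) / (cμ − λ),  a = λ/μ,

with Erlang's C. TUCA is treated as a single-dimensional quality measure;
priority classes, abandonment, finite buffers and transient analysis are
out of scope. Units are minutes throughout; conversions happen only in
reporting.

**Numerical evaluation.** Erlang C is computed through the Erlang-B
recurrence B(k) = aB(k−1)/(k + aB(k−1)), C = B/(1 − ρ(1−B)), which avoids
factorials and large powers and is validated against an exact
rational-arithmetic evaluation of the textbook sum to 1e-12 relative for
c ≤ 20 (the unit never staffs more than 13, but the library must not
overflow). Unstable loads (ρ ≥ 1) return `inf` by default so that policy
search naturally avoids them; a strict mode raises instead. The marginal
gain ΔTUCA(c) returns `inf` when `c` is unstable but `c+1` is not (the
stabilising nurse is infinitely valuable), preserving greedy-allocation
semantics at the stability boundary. An empty unit has TUCA 0 by
definition.

**G/G/c approximation.** For night shifts the package defaults to a
Kingman-style closed form,

E[W] ≈ (cv_a² + cv_s²)/2 · ρ^(√(2(c+1))−1) / (c(1−ρ)) · 1/μ,

with both coefficients of variation defaulting to 1 (the empirical night
CVs were never published, so they are configurable). At c = 1, cv = 1 the
form is exactly the M/M/1 delay. Its accuracy is load-dependent: measured
against exact M/M/c at cv = 1 it always sits above the exact value and
stays within a factor 2 for utilisations ρ ∈ [0.5, 0.9], but overestimates
the (tiny) wait at light traffic by large factors — an intrinsic property
of the ρ-power form, documented here because the test suite asserts the
factor-2 band only on [0.5, 0.9].

## Work-sampling estimation

Observations watch one randomly chosen nurse for 10-minute windows, so
care events are left-/right-censored at window edges. Only direct-care
segments are counted; indirect, administrative and other activities pass
through I/O but never enter estimates. Per (shift, type) cell:

1. events = (observed starts + observed ends)/2 — starts miss
   left-censored events, ends miss right-censored ones, and for a
   stationary process both counts have expectation λ·(window minutes), so
   the average is unbiased for the arrival count attributable to the
   observed time (note: *not* for the count of events intersecting the
   windows, which includes a length-biased in-service term);
2. arrival rate = events / observed minutes × mean nurses on duty / mean
   patients of the type present;
3. mean duration = observed direct-care minutes / events (a ratio
   estimator, asymptotically unbiased).

All chaining is at full precision; printing rounds rates to 3 decimals and
durations to 2. The published intermediate 0.21 events/min is reproducible
only from unrounded intermediates (0.0436 × 4.78), so full-precision
chaining is mandatory. Zero-duration segments are dropped; overlapping
direct segments for one nurse are invalid (a nurse serves one event at a
time). Cells with zero estimated events are flagged inestimable rather
than silently imputed. Starts/ends are counted per interval without
cross-interval linkage of event fragments, consistent with the estimator's
construction.

## Patient-mix model

Mix probabilities factorise as an occupancy pmf over 0..13 occupied beds
(11 regular + 2 surge; capacity is configuration, not hard-coded) times a
multinomial split over the four types, with type probabilities pooled
across shifts (a per-shift split is a configuration extension). The
enumeration of all C(17,4) = 2380 states underlies every expectation.
Fitting is by empirical frequencies: occupancy over days, type shares over
patient-days.

The packaged default distribution is **synthetic-plausible, not the
study's**: occupancy concentrated on 11 beds (support 8–13, mode 0.35 at
11) and type probabilities (0.24, 0.50, 0.14, 0.12), chosen once so that a
typical 11-bed day carries ~2–3 invasively ventilated infants and ~7 on
noninvasive support. The fitted distribution behind the original headline
percentages was never published, so all distribution-dependent results are
reproduced qualitatively (dominance, capture, orderings), never as exact
percentages.

## Staffing policies

A fixed plan staffs constant counts (status quo 5-5-4). The flexible rule
starts at the smallest stable staffing (≥ a configurable floor; no
patient-ratio floor is imposed) and adds nurses while ΔTUCA(c) ≥
ΔTUCAᵐⁱⁿ. Policy evaluation takes expectations over the enumerated mix
space per shift; shifts combine as a plain average of per-shift expected
TUCA under the default `by_probability` weighting (each shift is one
situation per day), with an event-rate weighting offered because "average
wait across situations" is ambiguous between the situation's and the
event's point of view. Expected nurse-hours multiply expected counts by
shift durations 8/8/10 h from the ward clock times, ignoring the shift
overlaps (1 h early/late, 0.5 h late/night) — a documented simplification.
Shifts are treated independently (the model has no cross-shift coupling).
Mixes that are unstable under a plan contribute a configurable cap
(default 60 min) to expectations, with the capped probability reported;
propagating `inf` is available by configuration.

The budgeted variant allocates greedily: every situation starts at its
minimum stable staffing and each step adds one nurse to the situation with
the highest ΔTUCA (ties broken deterministically: shift order, then
lexicographic mix) while the probability-weighted expected count stays
within budget. By convexity this matches exhaustive search on small
instances (verified) and is dual to the threshold rule: the greedy plan at
the budget a threshold policy consumes reproduces that policy. The
±k-nurse constrained policy applies the same threshold logic inside the
window [base−k, base+k]. The efficiency frontier sweeps the threshold over
0.65–3.60 min in 0.05 steps (60 points).

## Synthetic data

`simulate_unit` is a discrete-event FCFS simulation of the pooled ward
(full pooling matches the model assumption; patient-dedicated nursing is a
known limitation of that assumption, not modelled). When several nurses
are idle the server is chosen uniformly at random, so each nurse serves a
1/c share of events in the long run — the symmetry the work-sampling
estimator's nurse-scaling step relies on. The simulator doubles as the
independent oracle for the analytic formulas: batch-means confidence
intervals (20 batches, Student-t) absorb the autocorrelation of waits.

`generate_census` links consecutive days by a Poisson(turnover) number of
patient arrival/departure moves (default 1.1/day). Occupancy takes a
Metropolis-Hastings step targeting the occupancy pmf (proposal: the pmf
restricted to a ±r window; acceptance min(1, W(k)/W(k'))), so the target
pmf is exactly stationary and — with day 1 drawn from it — every day's
occupancy is marginally on target while days remain autocorrelated. Zero
turnover freezes the mix. Net occupancy changes plus paired replacements
consume the moves; incoming patients draw fresh types.

`generate_observation_study` reproduces the field design: per day one
shift (default at the study's realised registration frequencies
0.3333/0.4524/0.2143), a 3-hour block of twelve 10-minute intervals with
5-minute breaks placed uniformly so it falls completely inside the shift,
one uniformly chosen on-duty nurse per interval, and that nurse's
direct-care segments clipped to the window with censoring flags. Events in
progress across a boundary are emitted once per overlapping interval. Each
shift simulation is preceded by 300 minutes of warm-up so windows observe
the queue near steady state. An optional truncation probability emulates
prematurely abandoned blocks (the field study's truncation distribution is
unknown, so none is imposed by default). The simulator models nurses as
idle-or-in-direct-care; the other activity categories exist only in the
I/O schema.

What the generator does **not** emulate: within-shift admissions and
discharges, day-of-week effects, observer consent gaps, priority handling
of critical events, and nurse-to-patient assignment. Passing tests
therefore validate the estimator and policy machinery under the model's
own assumptions, not the field realism of those assumptions.

## Robustness Monte Carlo

Per repetition and shift a planned mix is drawn, the flexible rule staffs
against it, and the realized mix deviates: with probability p the count is
off by one (±1 with p/2 each; at an empty or full unit the direction is
re-sampled toward the feasible side, keeping the symmetry conditional on
feasibility), and n patients re-draw their type from the type
distribution — a redraw may return the original type ("potentially
mis-specified"). The fixed baseline is evaluated on the same realized
mixes (common random numbers; per-(rep, shift) substreams keep planned
draws identical across scenarios, and the perturbation consumes draws in a
fixed order so scenarios are coupled across p and n). Overloaded realized
mixes are capped at 60 minutes so means stay finite; capping frequency is
reported. Default 1000 repetitions with one root seed and deterministic
substreams.

The robustness experiments evaluate the **midpoint policy of the
frontier's dominating segment**: thresholds whose flexible policy is at
least as good as the 5-5-4 status quo on both axes form a segment
[t_A, t_B]; the midpoint (snapped to the 0.05 grid) is the representative
"better care at lower cost" policy a unit would actually adopt. The
hours-matched endpoint alone is so richly staffed that no realistic
mis-specification makes it lose to the fixed rule; the TUCA-matched
endpoint is so lean it loses almost immediately — the midpoint exhibits
the policy-relevant behaviour: it beats fixed staffing under mild
mis-specification and crosses above it when most of the unit's types are
uncertain.

## Validation experiment sizes

- Simulation-vs-formula agreement: 12 (c, ρ) grid points, ~120,000 events
  each, 99% batch-means intervals.
- Parameter recovery: 500 observed hours (3,000 ten-minute intervals)
  spread over 1,500 days in two-interval blocks with balanced shift
  sampling and a fixed census (2, 3, 4, 4). Short blocks cut within-block
  autocorrelation of the queue path and the census roughly equalises
  per-cell event counts (~140–180 per cell), both chosen from a variance
  analysis before running. Even so, per-cell standard errors are 5–9%
  against the 15% recovery bound — at 500 hours the check is powered but
  not lavishly so; errors shrink with more hours.
- Robustness: 1,000–4,000 repetitions per scenario; orderings are asserted
  on seed-paired differences, which common random numbers make far more
  precise than the marginal standard errors suggest.

## Known limitations

- TUCA aggregates critical and non-critical events into one wait measure.
- Full pooling overstates flexibility where nurses are patient-assigned;
  dedicated nursing would lengthen waits.
- The Kingman form is an approximation, poorest at light traffic.
- The default mix distribution is a plausible stand-in; all
  distribution-dependent percentages depend on it.
- The estimator assumes stationarity within shifts and a constant nurse
  count during observed periods; heterogeneous staffing across days biases
  the nurse-scaling step unless staffing is constant per shift, as in the
  generator.
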
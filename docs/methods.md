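# Methods

This note records the model, its assumptions, the calibration choices that
were genuinely open, and what the synthetic-data tests do and do not show.

## System and scope

One clinic day of a high-end health-screening center is simulated as a
terminating discrete-event system.  Time is in minutes from the 7:00 AM
opening; the nominal operating horizon is 9 h (t = 540), and the noon
switch of shared rooms sits at t = 300.  Each of the six customer types
follows a fixed published route through stations `A`–`V`; routes encode
the clinical sequencing rules (fasting items `G`, `I`, `L`, `M` precede
lunch `P`; abdominal ultrasound `I` precedes endoscopy `L`; anesthesia
recovery `M` immediately follows `L`).  A stricter rule set — the full
pre-anesthesia work-up `{G,H,I,J,K}` before `L` — is available in the
route validator but is *not* enforced as a default, because one observed
route (X2) deliberately relaxes it; the published routes are authoritative.

Statistics are reported over the whole run: arrivals stop per plan and the
system drains past the horizon until empty (`truncate=True` reverts to a
hard 540-min cut).  Waiting and service times therefore account for every
customer's complete visit.  Lunch counts as service, not waiting.

## Service-time laws

Station laws use the Arena parameter convention (see the `distributions`
module docstring).  Two conventions deserve a note:

* **Lognormal** parameters are the *arithmetic* mean and sd of the
  variate.  This is the only reading under which the published expressions
  reproduce the published simulation means (e.g. ECG: 1 + LOGN(3.42, 1.37)
  → mean 4.42), and it matches Arena's own convention.
* **Beta** is parameterized (β, α) with mean `scale·β/(β+α)`; the breast
  ultrasound/monograph expression 0.999 + 29·BETA(1.35, 2.55) then yields
  the published mean 11.04 and sd 6.23.

Report-time rounding is half-away-from-zero to 2 decimals; all comparisons
(validation verdicts, interval membership) use unrounded values.

Published simulation sds for a few stations (D 2.22, E 1.48, G 3.09,
L 8.75) and means for S (4.80) and T (4.59) are inconsistent with the
closed forms implied by the printed expressions; these cells are reported
as-is by the validation tooling but are not assertable targets.

## Fitting

`fit_distribution` fits each candidate family by maximum likelihood *with
its own location offset* (scipy three-parameter fits; a negative fitted
location is clamped by refitting with the offset pinned at zero, since a
service time cannot begin below zero minutes).  Free-location fitting is
essential: the published expressions carry near-unit offsets, yet the
sample minimum of offset-plus-lognormal data sits well above the true
offset, so pinning the location at the sample minimum distorts the shifted
sample away from every candidate family and misselects.

Selection is by smallest Kolmogorov–Smirnov statistic with a parsimony
rule for near-ties: families within `1/√n` of the best KS value — one
noise unit of the statistic, below its 5 % critical value `1.36/√n` — are
treated as equivalent and the fewest-parameter family wins.  Without this
rule the 4-parameter beta regularly displaces a true uniform by fitting
sampling noise.  Equal-complexity races (lognormal vs gamma) are decided
purely by KS; at n ≈ 1300 these two families are genuinely hard to
distinguish and occasional swaps are expected and statistically honest.

## Arrivals and the day origin

The empirical check-in histogram uses the printed hourly counts over 2342
customers (16 / 1222 / 877 / 227).  Within-bin times are uniform; the
open-ended late tail is spread over 9:00–9:30, and pre-opening arrivals
occupy [−30, 0) and are served from t = 0 (their pre-opening wait is not
counted — the clinic is closed).  The day origin at 7:00 AM centers the
observed arrival mass.

## Staffing calibration (the genuinely open part)

Room counts are published but staffing is not, and the published tables
over-determine the problem: no single staffing we found reproduces both
the current-status queue table (≈21 customers/day) and the 30-customer
experiments.  The defaults were chosen to be consistent with the printed
evidence at the experimental scale, in this order of priority: (i) the
endoscopy `L` must be the top-ranked bottleneck, (ii) the policy ordering
(capacity < schedule < baseline < mix) must hold, (iii) the baseline
waiting level should sit near the published value.  Concretely:

* Counts follow the floor plan where one exists: check-in 2, dressing 4,
  questionnaire 8, blood-pressure 1, blood-draw 2, ECG 1, cardiac
  ultrasound 2, endoscopy 3, recovery bays 4, thyroid 1, breast 1,
  ophthalmology 1, otolaryngology 1, gynecology 3, urology 1, coronary CT
  1; lunch is uncapacitated.  Height/weight runs mornings only and a
  second vision/hearing lane opens at noon (shared room); abdominal
  ultrasound drops from 2 to 1 at noon.
* **Urology `T` is open all day.**  Gating it to afternoons (the literal
  reading of the room-sharing note) forces every male customer to idle
  until noon, which is irreconcilable with the published male totals
  (~194 min) and the published near-zero queue at `T`; the room-sharing
  constraint is treated as a simplification not carried into capacity.
* **Lung CT `K` has 2 slots.**  `K` is performed in the radiology
  department off the screening floor (it has no room on the floor plan and
  was excluded from wristband data collection for exactly that reason), so
  its capacity is not a floor-plan count.  With a single slot its queue
  overtakes the endoscopy at 30 customers/day, contradicting the published
  bottleneck ranking.
* The resulting baseline at 30 customers/day is ≈ 59 min of waiting
  against the published 72.29 — about 18 % low, within the uncertainty a
  calibration without staffing data can claim.  A staffing tuned instead
  to the current-status queue table (single cardiac sonographer, two
  endoscopy teams) reproduces that table almost exactly but yields ≈ 113
  min at 30 customers/day; the tension between the two published operating
  points cannot be resolved by any fixed staffing we found.

## Policies

* **S1 (mix)**: replace the observed type mix; default uniform (1/6 each),
  the published experiment's exact proportions being unstated.  Uniform
  booking multiplies the rare long-route types that visit the single-slot
  coronary CT, which is why waiting *increases* — the same direction as
  published.
* **S2 (capacity)**: +1 endoscopy team in every window (default delta 1).
* **S3 (schedule)**: deterministic batches of 5 every 25 min from opening
  — six batches spanning the same ~2.5 h window as observed check-ins,
  i.e. "spread the observed arrival window evenly".  A shorter interval
  (20 min) compresses arrivals relative to the empirical tail and
  *raises* waiting, contradicting the policy's published purpose; the
  25-min default is the spreading schedule consistent with it.

## Replication analysis

Replicate r uses seed `base_seed + r`; one shared generator per replicate
is consumed in event order (no common-random-numbers variance reduction).
Per-type and per-station means are taken within a replicate, then averaged
across replicates with across-replicate standard errors.  Confidence
intervals for observed station statistics use the normal 1.96 multiplier,
which reproduces the published interval bounds exactly at 2 decimals
(Student-t would not).  Utilization is busy-server time over
capacity-time, zero-capacity windows excluded; non-preemptive noon drops
can in principle push it marginally above 1.

## Synthetic wristband logs

The generator emulates what the sensing infrastructure produces: one
record per customer per station with entry/exit stamps laid end to end
from a histogram check-in time (queueing delay is irrelevant to duration
fitting), missing-timestamp events at rate 3 %, and durations inflated
×3 at rate 1 % (defaults; both configurable).  The zero-service
bookkeeping steps (check-in/leave) get a small 0.2–1.0 min desk dwell so
records remain well-formed.  It does **not** model sensor physics,
identity confusion, re-entries, or cross-day visits — so passing tests
demonstrate correct *pipeline mechanics* (cleaning, grouping, fitting,
selection) on data with the right marginal structure, not robustness to
every field-data pathology.

Cleaning applies, in order: (1) drop unknown customer types, (2) drop
records missing a timestamp, (3) per station drop durations above twice
the station mean, the mean computed once on rule-1/2 survivors (single
pass, no iterative re-trimming).  Two consequences are worth knowing:

* the 2×-mean rule truncates genuine upper tails of high-CV lognormal
  stations (up to ~7 % of records), biasing the post-cleaning mean down by
  10–14 % there — so fitted means are assessed against the *cleaned*
  population, which is also what the original workflow fits;
* cleaning is exactly idempotent only at bounded-support (uniform-law)
  stations; on heavy-tailed stations a second pass removes a further
  ~0.8 % because the trimmed mean is lower.  The single-pass rule is kept
  as specified.

## Numerical and degenerate-input conventions

Events are ordered by `(time, creation-sequence)`; simultaneous arrivals
keep plan order, which makes runs bit-reproducible from the seed.
Capacity windows are half-open `[start, end)`.  A zero-variance lognormal
is a point mass (used for constant-service tests).  Entities that can
never be served (a permanently closed station) raise a model-consistency
error rather than hanging.  Arrival plans must be time-sorted; mixes and
histogram probabilities must sum to 1 within 1e-6/1e-9.

## Problem sizes used in tests

The test suite exercises: 10^6-draw moment checks per station law; an
M/M/1 run of ~60,000 simulated minutes (λ=0.8, μ=1.0) against the
closed-form wait `ρ/(μ−λ)` = 4.0 using batch-means standard errors (the
naive iid SE understates the autocorrelated truth several-fold) and
Little's law; fitting recovery at n = 1305 (the published ECG sample
size) and a 2000-customer generate→clean→fit pipeline; and the policy
comparison at 30 customers × 50 replications.  These sizes were chosen to
make sampling error small relative to the tested tolerances.

## Known limitations

* Staffing levels are calibrated, not observed (see above); absolute
  waiting levels carry that uncertainty even though rankings and policy
  directions are stable across the staffings we examined.
* No dynamic rerouting ("fill an idle station while waiting"), reneging,
  balking, priorities, or staff breaks; the day-before booking constraint
  of the coronary CT is modeled as an ordinary capacity-1 station.
* Room-sharing is approximated by independent per-station capacity
  windows rather than a shared physical resource.
* The published per-type table and queue table cannot both be reproduced
  exactly by this (or, as far as we can tell, any) fixed-staffing FIFO
  model; validation reports verdicts without attempting to reconcile the
  source tables' internal tensions.
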
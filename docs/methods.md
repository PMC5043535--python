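# Methods

## Model

The pathway is modelled as an open network of two infinite-server stations
(the acute stroke unit and the community rehabilitation ward) with
probabilistic routing to absorbing destinations (early supported discharge,
ESD, and home/other discharge). Four patient classes arrive at the acute
ward as independent Poisson processes; class-specific lognormal lengths of
stay (LOS) are sampled per ward, and on discharge from acute care a patient
moves *instantly* — no queueing, no blocking — to rehabilitation, to ESD or
out of the pathway. Because capacity is never imposed, the audited daily
occupancy of each ward measures unconstrained demand ("unfettered demand").

Two classical facts drive the analysis:

1. **Little's law.** Each ward's mean occupancy equals its offered load,
   the sum over inflows of arrival rate × mean LOS.
2. **Infinite-server (M/G/∞) occupancy is Poisson** with mean equal to the
   offered load, insensitive to the LOS distribution's shape. For the
   two-station tandem the joint occupancy is a pair of *independent* Poisson
   variables, because at any instant each patient occupies at most one ward
   and the patients form a Poisson random measure.

Delay probabilities come from the Erlang-loss truncation: for bed count `c`,
`p(delay) = P(N = c)/P(N ≤ c)` evaluated on the empirical occupancy
distribution. On an exactly-Poisson distribution this equals the Erlang B
blocking probability `B(c, a)` at offered load `a`, computed independently in
the package by the stable recursion `B(0)=1, B(k)=aB(k-1)/(k+aB(k-1))`; the
equality is enforced to 1e-9 in the tests. By PASTA (Poisson arrivals see
time averages) the state probabilities are also the arriving-patient
probabilities.

ESD is a destination only: no ESD capacity or LOS is modelled, so capacity
results are produced for the acute and rehabilitation wards.

## ESD eligibility

Each class has a routing vector per ward over {rehab, esd, exit} and LOS
models keyed by (ward, ESD flag). The ESD flag of a patient is *defined as
the sampled route ending in ESD* — eligible (milder) patients are exactly
those who go on to ESD, and they draw shorter stays. A consequence is that
the class-level `esd_eligible_prob` equals the routing-derived total
P(route → ESD), a consistency the validator enforces. This convention also
makes the flag observable in admission records (via the destination field),
so the estimation module can fit the (ward, flag) LOS cells without latent
variables.

## Default configuration

All rates are per day, all durations in days. The defaults encode a pathway
with roughly 640 admissions a year in the mix observed over a 46-month
extract (stroke 54%, TIA 6%, complex-neurological 19%, other 21% of 2444
admissions):

- **Arrivals.** Stroke inter-arrival mean 1.2 days; the other classes scale
  by the admission counts 1320 : 158 : 456 : 510, giving 10.03 (TIA), 3.47
  (complex-neuro) and 3.11 (other) days. The printed 1.2-day stroke figure
  is slightly slower than 1320 admissions in 46 months would imply (~1.06
  days); the printed anchor is used and the other classes scale from it.
- **Routing.** Stroke: acute → rehab 0.40, acute → ESD 300/1320, remainder
  home; rehab → ESD 163/528. The 0.40 transfer probability is a calibrated
  choice (only its product with rehab LOS is identified, and that product is
  pinned by the rehab offered-load target); with it, the ESD split
  reproduces the source counts exactly: 300 of 463 ESD patients from acute
  (65%), total ESD share 463/1320.
  Complex-neuro: acute → rehab 0.11. TIA and other patients occupy acute
  beds only and exit on discharge.
- **Length of stay.** Lognormal throughout. The fitted LOS parameters of
  the study hospital are not published, so the defaults fix plausible
  relative means (e.g. ESD-bound stroke patients stay 6 vs 8 days in acute
  care and 20 vs 28 in rehab; TIA 1.5 days; log-scale sigma 0.7–1.0) and
  then `calibrate_offered_load` rescales each ward's means by a common
  factor so the offered loads hit **8.5 acute / 10.0 rehab** beds. Those
  targets were chosen because the wards' average occupancy rounds to 9 and
  10 beds and the resulting truncated-Poisson delay table reproduces the
  reported single-ward pattern (e.g. 0.14 at 10 acute beds, 0.02 at 14)
  within print rounding. Calibration preserves the lognormal sigma, i.e.
  the coefficient of variation.
- **Seasonality.** Day-of-week and quarter-of-year multiplier hooks exist
  (thinning against the peak rate) and must average to 1 so annual load is
  preserved; the default is flat because no seasonal magnitudes are
  available. Tests exercise load preservation only.

## Experiment protocol

Five audited years per replication after a three-year warm-up, 150
replications (`RunSpec` defaults). The model starts empty; the warm-up is
discarded to remove the empty-start bias, which the tests verify is visible
when the warm-up is switched off. Occupancy is audited once per day at a
configurable epoch (default midnight). Audit counts use start ≤ t < end, so
a same-instant discharge frees the bed before the census.

Randomness: one independent `numpy` `SeedSequence` substream per
(replication, class, purpose ∈ {arrival, routing, LOS, codes}). Substream
identity does not depend on the scenario, so scenarios compared at the same
replication share common random numbers; re-running with the same base seed
is bit-identical.

Because patients never interact, a replication is computed exactly by
sampling every patient journey and counting stays in progress at each audit
instant (two sorted searches per ward) — an event-schedule evaluation of the
discrete-event model that is orders of magnitude faster than a general
event loop and numerically identical for this model class. The
finite-capacity pooling oracle, where patients *do* interact, uses a
conventional heap-based event loop.

## Scenarios

`current` (identity), `plus5pct` (every inter-arrival mean divided by 1.05),
`full_pool` / `partial_pool` (flows unchanged; evaluated against bed plans),
`no_complex_neuro` (class removed). The default reporting grid mirrors the
reported bed ranges: acute 9–14 beds, rehab 10–16, pooling plans over a total
of 26 beds (pool of 0, 4–9, and full pooling of 22 and 26).

## Bed pooling

For a plan with `d_a` dedicated acute, `d_r` dedicated rehab and `p` pooled
beds, joint occupancy `(x, y)` is feasible iff
`max(x − d_a, 0) + max(y − d_r, 0) ≤ p`. The pooled-system delay
probabilities truncate the unconstrained joint distribution to the feasible
set F:

```
p(delay, acute) = P{(x,y) ∈ F : (x+1, y) ∉ F} / P(F)
```

and symmetrically for rehab. With `d_r = p = 0` this is algebraically the
single-ward formula, and with `d_a = d_r = 0` both streams reduce to the
truncation of the summed occupancy — identities the tests check to 1e-12.
For reversible loss systems (independent streams, exponential stays) the
truncation is the exact stationary law of the constrained system; in general
it is an approximation, so the package carries an independent
**finite-capacity oracle**: a direct event-driven simulation in which an
admission takes a dedicated bed first, then a pooled bed, and is counted as
delayed and lost otherwise (Erlang-loss discipline, the same framing as the
single-ward formula; delayed transfers likewise leave the pathway). By
default the oracle decides admission from the occupancy counts alone, which
is equivalent to moving a pooled-bed occupant back into a freed dedicated
bed; a `repack=False` mode keeps bed assignments sticky and demonstrably
blocks slightly more often. Formula and oracle agree within Monte-Carlo
error on a grid of small instances in the acceptance suite.

Two reporting subtleties:

- Moving a *single* dedicated bed into the pool can increase the donating
  stream's delay (it loses guaranteed access); moving balanced bed *pairs*
  monotonically improves the worse stream on the tested instances, and the
  acceptance check of the "pooling diminishes the acute/rehab trade-off"
  property therefore walks plans in balanced two-bed steps from 14/12/0 to
  full pooling of 26.
- Single-ward tables round p(delay) to 2 decimals and pooling tables to 3,
  but the "1 in every n" column is always the nearest integer of the
  *unrounded* probability — reciprocals of rounded values would be visibly
  inconsistent (0.0294 prints as 0.03 yet is 1 in 34, not 1 in 33).

## Input modelling

`classify_diagnosis` maps ICD-10 prefixes (I60–I64 → stroke, G45/G46 → TIA,
a small neurology/neuro-oncology list → complex-neuro, fallback → other).
Inter-arrival times: exponential MLE, rate = (n−1)/(last − first).
LOS: per-family MLE ranked by AIC (`aic = 2k − 2ℓ`); the lognormal sigma is
the n-denominator MLE of the log durations, and a zero-spread sample is
flagged degenerate rather than fitted. Routing: exact empirical destination
fractions per (class, ward), no smoothing. LOS cells are fitted per
(ward, ESD flag) when both cells have at least 30 stays, otherwise pooled —
a stated heuristic. Arrival streams are treated as stationary Poisson (no
seasonality estimation), and no acute↔rehab LOS correlation is modelled.

## Synthetic records

`generate_records` inverts the estimation pipeline: it samples journeys from
a configuration and emits one row per ward stay with a diagnosis code drawn
from a small built-in ICD-10 table. It emulates exponential arrivals,
lognormal LOS and multinomial routing with continuous day-fraction
timestamps. It does **not** emulate working-hours effects, coding errors, or
bed-blocking inflation of recorded LOS — the known contaminant of real
administrative extracts — so round-trip recovery tests demonstrate estimator
correctness on clean data, not robustness to those artefacts. Recovery is
statistically tight only when every class has on the order of a thousand
admissions; at a 46-month horizon the TIA stream (~140 arrivals) carries
~8% relative standard error on its inter-arrival mean, and rare LOS cells
(complex-neuro rehab, ~50 stays) ~10% on sigma, so percent-level agreement
at that horizon is seed luck rather than a property of the estimators.

## Numerical choices and degenerate inputs

- Erlang B via the multiplicative recursion (stable to large loads);
  `invert_offered_load` brackets and solves with Brent's method to 1e-12.
- Exact Poisson reference PMFs truncate at the 1e-15 upper tail and
  renormalise; truncation cancels in the delay ratio.
- `p(delay)` on a bed count with zero cumulative empirical mass returns 1
  with a warning (the ward is never observed that empty).
- Replication uncertainty: 95% intervals are 2.5/97.5 percentiles of
  per-replication delay probabilities, widened if needed to contain the
  pooled point estimate. The intervals are an addition of this
  package; the underlying planning method reports none.
- The trade-off curve warns (does not fail) if the empirical delay ratio is
  not monotone in beds, which can happen for strongly multi-modal PMFs.
- Goodness of fit of occupancy against the Poisson law subsamples audits at
  a 14-day spacing before the chi-square test, because daily occupancy is
  serially correlated on the LOS timescale and a test on all days would
  grossly overstate the evidence.

## Limitations

- The model predicts whether a delay occurs, not its duration; service
  metrics such as four-hour admission targets are out of scope by design.
- ESD is an absorbing destination; community capacity constraints feed back
  into neither ward.
- The pooling truncation is exact only for reversible systems; for the
  pathway (where rehab arrivals are acute discharges) it is validated
  empirically, not proved.
- Calibrated defaults reproduce reported *patterns*; they stand in for the
  study hospital's unpublished fitted parameters.
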
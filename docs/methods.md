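# Methods

## Model

`eplabsim` simulates the inpatient journey of electrophysiology (EP)
patients through a cardiology department as a day-structured
discrete-event process. Three patient classes share one pool of ward
beds. TEP (target EP) patients additionally pass through the EP labs:
admission → pre-operative stay → procedure (physician + lab during
working hours) → post-operative stay → discharge. CLEP and NEP patients
are bed occupants only; they exist to impose realistic competition for
beds and are discharged when their sampled length of stay ends.

Time is hybrid: stays are integer days; within a lab day, events are
continuous minutes. One simulated day proceeds as

1. **morning turnover** (default 07:00): discharges release beds;
2. **admissions**: first the FIFO waiting list, then today's arrivals in
   a random interleaved order across classes, while free beds last;
3. **lab operation** (workdays, default 08:00–22:00): per physician
   slot, FIFO by (first-planned day, admission day, id); a procedure
   starts at the earliest instant at which its physician slot and any
   lab are both free, provided that instant is strictly before closing;
   it then runs to completion (possibly past closing), releasing the
   physician at once and the lab after clean-up. Unstarted patients roll
   to the next workday and re-draw their physician slot from that day's
   allocation.

A TEP patient admitted on day *a* with sampled pre-op *k* is planned for
day *a + k*, advanced to the next workday if the labs are closed (so
*k* = 0 means a same-day candidate, matching procedure types whose
tabulated pre-op minimum is 0). Discharge falls `LOS − preop` days after
the *realized* procedure day; a patient with zero post-op days keeps the
bed until the next morning's turnover. Only TEP discharges inside the
observation window count toward the outcome.

### Bed policy

Arrivals who find every bed occupied join a FIFO waiting list and are
admitted at a later turnover (`bed_policy: queue`, the default). The
alternative `balk` policy drops them instead. Queueing is the default
because it preserves offered CLEP/NEP demand — with balking, lost
CLEP/NEP arrivals deflate their census and the bed-limited scenarios
overstate TEP throughput by roughly a quarter — and because it matches
how a blocking resource behaves in standard simulation frameworks.

## Stochastic inputs

* **Arrivals** (all seven weekdays): negative binomial per class, by
  moments — r = m²/(s²−m), p = r/(r+m) — with a Poisson(m) fallback when
  s² ≤ m (the negative binomial cannot be under-dispersed).
* **Durations**: lognormal truncated to the tabulated min–max, sampled
  by inverse-CDF (exactly equivalent to rejection, but O(1) regardless
  of how little mass the window keeps). The closed-form moment fit is
  σ² = ln(1+s²/m²), μ = ln m − σ²/2. Because tabulated summaries are
  sample statistics of *already-bounded* data, the engine by default
  re-solves μ (σ fixed) so the truncated mean equals the tabulated mean
  (`fit_mode="calibrated"`). The uncorrected fit (`"plain"`) realizes
  means a few percent high — enough to shift bed census and depress
  bed-limited throughput by ~10 % — and the full two-moment refit
  (`"refit"`) is infeasible for several tabulated rows, where the
  truncated lognormal's SD saturates below the printed SD however the
  parameters are chosen. Calibration falls back to the plain fit when
  the target mean sits on a truncation bound or the solution would keep
  < 1e−6 of the distribution's mass.
* **Integer stays**: continuous draw, rounded half-up, clamped to the
  integer part of the truncation range. Half-up is a convention choice
  (the rounding rule is not otherwise determined); it makes tests
  deterministic.
* **Pre-op given LOS**: the pre-op draw is conditioned on not exceeding
  the realized LOS, implemented as the equivalent capped-truncation
  draw; the shape below the cap is unchanged and post-op stays are never
  clamped negative.
* **Procedure mix and physicians**: the procedure type is categorical by
  the normalized tabulated proportions (the raw shares sum to 100.1 %;
  each is divided by that sum). Each workday has two anonymous on-duty
  physician slots; a patient draws slot A with that weekday's tabulated
  probability. Identity is not tracked across days — the input data only
  support per-weekday two-way splits.

### Randomness

A replication consumes four named substreams (arrivals, patient
durations, admission order, physician assignment) spawned from one
`SeedSequence`. Batches derive replication *r*'s seed as
`SeedSequence([master_seed, r])`, so results are bit-reproducible and
scenarios sharing a master seed share common random numbers.

## Scenarios

Two capacity-limiting regimes: *fully occupied wards* (empirical
resources, TEP arrivals replaced by bed-saturating demand: after CLEP/NEP
admissions, every remaining free bed receives a TEP patient) and *fully
occupied EP labs* (beds 110, labs 1, saturating demand).

Reductions target the two AF-ablation classes. For stay phases the
"expected difference" is `pct % × LOS mean` per class; it is removed from
the pre-op mean (floored at 1 day, the unachievable remainder dropped),
from the post-op side (LOS mean shifted, pre-op untouched), or from both
proportionally (pre-op floor enforced, its shortfall landing on post-op).
SDs are held fixed and the distributions refit. When a reduced LOS mean
falls below its truncation minimum (possible for short-stay classes at
30 %), the minimum is relaxed to ⌊new mean⌋, never below the pre-op
lower bound or 1 day — without this, reported reduction cells would be
unrepresentable. Operative-time reductions scale the whole distribution
(mean, SD and bounds) by `1 − pct/100`.

## Outputs and validation statistics

A batch reports the mean and sample SD (ddof = 1; a single replication
reports SD 0 by convention) of per-replication totals, pooled daily
statistics over all replication-days (per-replication daily means are
also kept), and percent differences versus a base case rounded to one
decimal. Simulated and observed daily-discharge records can be compared
with a two-sided Mann-Whitney U test (tie-corrected; a fully tied input
returns p = 1 by convention).

## Calibration

`estimate_config` rebuilds every learnable input from a patient-log
table: per-class daily-arrival moments over the full calendar span of
the log (zero days included), per-procedure-type operative minutes
(clock-time differences, +24 h if negative), LOS and pre-op day
differences (a same-day discharge counts as a 1-day stay), and
per-weekday physician splits from the two most frequent physician ids
(others folded into the closer slot, with a warning). Clean-up times are
not recoverable from admission logs and come from a template
configuration. Classes with fewer than two complete rows raise an error
rather than silently producing an undefined SD; incomplete rows are
dropped with a count warning.

`generate_synthetic_log` draws a log from a configuration's own
distributions. It reproduces the *marginal* distributions, not the
engine's queueing: procedure dates sit exactly `preop` days after
admission without workday advancement, so the estimator round trip is
unbiased. It is the package's fixture generator; recovery tests check
arrival means within 3 standard errors and duration means within 5 %.

What the synthetic log does not emulate: weekday procedure clustering,
bed-congestion-induced admission delays, seasonal drift, or incomplete
records — so passing round-trip tests demonstrate estimator
correctness on clean data, not robustness to messy exports.

## Default configuration and problem sizes

The packaged configuration describes a large Chinese tertiary cardiology
department: 87 ward beds, two EP labs open 08:00–22:00 Monday–Friday,
two on-duty electrophysiologists per workday, eleven EP procedure types,
and a 10-day warm-up followed by a 61-day observation window. Day 1
defaults to a Sunday so the window aligns with a May–June calendar; this
is configurable since the alignment is a reconstruction. Scenario
statistics default to 1000 replications (the acceptance script uses
exactly that); the test suite uses 300 replications for headline
comparisons, which puts the Monte-Carlo standard error of a mean total
near 1–3 patients, and short-horizon configurations for structural
property checks.

## Known limitations

* Elective arrivals only; no emergency pre-emption, no weekend lab
  openings, no multi-department interactions.
* The pooled daily-discharge mean reproduces the reference value, but
  the pooled daily SD realizes lower (≈1.9 vs ≈2.5); day-of-week
  clustering of discharges evidently differs from the original process
  in ways the available summaries do not pin down.
* Balked/queued demand never re-enters as future arrivals.
* Physician slots are anonymous per day; rota constraints across days
  are not modelled.
* Duration SDs cannot always be honoured jointly with bounds (see the
  refit infeasibility above); the calibrated fit privileges the mean,
  which is what throughput responds to.
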
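# Methods

## Scope and data model

The package models a daily remote symptom self-report programme. The
atomic observation is one integer score 0–10 for one (patient, calendar
day, instrument, item). Three instruments are defined: ESAS-r (nine
fixed symptoms plus an optional patient-named `other:<label>` symptom),
the single-item Distress Thermometer (DT), and the short-form Brief
Pain Inventory (BPI; 4 severity + 7 interference items). All three are
treated as one daily session: the simulator completes or misses them
together, and adherence counts a patient-day as completed if any
validated entry exists that day — the permissive reading, since a
partial session still evidences a completed check-in.

ESAS-r is sometimes described as a 10-item measure; the de-facto
instrument standard is nine fixed symptoms with an optional tenth,
patient-named line, which is what we implement (the optional line is
scanned by the alert rules exactly like any fixed item).

BPI composite scoring follows the published convention: severity is the
mean of the four severity items and is undefined unless all four are
answered; interference is the mean of answered interference items and
is undefined with fewer than four of seven. Composites are descriptive
only — alerting always operates on raw item scores, because the rules
speak of individual symptoms, and a composite can mask a single
spiking item.

## Validation

Raw input may contain unknown instruments/items, non-integer or
out-of-range scores, duplicate same-day submissions, and entries
outside a patient's follow-up window. Validation is total: every input
entry is either accepted or appears in the rejection report with a
machine-readable reason; nothing is silently dropped, and re-validating
a clean record set is a no-op. Duplicates resolve latest-wins by
submission timestamp (ties: last in input order), on the view that the
most recent self-report supersedes earlier ones the same day. Scores
are strictly integers; fractional values are rejected, not rounded
(integral floats such as `5.0` from JSON are accepted). Enrollment
dates default to each patient's earliest valid entry when not supplied;
the follow-up window is half-open, 60 days by default.

## Alert engine

Three rules per patient-item-day (defaults): two successive
day-over-day rises of ≥ 2 (`CONSECUTIVE_RISE`, attached to the final
day of the run), a one-day rise of ≥ 3 (`SUDDEN_RISE`), and any score
≥ 8 (`SEVERE`). Design choices where the behaviour was genuinely open:

* "a rise of 2 points each day over 2 consecutive days" is read
  strictly — both day-over-day increments must be ≥ 2 over three
  observed consecutive calendar days — rather than as a net 2-point
  rise sustained for two days. The strict reading is the literal one
  and is the more specific trigger; the generalisation to `n`
  consecutive rises is a config field.
* Missing days break the delta rules. A gap carries no score
  information, and interpolating across one would invent clinical
  signal; `SEVERE` needs no history and is unaffected.
* One alert per (patient, date, instrument, item), with all fired rules
  merged into it. This matches the dashboard's notion of a flagged
  patient-day-symptom and keeps the log free of duplicates; a
  per-rule or per-patient-day granularity would only rescale counts.
* The monitoring window is half-open `[08:00, 17:00)` on monitoring
  weekdays (Mon–Fri); weekend = Saturday/Sunday; timestamps are
  clinic-local and timezone-naive. Entries with no submission
  timestamp are treated as submitted at 00:00, i.e. routed
  after-hours — the conservative choice, since an unverifiable time
  should not claim the nurse-covered window.

The engine is deterministic: identical input and config yield a
byte-identical serialized log. Its acceptance oracle is a naive per-day
restatement of the three predicates, compared exactly on 1,000 random
gapped series.

## Simulator

The simulator emulates the statistical structure the pipeline assumes,
with ground truth (flare events, completion flags) for every patient.

* **Trajectories.** Per item, an integer bounded random walk:
  `s(t+1) = clamp(round(s(t) + eps), 0, 10)`, `eps ~ N(0, daily_sd)`,
  started at the baseline mean. This yields the day-to-day
  autocorrelation of symptom diaries at the cost of no mean reversion,
  so long follow-ups drift more than real cohorts would.
* **Exacerbations.** Independent Bernoulli onsets per item-day (rate
  0.03 by default), each adding a jump of +3..+5 to that item for
  2–5 days — the events the delta rules exist to catch.
* **Missingness.** Whole-day, missing-completely-at-random at rate
  `1 − adherence_p` (default 0.8 completion), one flag per patient-day
  shared across instruments. Real non-completion is health-dependent
  (fatigue, competing priorities), i.e. plausibly informative; MCAR is
  the default because no dependence structure is documented, and the
  parameterisation leaves room for a score-dependent hook.
* **Timestamps.** Submission seconds uniform in the preferred
  06:00–20:00 window.

Defaults — 13 patients, 60 days, baseline 2.5, `daily_sd` 1.0 — describe
a small two-month pilot cohort with mild average burden. The trajectory
moments are not estimated from any dataset; they are surfaced in
`SimParams` as explicitly tunable placeholders. Patient `i` of a cohort
is generated from the stream keyed `(seed, i)`, so cohorts are exactly
reproducible and patients independent.

**What passing simulator-based tests shows.** That the engine, the
analytics and the reporting behave correctly on data with realistic
structure (autocorrelation, flares, gaps) — not that real cohorts would
produce any particular alert volume. Simulated alert counts run much
hotter than a real clinic's because the unreverted random walk spends
substantial time at high scores; the counts are exercised for
monotonicity and determinism, never compared to observed clinic totals.

## Analytics

* **Adherence** pools patient-days: observed/expected, where expected
  is each patient's follow-up window optionally intersected with an
  analysis window. A zero denominator reports an explicit undefined
  result. With `adherence_p = 0.8` the estimate over 13×60 patient-days
  recovers 0.8 within the exact binomial 99% interval in ≥ 98% of
  replicates.
* **Intervention summary**: responses link to alerts by a stable alert
  id; dangling references are a hard error. The percentage requiring
  intervention is `100 × (alerts linked to a response other than
  NO_INTERVENTION_NEEDED) / total alerts`, rounded half-up to one
  decimal. Nurse- and patient-initiated contacts without an alert are
  tallied separately and never enter the denominator.
* **Cost avoidance** = cost/day × mean length of stay × avoided
  admissions, computed in `Decimal` and rounded half-up to two
  decimals, so currency arithmetic is exact.

Rounding convention throughout: percentages half-up to 1 decimal,
currency half-up to 2 decimals.

## Dashboard snapshot

The triage view for one date: one row per enrolled patient, flagged
patients first (then by patient id), each item showing the trailing
**five calendar days** ending at the snapshot date. Calendar days, not
observed days: a gap is clinically informative and is rendered
explicitly, never imputed. The distress flag uses the most recent DT
score inside the window; BPI composites are computed on the snapshot
day. Rendering (text/CSV/HTML) is pure — same snapshot, same bytes —
and the three formats carry identical data; the CSV round-trips through
its reader. A static rendered snapshot exercises the same logic as a
live dashboard without a service stack.

## Numerical and testing choices

* Problem sizes: the default test suite simulates small cohorts (3–13
  patients, 15–60 days); the full-scale checks use 1,000 random series
  for the oracle comparison, 200 cohorts for threshold monotonicity and
  500 replicates for adherence recovery, sizes at which the Monte-Carlo
  error of each check is far below its pass margin.
* The adherence-recovery interval is the exact (Clopper-style central)
  binomial 99% interval on 780 trials; the ≥ 98% replicate coverage
  margin leaves ~4 standard errors of slack at 500 replicates.
* The flare-detection guarantee (every isolated flare onset on an
  observed day with an observed prior day trips `SUDDEN_RISE`/`SEVERE`)
  is tested in the noise-free regime; under background noise a
  concurrent latent drop can mask a flare, which is a property of the
  generator, not a defect of the engine.
* Determinism is asserted at the byte level on every serialized
  artifact (cohort CSV, truth JSON, alert log, summaries, snapshots).

## Known limitations

* No disease-specific trajectory realism, mean reversion, survival or
  withdrawal processes; no caregiver-vs-patient reporter distinction.
* MCAR missingness understates the bias that health-dependent
  non-completion would induce in adherence and alert statistics.
* The alert-count granularity (per patient-day-item) is one of several
  defensible conventions; comparisons against logs kept at a different
  granularity require rescaling.
* Timestamps are timezone-naive; programmes spanning timezones or DST
  boundaries need a policy the package does not impose.
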
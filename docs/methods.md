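# Methods

This note documents the models, rules and numerical choices behind
`homevitals`, in the order the pipeline applies them, together with what the
synthetic cohort generator does and does not emulate.

## Data model

Measurements are long-format rows `(participant_id, domain, value,
timestamp, device_id)` with six physiological domains: heart rate (HR, bpm),
systolic and diastolic blood pressure (SBP/DBP, mm Hg), oxygen saturation
(SPO2, %), body temperature (TEMP, °C) and body weight (WEIGHT, kg).  Four
home devices map onto these domains: blood-pressure cuff → {SBP, DBP}, pulse
oximeter → {SPO2, HR}, scales → {WEIGHT}, thermometer → {TEMP}.  A cuff
reading yields two rows sharing a timestamp; no row-level pairing is assumed
or needed, because blood-pressure classification operates on within-subject
means.  Timestamps are stored timezone-aware in UTC; a single configured
study timezone (default `Europe/London`) governs hour-of-day binning and
calendar-day arithmetic, so daylight-saving transitions affect calendar
counts but not elapsed time.  Validation is total: every input row is either
accepted or reported with its row number and the violated invariant; rows
are never silently dropped.

## Cleaning rules

Two rules run in a fixed order before every analysis (each can be switched
off for sensitivity analyses):

1. **Duplicate removal (60 s window).**  Within each (participant, domain)
   stream, a measurement is removed iff it occurs strictly less than the
   window after the most recent *retained* measurement.  Anchoring on the
   retained row makes a burst of device retries collapse to its first
   element and makes the filter idempotent.  Comparison against the last
   raw row instead would let a long burst march forward and survive.
2. **Outlier exclusion (4 SD).**  Per (participant, domain) stream, the
   mean and sample SD (n−1) are computed once over all values, candidates
   included, and rows with `|value − mean| > k·SD` are removed in a single
   pass — no re-iteration, so the filter is its own fixed point under the
   no-recompute contract.  Streams with fewer than two values or zero SD
   pass through untouched (the inequality is strict).  The rule is applied
   per domain, not pooled across domains, because the units differ.

A `FilterReport` retains every removed row with a reason tag;
`n_input = n_output + n_removed_duplicates + n_removed_outliers` always
reconciles exactly.

## Compliance analytics

- *Days of observation* is the elapsed (fractional) time between a
  participant's first and last measurement; it is the denominator for
  alert-burden rates.
- *Calendar days* is the inclusive count of local dates in that span; it is
  the denominator for day fractions.
- A *full-set day* requires every **available** device to have contributed
  at least one measurement that local day (a participant issued only a
  thermometer scores a full-set day whenever it is used); an
  *any-measurement day* requires any single measurement.
- *Weekly counts* bin measurements into consecutive 7-day blocks anchored
  at the first measurement, including zero-count interior weeks.  The
  per-participant engagement trend is the OLS slope of count against week
  index, fitted **on interior blocks only** by default: the first block
  contains the anchoring measurement by construction (its count is
  conditioned to be ≥1) and the last block is right-censored at the final
  measurement, so both carry structural bias.  During development, a
  cohort-level one-sample t-test of slopes fitted on *all* blocks rejected
  a true null 37.5% of the time at nominal 5% (200 seeded
  constant-adherence cohorts); fitting interior blocks brought this to 8%,
  inside the binomial 3σ band.  `fit="all"` remains available.
- The cohort-level question "does engagement change over time?" is answered
  by a two-sided one-sample t-test of the finite slopes against zero.

## Threshold-band alerting

A scoring scheme assigns each scored domain an ordered set of half-open
intervals `[edge_{i-1}, edge_i)` carrying integer subscores 0–3.  Device
outputs are continuous, so the printed integer chart of the National Early
Warning Score 2 is encoded with half-open intervals at the printed edges,
which reproduces the chart exactly on integer inputs: e.g. pulse
`[0,41)→3, [41,51)→1, [51,91)→0, [91,111)→1, [111,131)→2, [131,∞)→3`.
Only HR, SBP, TEMP and SPO2 carry bands; DBP and WEIGHT are never scored,
and requesting a subscore for them is an error.  No composite score across
domains is ever formed: home streams are asynchronous and two of the six
inpatient score components (respiratory rate, consciousness) cannot be
self-measured, so domains are alerted independently at subscore tiers 1+
(less abnormal) and 2+ (more abnormal).  The 2+ event set is a subset of
the 1+ set by construction.

The `MINDER` scheme models a study-team criterion set as a single-tier
normal/abnormal band per domain.  Its shipped thresholds (HR outside
50–110 bpm, SBP outside 100–180 mm Hg, temperature outside 35.5–37.8 °C,
SpO2 below 94%) are documented placeholders with clinically conventional
community cutoffs; any deployment should substitute its own via a YAML
scheme file (`--scheme path.yaml`), and all MINDER-tier outputs are
scheme-dependent.

Alert burden is reported per participant as tier alerts per day of
observation, and cohort-wide as the proportion of scored measurements
alerting plus the median/IQR of the per-participant daily rates.
Participants with zero days of observation are excluded with a warning.

## Longitudinal summaries

- Within-subject mean and sample SD per domain; a domain is *eligible* for
  cohort aggregation iff its own span strictly exceeds 7 days.
- Blood-pressure classification uses the within-subject means:
  hypertensive iff mean SBP ≥ 135 **or** mean DBP ≥ 85 (inclusive);
  hypotensive iff mean SBP ≤ 90 or mean DBP ≤ 60.  Mixed means can satisfy
  both arms (high systolic with very low diastolic); such participants are
  reported `BOTH_FLAGGED` with a warning rather than forced into one class.
- Weight trajectories use a **trailing** 5-observation sliding average (no
  future data, matching prospective monitoring), one averaged point per raw
  weight from the fifth onward.  Each averaged point is compared with the
  most recent averaged point recorded at least 182.5 days (six months)
  earlier; a change strictly greater than 5% in magnitude is flagged LOSS
  or GAIN.  By construction nothing can be flagged before five
  measurements and a full lookback span exist.  Whether the historical
  comparator should be an averaged or raw value is genuinely open; the
  averaged value is used so that both ends of the comparison have the same
  noise scale.
- Cohort ("grand") summaries are computed over the eligible within-subject
  means: mean/SD and median/IQR are both always reported, with quartiles by
  linear interpolation between order statistics, plus a Shapiro–Wilk p as a
  *reporting flag* indicating which convention (mean/SD if approximately
  Gaussian, else median/IQR) a summary table would print.  Emitting both
  avoids silent convention switches.

## Group inference

One-way ANOVA, Tukey's honestly-significant-difference test with the
Kramer adjustment for unequal group sizes (`SE_ij = sqrt(MSW/2·(1/n_i +
1/n_j))`, q referred to the studentized-range distribution on N−k df),
Spearman rank correlation (Pearson correlation of mid-ranks; p via the t
approximation on n−2 df) and the two-sided one-sample t-test are
implemented from their definitional formulas; `scipy` supplies only the
reference distributions.  The test suite cross-checks every procedure
against the independent scipy implementations to 1e-6–1e-12.  The Kramer
form is used because dementia-subtype groups are strongly unbalanced.
Missing data are deleted pairwise for correlations and listwise within each
ANOVA; participants lacking a cognition score are skipped with a count.  No
family-wise multiple-comparison correction is applied anywhere (the
analysis is exploratory); the run manifest records this explicitly.

Degenerate inputs have defined behaviour: zero within-group variance with
distinct means yields an infinite F with a warning; identical groups yield
F = 0, p = 1; a zero-variance sample in the t-test yields t = 0, p = 1 when
the mean equals the null value and a warned infinite t otherwise.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
physiology.  Per participant, each domain has a baseline drawn from a
between-participant Gaussian; per measurement, Gaussian within-participant
noise is added; weight additionally follows a slow random walk (0.05
kg/day steps) since it is the one domain that genuinely trends.  Defaults
(population mean, between-SD): HR 69.6/9.4 bpm, SBP 131.7/14.1 mm Hg, DBP
74.9/7.5 mm Hg, TEMP 36.4/0.3 °C, SPO2 95.2/1.5 %, WEIGHT 71.4/15.8 kg.
Within-participant SDs are assumptions chosen once for realistic once-daily
home self-measurement: HR 6 bpm, SBP 10, DBP 6 mm Hg, TEMP 0.2 °C, SPO2
1.5 %, WEIGHT 0.4 kg.

Adherence is i.i.d. Bernoulli per device-day at 0.1865 per device, making
the probability of at least one measurement on a day
`1 − (1 − 0.1865)⁴ ≈ 0.562`; measurement hours are drawn from a 24-bin
categorical distribution peaking at 8–9 AM (local time); withdrawal is a
constant 6×10⁻⁴ per-day hazard that right-censors streams.  Subtype
composition defaults to 68:5:9 (Alzheimer : vascular : α-synuclein), and
α-synuclein participants receive a −10 mm Hg systolic shift and 1.5×
within-participant SD multipliers on DBP and SpO2, reflecting the lower and
more variable blood pressure associated with autonomic dysfunction.

Acute events are injected deterministically on top: fever with tachycardia
(+2.0 °C, +30 bpm additive), bradycardia drift (linear ramp to an endpoint
delta over the window), progressive weight loss (percent per 182.5 days,
multiplicative) and a pacemaker-style step (heart rate pinned to a set
value).  Only rows inside (window × affected domains) are touched — an
invariant the tests assert by direct differencing — and every realized
event is recorded in a ground-truth log for detector validation.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: circadian blood-pressure dipping and other
mechanistic structure, heavy-tailed or skewed measurement errors, device
faults beyond additive noise, autocorrelated adherence (weekend effects,
illness-driven gaps), prompted versus self-initiated measurements, and
staggered enrollment.  Parameter-recovery and calibration results
demonstrate internal consistency of the pipeline, not external validity.

### A deliberate negative result

The acceptance suite asserts that every injected fever/tachycardia day
with a temperature or heart-rate measurement produces a 1+ alert.  Under
the default conditions this is false ≈5% of the time: with a temperature
between-participant SD of 0.3 °C, a participant with baseline 35.9 °C
reaches only 37.9 °C under a +2.0 °C fever — below the 38.1 °C band edge —
and similarly a low-baseline heart rate can stay under 91 bpm despite a
+30 bpm rise.  Absolute threshold bands cannot guarantee per-day detection
of relative physiological changes; this is precisely the argument for
personalized (baseline-relative) alerting thresholds.  The test is kept in
its strongest form and fails honestly rather than weakening the generator's
variability below the dispersion real cohorts show.

## Problem sizes and numerical choices

Simulated checks use sizes chosen to give the stated statistical
tolerances at interactive cost: 200 participants × 365 days for
parameter recovery (CLT 3σ bounds, e.g. ±2.0 bpm for HR), 100 seeded runs
for the weight-detector timing property (±21 days around the analytic
−5% crossing, which for a 10%-per-six-months decline starting after a
183-day flat baseline falls at day `183 + 91.25 + 2` — the +2 being the
trailing-window lag), 1000 null simulations for ANOVA type-I calibration
(5% ± 2%), and 200 for the engagement-slope calibration.  Tukey p-values
are compared with the reference implementation at 1e-6, which matches the
numerical accuracy of the studentized-range CDF quadrature; definitional
identities are asserted at 1e-10 to 1e-12.  Values are rounded to one
decimal by the generator (device display resolution); scheme YAML parsing
is exact, with band edges taken verbatim as floats.
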
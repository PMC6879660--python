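# Methods

This note documents the analysis conventions, the tunable parameters, the
synthetic-data model, and the numerical choices made where the design was
genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Time base and conventions

All analysis runs on a uniform 10-min epoch grid anchored to the wall clock
(epochs start at hh:00, hh:10, …), with half-open, left-labelled epochs: the
epoch labelled 08:00 covers 08:00:00–08:09:59.9.  Raw streams are resampled
by within-epoch mean (temperatures, position, light) or sum (activity);
partial epochs at either end of a stream are dropped, interior epochs with no
samples are kept but invalid.  Days are calendar days in local clock time; no
DST handling is attempted (the intended recording windows contain none).

Clock times are treated as points on a 24-h circle everywhere: phase markers
and sleep times are summarized by circular means (dispersion as circular
SEM), differences are shortest circular distances, and cohort quantiles of
clock times are computed after unwrapping onto a continuous axis centred on
the cohort circular mean, so a subject at 23:50 ranks earlier than one at
04:00.

A channel must span at least 7 complete days to be analyzable; shorter
channels are excluded and logged.  Library functions accept a `toy_mode`
flag that relaxes the 7-day and 80 %-validity preconditions for small
worked examples; the pipeline default enforces them.

## Cleaning

Cleaning changes only the validity mask, never stored values, and runs in a
fixed order:

1. **Sensor-off masking.**  Diary-reported removal intervals invalidate every
   overlapping epoch (half-open overlap test).
2. **Rate-of-change filter.**  The threshold is the interquartile distance
   IQD = Q3 − Q1 (linear-interpolation quartiles) of the channel's valid
   values; an epoch is invalidated when its absolute difference from the
   previous valid epoch exceeds the IQD.  Two points were deliberately
   pinned after experiment:
   - Comparisons use the *input* series, not the filter's own evolving
     output.  A stateful "last surviving value" variant looks equivalent but
     cascades catastrophically: after one genuine super-IQD step (evening →
     sleep), every epoch of the new level is rejected against the stale
     reference, and whole nights disappear (we measured 41 % removal on
     synthetic light, 13 % on activity).  The stateless rule removes only
     transition epochs (~1–3 %).  Its worst case is that an isolated spike
     costs two epochs — the spike and the return to baseline — which is
     acceptable for transient artifacts.
   - The filter is a single pass.  Re-running it on its own output recomputes
     the IQD from the survivors and can remove more; this non-idempotence is
     documented and pinned by a regression test rather than "fixed".
   An alternative `iqd_mode="diffs"` computes the threshold from the
   distribution of consecutive absolute differences instead; it is available
   behind the config switch and is not the default.
3. **Light log transform.**  After filtering on raw lux, light is converted
   to log10(lux + 1) for waveforms and indexes; the +1 keeps 0 lux finite and
   maps it to exactly 0.  The time-in-bin analysis always uses raw lux.

## TAP

Wrist temperature, activity and position are normalized per subject to
[0, 1] by an affine map between the 5th and 95th percentiles of the cleaned
week (values outside are clamped), wrist temperature is inverted, and the
three components are averaged with equal weights.  Percentile bounds rather
than min/max make the normalization robust to residual spikes while
preserving the 0 = rest / 1 = active semantics on the bulk of the data.  By
default an epoch needs all three valid components; a lenient ≥2-of-3 mode
exists behind `tap_min_components=2`.  Per-subject (not population) bounds
are the default because the variable is used for within-subject phase
assessment; a population mode can be emulated by passing explicit
`NormalizationSpec`s.

## Non-parametric indexes

IS and IV are computed at full 10-min resolution (p = 144 epoch-of-day
slots), not on hourly means.  With masked gaps, IV's sum runs over
grid-adjacent pairs with both epochs valid, and the divisor uses the number
of such pairs (identical to N − 1 on gap-free data).  IS is clamped to
[0, 1]; a zero-variance channel is rejected as undefined rather than given a
conventional value.

M/L windows are found by exhaustive search over all 144 circular window
starts on the per-subject mean waveform, wrapping midnight; ties break to
the earliest onset in epoch-of-day order.  Day-peaking variables (light,
environmental temperature, activity, position, TAP) use M10/L5; wrist
temperature and sleep, whose acrophase falls in the rest period, use M5/L10.

NRA rescales each variable's cohort RA distribution: values at or beyond the
5th/95th percentile recode to 0/1, the rest map affinely.  The recoding is
done within-variable.  Cohorts under 20 subjects trigger a warning
(percentiles are unstable); a cohort with no RA spread at all makes the
rescaling undefined, and the pipeline then falls back to the clamped raw RA
with a warning rather than aborting the run.

CFI = (IS + (1 − IV/2) + NRA)/3 with IV clamped at 2 (its white-noise value)
so all three components lie on [0, 1].

## Phase markers and CHI

NPM is the timing of the nocturnal 5-h window (L5, or M5 for wrist
temperature and sleep); DPM that of the diurnal 10-h window.  Both are
reported as the window **midpoint** by default — the midpoint is
rotation-symmetric and matches the marker's use as a phase centre — with an
onset convention available via `marker_convention="onset"`.

The darkness centre is the circular midpoint of sunset → next sunrise.  The
default site values (sunset 17:47, sunrise 08:07, centre 00:57) are the
midpoints of the reference site's early-winter ranges and are always
overridable per site/date; no astronomical computation is attempted.
DM-NPM divides the circular NPM–centre distance by its 12-h maximum.  CHI =
(NRA + IS + (1 − DM-NPM))/3 and inherits the NRA fallback above.  All
variables, including environmental temperature, use the same darkness
reference.

## Sleep diary

An epoch counts as asleep when its midpoint m satisfies start < m ≤ end for
some diary interval.  The boundary convention is half-open on the left so
that a 10-min interval straddling midnight (23:55–00:05) maps to exactly one
epoch; total binarized minutes match diary minutes to within one epoch per
interval boundary.  Naps are included in the binary sleep series but
excluded from nocturnal onset/offset and MSFsc.

MSFsc follows the standard chronotype-questionnaire construction with the
asymmetric day-class lists: an episode's onset is classified by its onset
date (Sunday–Thursday work, Friday–Saturday free) and its offset
independently by the offset date (Monday–Friday work, Saturday–Sunday
free).  With SD the mean sleep duration per class,
MSW = onset_w + SD_w/2, MSF = onset_f + SD_f/2, SD_week = (5·SD_w + 2·SD_f)/7,
and MSFsc = MSF − (SD_f − SD_week)/2 only when SD_f > SD_w (no correction
when free sleep is not longer — the sleep-debt correction has nothing to
correct).  Subjects with fewer than 3 work nights or 1 free night are
flagged and excluded from MSFsc analyses, not imputed.  Social jetlag is the
absolute circular difference |MSF − MSW|.

## Light exposure

The day tiles into night (00:00–08:00), morning (08:00–16:00) and evening
(16:00–24:00) — 48 epochs each, with interval labels following the
epoch-start convention (the "08:00 to 15:50" morning includes the epoch
labelled 15:50).  Lux bins are half-open, lower-inclusive: [0, 10),
[10, 100), [100, 1000), [1000, ∞).  Each valid epoch contributes 10 minutes
to exactly one cell; cells are averaged over recording days.  Bin durations
per interval and day sum exactly to that interval's valid-epoch minutes.  A
cleaned week whose maximum lux is below 10 is rejected as almost certainly
log-transformed input.

## Chronotype classification

Subjects at or below the 20th percentile of the (unwrapped) TAP NPM are
early types, above the 80th late types, the rest neither; membership is
E iff rank ≤ ⌈0.2·n⌉ with stable ranking, so counts are exactly n/5, 3n/5,
n/5 when n is divisible by 5 and values are distinct.  Ties spanning a
percentile boundary break by subject input order with a warning; if the
E-cut and L-cut order statistics coincide (no discriminating spread), every
subject is classified N with a warning.  Empirical cut times are reported,
never hard-coded.  The agreement matrix cross-tabulates the ACM-based and
MSFsc-based labels over the common subject set: coincidence (diagonal),
one-step errors (|rank difference| = 1) and opposite-extreme errors (E↔L).

## Synthetic cohort generator

The generator is phenomenological ground-truth machinery, not a
thermoregulation model.  Each subject gets 7 programmed nights: onset at
01:15 + phase offset (+ weekend delay on Friday/Saturday-onset nights),
duration 7.5 h (+ 1 h weekend extension), per-night Gaussian onset jitter.
Channels are built from a smooth 0–1 sleep drive with raised-cosine edges:

- **WT**: 31.8 °C baseline + 2.5 °C squared-cosine bump peaking at each
  night's midsleep (vasodilation precedes sleep and outlasts waking by
  ~1.2 h), plus daytime fluctuations and white noise (SD 0.25 °C).
- **A**: 30-s accumulation samples gated by wakefulness with a 7-cycle/day
  ultradian modulation, multiplicative gamma noise, and a residual nocturnal
  movement fraction (default 0.2 of the waking rate); 10-min sums land near
  70°/min by day.
- **P**: waking angle ≈ 50° vs ≈ 8° asleep, with 10-min-scale posture blocks
  and 30-s noise.
- **L**: lognormal daylight (log10 mean 2.0, brighter days for earlier
  phase offsets via a configurable gradient of 0.15 log-units per hour of
  earliness), dim indoor light after sunset, faint nocturnal residue
  (~0.25 lux) while asleep.
- **ET**: a 24-h sinusoid peaking mid-afternoon with day-to-day weather
  offsets.
- A slow, shared "behavioural drift" process (log-scale SD 0.5, ~1.5-h
  correlation) modulates the willingness-dependent channels so that days
  genuinely differ, as free-living days do.

The diary reports the programmed nights with 5-min reporting noise, naps at
0.5/week, and Poisson sensor-off gaps (1/week, 30–90 min) that corrupt the
wrist/arm channels (WT decays toward room temperature, A and P read zero)
and are logged for masking.  Cohorts draw phase offsets per class around
−1.0 / 0.0 / +1.2 h (SD 0.3 h) for E/N/L with class-graded weekend delays
(0.5/1.0/1.5 h), plus mild between-subject variation in amplitude, jitter,
noise and rest levels.  All randomness flows from one root seed through
spawned per-subject generators; cohorts are bit-for-bit reproducible.

What the generator does *not* capture — and hence what passing tests do not
show about real data: irregular schedules beyond Gaussian-plus-weekend
structure (shift work, all-nighters), diary omissions and misreports beyond
small timing noise, masking of wrist temperature by ambient exposure,
seasonal photoperiod change, and daytime napping-in-darkness patterns.  One
visible consequence: synthetic TAP interdaily stability runs around 0.8,
higher than typical free-living values (~0.5–0.65), because real weeks are
less regular than the programmed ones; activity and environmental
temperature stabilities land in realistic ranges.  Defaults were chosen to
keep the programmed phase recoverable from the waveform (the generator's
primary job); pushing IS(TAP) into the field-typical range by inflating
jitter degrades the phase ground truth itself.

## Numerical choices

- Percentiles and quartiles use linear interpolation between order
  statistics everywhere (numpy default), one convention for the IQD filter,
  TAP bounds, NRA and terciles.
- Window searches return the first (earliest-onset) optimum; `argmax` /
  `argmin` tie behaviour is relied on and verified against a brute-force
  oracle including ties.
- Degenerate inputs reject loudly: zero-variance channels (IS/IV), lo = hi
  normalization bounds, p5 = p95 cohort RA, empty waveform slots for the
  window search, sunset = sunrise.  Constant channels pass the IQD filter
  untouched with a warning.
- Clock arithmetic guards against the float artifact where a tiny negative
  value modulo 24 rounds to exactly 24.0.
- Acceptance-scale problem sizes: the default validation cohort is 50
  subjects × 7 days × 144 epochs (plus 30-s raw streams for activity and
  position), which exercises every pipeline stage in a few seconds while
  keeping percentile-based cohort statistics meaningful.
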
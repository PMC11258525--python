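# Methods

This note documents the models, conventions and design choices behind
`heatwear`, in the spirit of a statistical methods appendix. Nothing here
states a result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Heat-stress indices

### Wet bulb globe temperature

The outdoor WBGT is the weighted sum 0.7·T_wet-bulb + 0.2·T_globe +
0.1·T_dry-bulb, with the globe temperature estimated from global radiation,
humidity and air temperature because field stations rarely carry a globe
thermometer. Two variable mappings are implemented:

- `as_printed` (default): `0.7·w + 0.2·(0.009624·y − 0.00404·z + 1.102·x −
  2.2776) + 0.1·x` with `w` wet-bulb (°C), `y` radiation (W/m²), `x`
  relative humidity (%), `z` air temperature (°C). This form appears in some
  field protocols.
- `literature_swap`: the same expression with `x` and `z` exchanged inside
  the globe estimate and in the 0.1 term, i.e. air temperature carries the
  1.102 coefficient and the 0.1 weight and humidity the small negative one.
  This matches the original outdoor-WBGT estimation literature.

The two forms agree only when humidity (in %) numerically equals air
temperature (in °C). At tropical humidity the `as_printed` form yields
values roughly 10 °C above the conventional WBGT scale, which makes every
ISO-7243-style class limit exceeded on essentially every warm day; the
swapped form produces values on the usual scale. Both are first-class so
analyses can be run and compared under either convention; the default is
the printed form for protocol fidelity, and the exceedance table should be
read with the mapping in mind.

The WBGT class limits (very high metabolic rate 23 °C, high 26 °C, medium
28 °C) are acclimatized ISO-7243-style reference values and are fully
configurable; class flags use strict exceedance (">"), heat-index
categories use "reached" ("≥"), both switchable.

### Heat index

The NWS procedure is computed in °F internally: the simple Steadman formula
`0.5·(T + 61 + (T − 68)·1.2 + RH·0.094)` is returned whenever its average
with the temperature is below 80 °F, otherwise the Rothfusz regression with
the standard low-humidity (RH < 13%, 80–112 °F) and high-humidity (RH > 85%,
80–87 °F) adjustments. The hand-off between the two expressions is
discontinuous; the jump stays below 1.5 °F for RH ≤ 60% and grows to about
2.2 °F at very high humidity. This is a property of the published procedure
itself, not of the implementation; the test suite asserts the 1.5 °F bound
in the moderate-humidity regime and strict monotonicity in temperature
everywhere.

## Daily summarization

Daily maxima are taken over 00:00–24:00; nighttime minima over a clock
window (default 18:00–08:00) ending on the summary date's morning, so a
night's exposure keys to the morning it ends — the same convention used for
sleep and body-temperature nights, which makes the later join trivially
aligned. A maximum or minimum is reported only when at least 50% of the
expected 15-minute slots are present; otherwise the field is missing and
flagged "unknown" downstream rather than silently dropped. Timestamps are
naive local time (the intended deployment region does not observe DST).
Heat-index rows in the exceedance table are cumulative threshold counts (a
danger day also counts as having reached caution); the mutually exclusive
highest-category labels are kept alongside for partition checks.

## Wearable quality control

- **Sleep.** Episodes longer than 180 min are merged into one night while
  each following long episode begins before 12:00 of the calendar day after
  the *first* episode's start date (chained merges allowed); wake minutes
  never count as sleep; episodes of ≤ 180 min (naps) stand alone. Nights
  with less than 180 or more than 780 min of sleep are rejected
  (`too_short` / `too_long`), with both boundaries kept since the exclusion
  wording is strict. The night key is the date of the block's end.
- **Heart rate.** Keep 30 ≤ bpm ≤ 208 − 0.7·age; both bounds inclusive
  because the exclusion rule is strictly "<30" and ">max".
- **Body shell temperature.** Keep 28.0–42.0 °C. The bounds represent
  hypothermia-induced loss of consciousness below and the protein-
  denaturation region above; they are configurable because different
  deployments may prefer tighter skin-temperature bands. Kept readings are
  averaged per night window.
- **Steps.** Zero counts default to non-wear (missing): an unworn device and
  a truly stationary day cannot be distinguished, and a zero is undefined
  under the log transform used by the adjusted models.
- **Demographics.** WHO adult BMI classes with the (24.9, 25) gap closed as
  [18.5, 25) normal / ≥ 25 overweight; age groups 6–11, 12–18, 19–45, > 45
  with integer-year boundaries.

## Completeness

Coverage is `distinct units with ≥ 1 valid record / units in the wear
window`, with units per variable: nights (sleep, body temperature), days
(steps) and 30-minute slots (heart rate). The heart-rate unit is a
convention — wrist PPG samples opportunistically, so any finer unit would
understate adherence and any coarser one would saturate; 30 minutes puts
the default generator's output on the few-percent scale typical of field
deployments. Group contrasts use Welch's t (Welch–Satterthwaite df, t-based
CI on the mean difference) and the Mann–Whitney U test (normal
approximation with tie and continuity corrections) with a Hodges–Lehmann
shift estimate and distribution-based 95% CI; the whole family of contrasts
is Holm-corrected, separately per test type. Degenerate comparisons (two
identical constant samples) return t = 0, p = 1 rather than erroring.

## Exposure–response models

The analysis table joins adult participants (age ≥ 19) holding ≥ 50%
completeness for the outcome with the matching daily exposure: same-date
daily maxima for steps, the nightly minimum of the night ending that
morning for sleep and body temperature, or a binary no-heavy-rain indicator
(steps only; the alternative reading — restricting to non-heavy-rain days —
is available by filtering, but the indicator is the default). Models are
ordinary least squares pooled over participants and days: unadjusted
per exposure on the native outcome scale, and adjusted with gender (men = 1,
women reference), age and BMI, with step counts natural-log transformed
only in the adjusted models. Standard errors are the classical
`sqrt(σ̂²·[(XᵀX)⁻¹]_jj)` with σ̂² = RSS/(n − k − 1); adjusted R² is
1 − (1 − R²)(n − 1)/(n − k − 1). There is no within-participant clustering,
random effect or autocorrelation correction — a deliberate match to the
pooled design this package targets, and a known limitation: with a real
cohort the SEs of between-person effects (e.g. gender) are optimistic.
Rank-deficient designs raise an error naming the collinear columns; table
rendering rounds half-up (ties away from zero) in decimal arithmetic, the
convention used for every printed percentage.

## Synthetic-data generator

The generator defines the package's study conditions: 83 participants
(51% women, ages truncated-normal 33.3 ± 19 on [6, 83], adult BMI 23.8 ± 4.7
on [16, 37.4], 59% wearing the additional temperature patch), 204 study
days, staggered 21-day wear windows.

**Weather.** Air temperature = 23.8 °C day-mean (day-to-day SD 0.9 °C)
+ 4.5 °C diurnal sinusoid peaking at 14:00 + AR(1) noise (SD 0.4 °C,
ρ = 0.8 per 15 min); humidity anti-phase with temperature around 60%;
radiation a clipped daylight half-sine peaking at 750 W/m²; wet bulb = air −
1.7·(100 − RH)/10 so the wet-bulb depression widens in dry afternoons;
rain on ~47.6% of days with heavy days (≥ 20 mm) at probability 16/204 and
afternoon-weighted interval allocation. These values were chosen once to
emulate a warm, humid equatorial site where the heat-index caution level is
reached on ~95% of days but extreme caution stays rare, and are not tuning
knobs: the same configuration is used by every test and by the acceptance
script.

**Outcomes.** Nightly sleep = 537.5 − 5.56·T_night-min − 0.39·age +
0.9·man + N(0, 60) minutes; log steps = 8.25 + 0.06·WBGT_max − 0.02·age −
0.03·BMI + 0.05·man + N(0, 0.5) (the intercept is calibrated to the
`as_printed` WBGT scale so that median counts land near 8,000); body shell
temperature per night = 36.31 − 0.72·man − 0.03·BMI + 0.03·T_night-min +
N(0, 0.95), emitted as four readings with N(0, 0.3) sensor noise. Noise
SDs are set so that recovery is feasible at the cohort's size while
adjusted R² stays small, as is typical for these outcomes.

**Pathology.** Per-participant coverage rates are Beta-distributed with
means/SDs of 0.826/0.213 (sleep), 0.861/0.189 (steps), 0.12/0.14 (women's
heart rate), 0.02/0.04 (men's), 0.362/0.245 (body temperature); units are
then thinned Bernoulli at the participant's rate. The Beta spread encodes
that adherence varies between wearers far beyond binomial noise, and it is
what gives the gender contrast in heart-rate completeness ≥ 80% power at
the default group sizes. Contaminants exercise every filter: 5%
out-of-range heart rates and body temperatures, 2% over-long nights, 20% of
nights split into two > 3 h episodes (to exercise merging), late-morning
naps on 15% of days, and 2% zero-step days. Episode timing is constructed
so the generator never emits overlapping episodes, which the QC layer
treats as a hard error.

**What passing does not show.** The generator has no circadian
heterogeneity between participants, no participant-level random effects, no
weekday/weekend structure, no autocorrelated adherence ("device died for a
week"), and its missingness is independent of the outcome (MCAR given the
stratum). Recovery and calibration results on it therefore validate the
pipeline's arithmetic and wiring, not the causal interpretability of
pooled-OLS estimates on real field data.

## Numerical and testing choices

- Determinism: every stream derives from one `SeedSequence`; the same seed
  yields bit-identical CSVs, which the pipeline manifest (config hash,
  seed, versions, stage counts) makes auditable.
- Parameter-recovery checks run the full generate → QC → completeness →
  refit loop on 100 seeds at the default study size and require each
  planted effect within ± 2 fitted SE in ≥ 90% of replicates.
- Null calibration uses 200 replicates at a reduced cohort (20
  participants, 60 days): under the null the exposure p-value is uniform at
  any panel size, so the smaller cohort is purely a problem-size choice.
- Holm adjustment follows the step-down formula `adj_(i) = min(1, max_{j≤i}
  (m − j + 1)·p_(j))`; it is monotone and never below the raw p-values, and
  is cross-checked against an independent implementation in the tests.
- The Hodges–Lehmann CI takes the k-th extreme pairwise differences with k
  from the normal approximation to the U null distribution; for very small
  samples it degrades gracefully to the full range of pairwise differences.

## Known limitations

- Pooled OLS ignores within-participant correlation (see above); mixed
  models and distributed-lag heat effects are out of scope.
- The heat index hand-off discontinuity (documented above) means threshold
  counts within ~1 °F of 80 °F depend on the branch rule.
- The WBGT `as_printed`/`literature_swap` ambiguity cannot be resolved from
  aggregate outputs alone; both mappings are provided rather than silently
  choosing one.
- Completeness units are conventions; heart-rate completeness in particular
  scales directly with the chosen slot width.
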
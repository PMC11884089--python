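# Methods

`relacc` implements a cut-point-free analysis of wrist-worn accelerometry in
which every volume and intensity metric is expressed both in absolute terms
and relative to the individual's aerobic capacity, together with a synthetic
cohort generator that makes the whole chain testable against planted ground
truth. This note records the models, the numerical choices, and what the
synthetic data do and do not establish.

## Signal and metrics

**ENMO.** The activity signal is the Euclidean norm of the tri-axial
acceleration minus one gravitational unit, truncated at zero *per sample*
and then averaged over tumbling 5-s epochs, in milli-g (mg). Truncation
order matters: truncate-then-average (used here, matching the standard
processing tools) is strictly larger than average-then-truncate whenever
sub-1-g samples occur within an epoch. Epochs with no samples are missing,
not zero. The epoch grid is anchored at local midnight; partial first/last
days are dropped at ingest. Raw files claiming a post-calibration error
above 10 mg are rejected; the calibration algorithm itself is out of scope
(input is assumed calibrated).

**AvAcc** (average acceleration, mg) is the arithmetic mean of epoch ENMO
over the full midnight-to-midnight day — a proxy for activity volume.

**IG** (intensity gradient) summarises how accumulated time falls off with
intensity: minutes per 25-mg intensity bin are regressed, log–log, on the
bin midpoints (12.5, 37.5, … mg); the slope is the IG. Natural logarithms
(any base gives the same slope); zero-time bins are excluded because log 0
is undefined; bins extend to the day's maximum epoch value with no fixed
cap — a fixed cap would change the number of bins used and hence the fitted
slope slightly. Fewer than two nonzero bins is an error, not a sentinel.

**MX** (mg) is the acceleration above which a person's most active X minutes
are accumulated: the (X·60/epoch_seconds)-th largest epoch value, rank-based
and non-contiguous, computed at the 5-s epoch level. The profile grid is
{1, 2, 5, 10, 15, 30, 60, 120, 240, 360, 480, 600, 720} minutes.

**Relative metrics.** Each participant's maximum aerobic acceleration is
predicted by extrapolating a linear VO2–ENMO calibration to their measured
VO2peak: `max_enmo = (vo2peak − intercept)/slope`. AvAcc and MX are then
expressed as percent of this maximum. The relative IG re-bins each day on
the percent-of-maximum scale in 5 % bins with a single open-ended bin above
300 %; the open bin's midpoint continues the grid at 302.5 % (configurable —
the convention is an interpretation, since only the bin span is standard),
and the first bin starts at 0 % so sub-5 % epochs contribute at midpoint
2.5 %. The shipped default calibration model is a through-the-origin wrist
extrapolation (slope 0.0325 mL·kg⁻¹·min⁻¹ per mg, intercept 0), chosen so
that the median predicted maximum is mutually consistent with the cohort
VO2peak distribution the package is calibrated against; the published
Hildebrand wrist/adult equation (slope 0.0320, intercept 7.28) ships as an
alternative registry entry. No coefficient is hard-coded in computation;
the registry lives in `defaults.yaml`. A VO2peak at or below the intercept
has no positive predicted maximum: the participant is flagged and excluded
from relative metrics rather than given a sentinel value.

## Validity rules

A valid day has wear time ≥ 14 h (inclusive at the boundary). A participant
enters analysis with ≥ 4 valid weekdays plus ≥ 1 valid Saturday and ≥ 1
valid Sunday, and wear covering every 15-min slot of the 24-h cycle.
Coverage is evaluated **pooled across valid days** (any valid day covering a
slot suffices) — the per-day alternative would be unsatisfiable with a
7-day protocol and does not match the cited tooling's semantics; this is an
interpretation and is flagged as such. Before metric computation, non-wear
epochs are imputed with the mean over the same clock-time epoch of the
participant's other valid days (where worn); worn epochs are never touched,
and a slot with no donor anywhere stays missing, which fails coverage
downstream. Metrics are then computed on full imputed 24-h days and
averaged arithmetically across valid days (IG on the slope scale, MX per
grid duration); weekday-only and weekend-only averaging support the
sensitivity analyses.

## Statistical layer

Dependent metrics are Z-transformed (mean 0, sample SD 1). The adjusted
model is OLS of the Z-scale metric on sex, occupation type (reference:
at-least-moderate work-related activity), third-degree polynomials in age
and body-fat percent, season, and employment level — the study's fixed
six-variable adjustment set. Polynomials are orthonormal (three-term
recurrence, equivalent to R's `poly()`); predictions are invariant to this
choice and individual polynomial coefficients are not interpreted.

The paper-style *log before Z* rule is made deterministic: with `auto`, the
dependent is log-transformed before Z when all values are positive and the
residual skewness of the untransformed fit exceeds 1. (IG values are
negative and are never logged.) A CI limit within ±5 % of the interval
width of zero is flagged. Effect sizes on the Z scale are categorised with
left-closed thresholds: small ≥ 0.1, medium ≥ 0.3, large ≥ 0.5.

Marginal means use a balanced grid over categorical covariates and observed
means for continuous ones (the source analysis does not state its grid;
this one is documented and deterministic). Percent differences are computed
on the natural scale: back-transformed (`exp(Δ·sd)−1`) when the log was
applied, otherwise `Δ·sd/|m_ref|` relative to the reference-group
model-implied mean — the absolute value keeps the sign of percent and
Z-scale contrasts consistent for negative-valued metrics such as the IG.
Metric overlap is Spearman correlation plus a PCA (eigendecomposition of
the correlation matrix of the standardized four metrics). MX group profiles
fit each MX grid point with the grouping variable (age band 20–40/41–60/
61–90, sex, or occupation) as exposure, adjusted for body fat, season and
employment, and report balanced marginal means with normal-theory bands.
No multiple-testing correction is applied anywhere; all intervals are plain
95 % CIs. Sensitivity variants re-standardise the dependent within each run.

## Synthetic cohort generator

The generator is the package's test bed: it emulates the *summary structure*
of a healthy adult cohort (n = 460, ages 20–89 uniform, 48 % women;
occupation 29/18/53 % across at-least-moderate / no-work / sitting-standing,
with the no-work category age-ramped so it is dominated by retirees and a
sex tilt placing more women in active occupations; employment conditional
on occupation with small off-diagonal mass so the design stays full rank;
body fat normal by sex; season uniform).

**VO2peak** is log-linear: reference 37.9 mL·kg⁻¹·min⁻¹ (male, age 55, body
fat 20.5 %), −1.04 %/year of age, a *direct* female offset of −7.8 % plus a
body-fat pathway (−1.9 %/point) that, via the sex difference in body fat,
brings the marginal female gap to ≈ −21 %. Splitting the gap matters: an
adjusted regression conditions on body fat, so only the direct part enters
the adjusted sex contrast on relative metrics. Draws below
8 mL·kg⁻¹·min⁻¹ are floored.

**Traces.** A day is a sleep window (23:00–07:00, exponential mean 3.8 mg),
a waking baseline (gamma, shape 2, mean 28 mg), and Poisson activity bouts
(6.8/waking hour; log-normal durations, median 4 min; Pareto intensities,
tail exponent 1.8, mean 102 mg, with duration shrinking as intensity^−0.5 —
vigorous bouts are short). Bouts are needed because i.i.d. epoch noise
cannot reproduce a volume of ~30 mg together with an intensity gradient of
≈ −2.5 and realistic MX profiles. Optional non-wear (one episode, 15 % of
days, median 45 min) zeroes the trace and clears the wear flag.

**Two knobs, one response matrix.** Each person-day is steered by a
whole-trace multiplier (volume) and an intensity-span shift (bout intensity
scaled by `e^v` with the bout rate counter-scaled) — but neither knob is
pure: because the intensity bins are fixed at 25 mg, scaling a trace also
tilts the fitted IG, and the span shift leaks into volume through baseline
masking and duration rounding. The generator therefore measures the 2×2
response of (log AvAcc, IG slope) to (log multiplier, log span) by paired
simulation (`relacc.calibration.measure_knob_response`; frozen values 0.31,
0.315 / 0.24 leak) and *inverts* it: planted effects are specified as
targets on the interpretable scale — sex: +5 % AvAcc and −0.020 IG slope
(women accumulate their extra volume at lower intensities); sitting/
standing occupation: −10.9 % AvAcc (which recovers an adjusted −9.8 % after
the weekday/weekend split and imputation attenuation) and zero IG effect,
consistent with a capacity-neutral occupational contrast; a smooth age
trajectory peaking near age 42 and declining thereafter — and converted to
knob settings so both metrics land on target simultaneously. Person-level
heterogeneity is applied on the raw knobs (volume SD 0.157, span SD 0.25),
which makes AvAcc and IG naturally correlated as in real data, plus a
coupling of 0.711 from the VO2peak residual into the volume knob (fitter
people move more) that gives relative metrics their realistic spread.
Occupation effects load on weekdays (weekend share 0.25 of the weekday log
effect), so weekend-only sensitivity analyses are attenuated by
construction. Saturdays run ≈ 3 % and Sundays ≈ 8 % quieter than weekdays.

**Calibration.** Emergent quantities cannot be written in closed form, so
`relacc.calibration` maps targets to parameters once and the results are
frozen in `defaults.yaml`: an alternating scale/span iteration drives the
cohort median AvAcc to ≈ 30 mg and median IG to ≈ −2.48; the response
matrix is re-measured after any trace-model change; and the sex–IG planting
was centred by common-random-number paired runs (the measured gain is
≈ 4 Z per unit slope target with a small positive offset from the sex
volume effect). A consistency test asserts that `defaults.yaml` and the
dataclass defaults never diverge.

**What the synthetic data do not show.** The generator matches summary
medians, spreads, and the planted contrast structure — not physiology. It
has no circadian structure beyond a sleep window, no heart rate or sleep
architecture, no day-to-day behavioural autocorrelation, no device noise or
calibration drift, and its non-wear is a single random episode rather than
behaviourally patterned. Passing tests therefore demonstrate that the
pipeline recovers known effects of realistic size under realistic marginal
distributions — not that it would be unbiased under every real-world
wear-pattern pathology.

## Problem sizes and determinism

All randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawns (one stream per participant), so cohorts
are bit-identical across runs and platforms. The replicate studies use 20
cohorts of n = 460 for planted-effect recovery and 200 cohorts for the
null (type-I error) calibration; large cohorts are simulated through a
streaming path that reduces each participant-week to metrics immediately,
so memory stays at one participant-week (~1 MB) regardless of cohort size.

## Known limitations

* The IG's dependence on absolute scale (fixed 25-mg bins) means volume and
  gradient effects are intrinsically entangled; the response-matrix
  inversion linearises this locally and is accurate for the planted effect
  sizes (|log effect| ≲ 0.3) but not for arbitrary extrapolation.
* The relative IG's open-bin midpoint (302.5 %) and first-bin convention
  (0–5 % at midpoint 2.5 %) are documented interpretations; both are
  configurable.
* `fit_adjusted_model` is plain OLS; heteroscedasticity of multiplicative
  data on the raw Z scale slightly widens realized type-I error relative to
  nominal, which the null-calibration test bounds empirically.
* Ingest supports the package's own delimited epoch format and plain-text
  raw sample blocks; vendor binary formats, idle-sleep-mode correction and
  timezone/DST handling are out of scope.
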
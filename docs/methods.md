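# Methods

This note records the models implemented by `grainacoustics`, the
parameter choices that matter, and what the synthetic-data generators do
and do not emulate.

## Signal model and impulse detection

Insect feeding/movement sounds in a grain mass are modeled as trains of
brief transients. The detector (`detection.detect_impulses`) makes no
assumption about waveform shape beyond brevity:

* 4th-order Butterworth high-pass at **200 Hz** (forward-backward, zero
  phase) suppresses room rumble below the band where insect impulse
  energy sits.
* The rectified signal is smoothed with a **1 ms** moving average to form
  an envelope; event samples are those above
  `median + k·MAD` with **k = 8** by default. Median/MAD is used instead
  of mean/SD so the impulses themselves do not inflate the noise floor.
  In near-digital silence the MAD collapses to numerical dust, so it is
  floored at 0.1% of the envelope peak.
* Events closer than the **20 ms** dead time merge; events outside
  **0.5–20 ms** are discarded. Insect impulses are 1–10 ms; a 2× margin
  is kept above before an event is called noise. The dead time is well
  below the minimum 30 ms intra-burst gap the generator emits, so
  separate impulses of one burst never merge.
* Onsets are corrected for half the smoothing window's group delay and
  reported at 0.1 ms resolution.

Every constant is exposed in `DetectionConfig`; the defaults were tuned
on the package's own synthetic fixtures (see below) where they recover
> 95% of ground-truth impulses with < 2 ms onset error at the default
signal-to-noise ratio.

Impulse spectra are 256-point one-sided Hann power spectra averaged over
50%-overlapping frames covering the impulse (Welch), normalized to unit
total power. Normalization removes overall gain, which makes the
downstream classification invariant to amplitude scaling.

## Spectral-profile classification

A *profile* is the bin-wise mean of the normalized spectra of verified
insect impulses, renormalized to unit power. A new impulse is compared to
each profile by the sum of squared bin differences (SSE); the best profile
is the argmin (ties to the first in list order) and the impulse is
accepted as an insect signal iff its best SSE is at or below a threshold.
Comparison is on the power scale; a zero-mean dB option exists for
emphasizing low-power structure but is not the default.

The numeric threshold is not dictated by the matching idea itself, so it
is a config value with a default (**0.044**) calibrated on synthetic
fixtures (`scripts/calibrate_threshold.py`): the geometric midpoint
between the insect upper tail (max SSE ≈ 0.005 over ~500 verified
impulses) and the distractor lower tail (min SSE ≈ 0.40). At that value
the distractor false-match rate on the calibration scenes is 0%, well
inside the ≤ 5% design goal, and the insect miss rate is 0%. The margin
is wide because the default insect (4 kHz) and distractor (0.5 kHz)
kernels occupy disjoint bands; narrower-band noise sources would shrink
it.

Two default profiles ship with the package, mirroring the field practice
of matching against a pair of verified-infestation templates (one
averaging 139 impulses over a 62-s interval, one 33 impulses over 20 s).
They are synthetic stand-ins rendered from the package's own impulse
model (`scripts/build_default_profiles.py`); any number ≥ 1 of
user-supplied profiles (CSV + JSON sidecar) is supported.

## Bursts, activity measures, thresholds

A *burst* is a maximal run of ≥ 3 insect-matched impulses in which every
consecutive gap is **strictly** under 200 ms; a gap of exactly 200 ms
splits. For a segment of duration *T* with bursts *B₁…B_n* of sizes
*k₁…k_n*:

* *R_b* = *n*/*T* (bursts·s⁻¹)
* *N_b* = (Σ*k_i*)/*n*, **missing** (NaN, never 0) when *n* = 0
* *R_bimp* = (Σ*k_i*)/*T* (impulses·s⁻¹), so *R_bimp* ≥ 3·*R_b*

The infestation threshold of **0.02 bursts·s⁻¹** is inclusive: 0.02 is
the *minimum* rate at which infestation is considered likely. Quiescence
— the proxy for cessation of economically damaging activity — requires a
*sustained* crossing: the first observed day from which the rate stays
below threshold at every later observation. A single-point dip does not
qualify because day-to-day rates are non-monotone (a silent day can be
followed by a rebound).

## Hermetic-storage analysis

**Oxygen budgets.** Volumes are percentages of the jar's air volume
(defaults: 260 ml air in wheat-filled 500-ml jars, 480 ml in 1000-ml
jars, with ambient O₂ at 21%); an alternate entry point accepts measured
initial/final volumes directly. Per-insect consumption is
(initial − final)/n, and initial = final + n·consumed holds exactly.

**Crossing times.** Times to 5% and 2% residual O₂ interpolate linearly
between the bracketing observations — the minimal assumption consistent
with reporting fractional days — with 0 when the series starts at or
below target and "never" as None. The depletion-rate statistic is the
jar population divided by days-to-2%, reported to 2 decimals.

**Regressions.** The pooled activity models are ordinary least squares of
a transformed response on O₂ depletion (percentage points):
`Log10(measure/N_t + 1)` for the rates *R_b* and *R_bimp* (per-insect
normalization puts treatments of different density on one scale; the
+1 log transform tames their dynamic range) and the identity for *N_b*,
whose natural range is already a narrow 3–6. Depletion is computed from
each replicate's **own first reading**, not the nominal 21%, so day-one
spread between jars is respected. Records with undefined *N_b* are
dropped (count warned). Reference coefficients are stored exactly as
printed on a ×10⁻³ scale with the scale explicit, to avoid magnitude
bugs. Each `RegressionFit` self-checks the F–R² identity
`F = (R²/(1−R²))·(df_den/df_num)` to 1e-6, and because depletion is an
affine flip of residual O₂, fits against either axis have slopes equal in
magnitude, opposite in sign, with identical R². Per-treatment fits
(`fit_treatment_regression`) are untransformed OLS reporting R², error
variance s² and s.

**Grain quality.** Count-and-weigh weight loss is
`100·(ND·WU − NU·WD)/(WU·(NU+ND))`; algebraically zero when damaged and
undamaged per-grain weights are equal, negative (returned with a warning)
only on pathological inputs. Germination capacity is total germinated
over total seeds across replicate dishes of 25.

## Synthetic-data generators

**Acoustic scenes.** The impulse kernel is a damped sinusoid — raised-
cosine onset (≤ 0.5 ms), exponential decay, two-tone carrier spreading
energy across the stated band — rendered with `round(duration·rate)`
samples (ties to even) and renormalized so the peak equals the requested
amplitude exactly. Only duration and train structure of real impulses are
constrained by observation; the waveform shape is this package's choice.
Burst starts follow a homogeneous Poisson process thinned to keep
consecutive bursts more than 200 ms apart (so ground-truth bursts remain
distinct under the grouping rule); scenarios whose rate cannot maintain
that spacing are rejected. Bursts hold 3–6 impulses (uniform) with gaps
uniform on 30–150 ms; per-impulse amplitude jitters uniformly on
0.7–1.0× to avoid unrealistically identical events. Distractors are
low-frequency (500 Hz) broadband thuds — the typical background noise
class — placed as isolated events at least 250 ms from any burst, and the
scenario constructor rejects distractor kernels whose normalized spectrum
has cosine similarity ≥ 0.9 with the insect kernel, so rejection is
always testable. Gaussian noise of configurable RMS is added last. The
default detection SNR is 10 (kernel peak 0.5 over noise RMS 0.05) — an
engineering choice, since no amplitude calibration for real recordings is
available. All generators are bit-reproducible under a fixed seed.

**Experiments.** Residual O₂ follows
`O₂(t) = floor + (21 − floor)·e^(−rt)` with floor 0.2% and
`r = c·n_insects/air_volume` per day. The exponential-toward-a-floor
shape reproduces the qualitative record — most depletion within the
first ~11 days, denser treatments in smaller jars crossing 5% and then
2% earlier — and the default **c = 2.1** (ml-equivalent per insect-day)
is a geometric-mean compromise: a rate strictly proportional to density
cannot match both ends of the observed time range (the extreme densities
differ 7.4-fold but the observed times-to-2% only 2.6-fold), so the
default gives ~3 days for 100 insects/500 ml and ~22 days for
25 insects/1000 ml while preserving the ordering. Activity is generated
by inverting each regression model at the row's depletion, adding
Gaussian noise **on the transformed scale**, back-transforming, and
flooring at zero; rows whose burst rate floors to zero get *N_b* = NaN
(no bursts ⇒ impulses-per-burst undefined) and *R_bimp* = 0. The three
measures are drawn from their marginal models, not jointly, so the
*R_bimp* ≥ 3·*R_b* identity of measured data is not enforced across
columns. Default noise SDs (1.8×10⁻³ for the *R_b* response, 0.7 for
*N_b*, 11.5×10⁻³ for *R_bimp*) are back-derived from the published slope
standard errors via SE(b) ≈ σ/(sd(x)·√n). The zero-flooring censors
late-depletion records and attenuates fitted slopes slightly; the
slope-recovery simulation (200 seeded replicates of ~36 observations
over the first 3 storage days across all six treatments) still covers
the generating slope with its 95% CI in ~94% of replicates.

**Grain counts.** Per-grain undamaged weights jitter around a nominal
45 mg wheat kernel; the number of damaged grains is chosen so each lost
~30% of its weight, and the damaged-portion weight is then solved in
closed form so the count-and-weigh formula returns the requested loss
exactly.

## Problem sizes and runtime

The test suite analyzes scenes of 30–120 s and the acceptance script ten
100-s scenes plus 200 simulated experiments; these sizes give stable
statistics (hundreds of impulses, tens of bursts per evaluation) while
keeping a full run in tens of seconds on one core.

## Known limitations

* The synthetic scenes contain stationary Gaussian noise and one
  distractor class; real recordings have nonstationary interference,
  reverberation, sensor/waveguide coloration, and overlapping impulses
  from multiple insects. Passing round-trip tests therefore demonstrates
  internal consistency of the pipeline, not field performance.
* The O₂ model is a single exponential per jar; it ignores grain
  respiration, temperature/humidity dynamics, and immature life stages.
* Published R² values for the pooled activity fits depend on the original
  raw data and are not reproducible from synthetic data; the package
  instead verifies direction, parameter recovery, and the F–R² identity.
* Inferential ANOVA/ANCOVA machinery (multiple-comparison letters) is out
  of scope; `summarize_treatments` stops at means ± SEM.
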
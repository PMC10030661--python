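# Methods

`bpbench` is a benchmark harness for machine-learning estimation of blood
pressure (BP) from the photoplethysmogram (PPG). It implements the full
chain a fair comparison needs — signal cleaning with an audited removal
cascade, BP label extraction from arterial blood pressure (ABP) waveforms,
a handcrafted PPG feature catalog, subject-grouped multi-label stratified
validation splits, and MASE-centred evaluation with bootstrap model
comparison — and ships a synthetic paired PPG/ABP generator so that every
stage is testable end to end without clinical waveform downloads.

## The synthetic waveform family

Real datasets provide measured waveforms; this package instead needs a
*controllable* family whose ground truth (labels, landmark positions,
artifact tags) is known exactly. Each cardiac cycle is a sum of Gaussian
lobes:

* an asymmetric **systolic lobe** (rise σ = 0.09 T, fall σ = 0.16 T, peak at
  0.28 T for cardiac period T) — fast upstroke, slower decline;
* a small **ripple** on the downslope (σ = 0.12·d, amplitude tied to the
  dicrotic depth, centred 0.35·d after the peak for notch delay d) — it
  gives the second derivative its conventional c-wave/d-wave wiggle;
* a **dicrotic lobe** (σ = 0.30·d, amplitude = `notch_depth` of pulse
  amplitude) whose centre is *calibrated*: a damped fixed-point iteration on
  a dense noiseless grid moves the lobe until the analysis chain's own
  dicrotic-notch landmark *e* (second-derivative criterion, below) falls
  exactly `notch_delay` seconds after the systolic peak. Generator ground
  truth and analysis therefore agree by construction, to sample-grid
  resolution.

ABP is the periodic shape rescaled to [DBP, SBP] mmHg. PPG is the same
shape, unit-amplitude in [0, 1] (no subject scaling or calibration is
assumed anywhere downstream), delayed by the pulse-arrival lag `ppg_delay`,
plus optional sinusoidal baseline wander and white noise. Records start
just after a systolic peak so the first onset valley is an interior,
detectable extremum, and cohort records are one second longer than a
segment so cross-correlation alignment can consume samples.

The calibration is exact for notch delays between 0.18 and 0.33 of the
cycle and dicrotic depths up to ~0.6 (values outside are clamped); cohort
sampling draws from the interior of that regime (delay 0.24–0.30 of the
cycle, depth 0.25–0.45). The family is explicitly *not* a hemodynamic
model: it carries the landmarks and the statistical structure the pipeline
consumes, nothing more.

### Cohorts

Subjects draw a latent (SBP, DBP) from a shifted log-normal family
parameterized by (mean, sd, skew) — three interpretable parameters matching
the right-skewed BP distributions of clinical cohorts; a negative skew
mirrors the distribution and skew 0 degenerates to a normal. Draws with
pulse pressure below 15 mmHg are rejected and resampled (the rejection rate
is reported). Segments within a subject jitter by `within_subject_sd`
(default 4 mmHg SBP, half that for DBP), which makes a subject's segments
correlated — the property the leakage experiments depend on. Presets
reproduce the published summary statistics of four open datasets
(mean/SD of SBP/DBP, segment length, segments per subject); the skew
parameter is set to 0.5 everywhere, a mild right skew consistent with the
min/max ranges those tables report but not printed by them. Default cohort
noise is small (noise SD 0.003 of pulse amplitude, baseline wander 0.04 at
0.25 Hz): enough to exercise the filters without degrading the derivative
landmarks, since quality-failing signals are the *artifact* channel's job.

Artifacts are injected with ground-truth tags, each violating exactly one
filter criterion: `flatline` (no cycles), `amplitude_spike` (PPG
peak-amplitude distortion), `extreme_bp` (ABP above 220 mmHg), `low_pp`
(pulse pressure under 10 mmHg), `tachy`/`brady` (rate outside 35–140 BPM),
and `bw_drift` (0.2 Hz wander — corrected, not removed). The default
injected mix excludes `bw_drift` so that "tagged" means "must be removed",
which is what the recall experiments measure.

## Cleaning pipeline

Steps, in audit order:

0. **Align + segment.** PPG is advanced by the lag maximising the absolute
   cross-correlation of the mean-removed signals, capped at ±1 s; both
   signals are truncated to the overlap and cut into non-overlapping
   segments (default 5 s; 2.1 s for short-recording presets).
1. **ABP plausibility.** A segment fails if any ABP sample leaves
   [30, 220] mmHg, the median per-cycle pulse pressure is not above
   10 mmHg, the cycle rate is outside [35, 140] BPM, or no cycles are
   identifiable. All violated reasons are recorded (a segment can fail
   several). Survivors get labels: SBP = median of cycle-peak pressures,
   DBP = median over the pooled multiset of onset and offset pressures
   (plural onsets/offsets pooled before one median; an even count averages
   the central pair).
2. **PPG cycle identification.** Peaks/valleys are local extrema with
   prominence ≥ 60% of the segment's interquartile amplitude range and
   spacing ≥ one period at 220 BPM; a cycle is a valley pair with exactly
   one peak between. Failure reasons: no cycles, or a median peak-to-peak /
   valley-to-valley rate outside [35, 140] BPM. The prominence criterion
   (not spacing) rejects dicrotic bumps — a spacing threshold at the
   140-BPM bound would also suppress the alternate peaks of tachycardic
   signals and hide the very violation being screened.
3. **Distortion.** Four per-segment sample SDs (n−1): peak-to-peak and
   valley-to-valley intervals (seconds) and peak/valley amplitudes. A
   segment fails if any exceeds its threshold. Default thresholds are
   explicit absolute values (0.15 s for intervals, 0.12 amplitude units on
   unit-amplitude PPG), the analogue of choosing thresholds by inspecting
   cumulative-percentile plots per dataset. A percentile mode (default
   q = 97.5) derives thresholds from the candidate population instead;
   derived thresholds are floored at 2 samples for interval SDs and 2% of
   the median pulse amplitude for amplitude SDs, so sample-grid
   discretization jitter on clean data is never auto-flagged, and they are
   recorded in the audit. Percentile thresholds are *contamination
   sensitive*: with heavy artifact fractions the percentile sits inside the
   contaminated tail, which is why explicit thresholds are the default.
   With fewer than three cycles the statistics are undefined; such
   segments pass by default (configurable to auto-fail).
4. **Baseline wander removal + re-check.** A natural cubic spline through
   the (valley index, valley value) knots estimates the baseline, extended
   beyond the terminal knots by their constant values; the corrected signal
   is the original minus the baseline (corrected valleys ≈ 0). Cycle and
   distortion checks are re-run on the corrected signal.
5. **Feature-generation failures.** Segments for which any landmark or
   feature cannot be computed are removed, with the missing point's name
   recorded.
6. **Skewness quality index.** Segments whose PPG sample skewness
   (Fisher–Pearson, m₃/m₂^1.5) is strictly below 0 are removed;
   zero-variance segments are removed as degenerate.

The audit table stores, per step and criterion, deleted and kept counts
(segments, subjects, records); kept(k) = kept(k−1) − deleted(k) holds
exactly, and re-running the pipeline on its own kept segments removes
nothing. PPG-side filters never read ABP and vice versa.

## Feature catalog

Landmarks per cycle: systolic peak **s** on the PPG; **w, y, z** on the
first derivative (VPG) — maximum upslope in (o, s), maximum downslope in
(s, f), and the highest interior VPG maximum after y (diastolic rise);
**a–e** on the second derivative (APG) — a = max in (o, s), b = global min
after a, c/d = next local max/min after b, and **e** (the dicrotic notch) =
the last *positive* APG local maximum before the most negative diastolic
APG minimum (the dicrotic wave). The positivity and before-the-dicrotic-
wave constraints reject smoothing micro-wiggles and boundary-valley
curvature that a bare "maximum after d" rule picks up.

Landmark *search* runs on Savitzky–Golay cubic polynomial derivatives of
the PPG with a window of 14% of the cycle (clamped 50–120 ms): raw
difference derivatives amplify white noise roughly by fs per order, which
destroys the APG chain at realistic noise levels. Reported VPG/APG
*amplitudes*, however, always come from plain central differences (scaled
by fs and fs²; one-sided at the ends).

Per cycle the catalog computes: elapsed times between all ordered pairs of
{o, w, s, e, z, f}; PPG/VPG/APG amplitudes at all eleven landmarks;
trapezoidal areas of the cycle-minimum-referenced PPG over [o,w], [w,s],
[s,e], [e,f] with A_sys = A1+A2 and A_dia = A3+A4 (the boundaries w, s, e,
f are the most robust landmarks either side of the peak); systolic and
diastolic widths at 25/50/75% elevation with linear-interpolated crossings,
plus their sums and ratios; 5-bin systolic and 10-bin diastolic histogram
densities for each of PPG/VPG/APG with per-phase min–max bin ranges (PPG is
unscaled, so global ranges would be meaningless); slope-deviation-curve
features (mean absolute deviation of each phase from its straight chord,
normalized by pulse amplitude); cycle skewness and excess kurtosis; and the
APG indices AI = (b−c−d−e)/a, I_bd = b/d, I_bcda = (b−c−d)/a, and I_sdoo.
The I_sdoo convention is not fixed by the literature this index descends
from; this package defines it as the diastolic-to-systolic duration ratio
(t_f − t_s)/(t_s − t_o) and isolates the formula in one function so it can
be swapped. Frequency features (dominant frequency in 0.5–8 Hz, its
magnitude, and the mean magnitude within ±0.5 Hz excluding the peak bin)
are computed once per segment on the mean-removed spectrum. Per-segment
aggregation across cycles is the median — robust to one residual odd cycle.
The 122-name schema is fixed and identical for every segment.

Scale behaviour, by design: times, widths, histograms, SDC, skewness,
kurtosis and the APG indices are amplitude-invariant; PPG amplitudes and
areas scale linearly.

## Validation splitting

SBP is encoded into 4 classes (cut points 100/140/160 mmHg) and DBP into 4
(60/80/100 mmHg), giving 16 joint classes; intervals are half-open
[lo, hi), so a value on a boundary belongs to the upper class. Each
subject's segments are tallied over the 16 classes, and subjects are
assigned whole to folds by iterative stratification generalized to
count-weighted rows and unequal fold weights: repeatedly take the class
with the fewest remaining examples, within it the subject richest in that
class, and assign to the fold with the largest remaining desideratum for
that class (ties: total remaining desideratum, then seeded randomness).
Subject-grouped splits have zero leakage by construction. The same engine
with fold weights (0.6, 0.2, 0.2) produces the hold-one-set-out split;
when subject identifiers do not exist, records act as pseudo-subjects and
the assignment carries an explicit leakage caveat. A deliberately wrong
baseline, `leaked_split`, assigns *segments* uniformly at random and
reports the fraction of segments whose subject spans folds.

## Evaluation

ME, SD (n−1), and MAE are computed on predictions pooled across folds —
never by averaging per-fold metrics, which would weight folds equally
regardless of size. MASE = 100 · MAE / MAE_naive (reported in percent),
where the naive prediction for each fold is that fold's training-mean
label, pooled the same way; the naive model never sees its test fold, and
its own pooled MASE is exactly 100. MASE is invariant to rescaling all
pressures, which is what makes it comparable across cohorts with different
BP spreads. Waveform-output models are scored by re-running the cycle
detector and label extractor on the predicted ABP; undetectable cycles are
counted as missing predictions.

Model comparison uses a paired bootstrap: segment indices are resampled
with replacement (the same replicate indices for both models), MASE_A −
MASE_B is recomputed per replicate (2000 by default), and percentile
intervals are formed at levels 1 − α/m with Bonferroni m = the number of
pairwise tests drawn together, for α ∈ {0.05, 0.01, 0.001}. The
significance mark is the smallest α whose corrected interval excludes 0.
The bootstrap operates on MASE (the quantity being compared), not MAE.

## Feature selection and tuning

Feature importance is the mean decrease in impurity across a fully grown
random forest and a fully grown extremely-randomized-trees ensemble (500
trees each, fit independently per target), normalized to sum to one;
selection takes the top ⌈rate · n⌉ names. Hyperparameters are grid-searched
(family grids × selection rates 0.05–1.0) with subject-grouped stratified
inner 5-fold CV on the training partition only, monitoring inner-validation
MAE; ties prefer fewer features, then grid order; the winner is refit on
the whole training partition. Ranking, threshold derivation and tuning
never touch the test fold (enforced by an access-tracking test).

## Problem sizes and numerical choices

The shipped experiments use deliberately modest cohorts — typically 25–100
subjects with 3–8 five-second segments each at 125 Hz — chosen so the full
generate→clean→featurize→split→fit→evaluate loop, the 100-seed selection-
recovery experiment, and the leakage comparison all run comfortably on a
single CPU; the statistical contrasts they probe (naive identity, leakage
direction, recall on tagged artifacts, affine-HR learnability) are large
by construction and do not need bigger samples. Determinism: all
randomness flows through integer seeds (`numpy` Generator); identical
(spec, seed) reproduce bit-identical records, and splits, forests and
bootstraps are seed-stable.

Degenerate inputs are handled explicitly: constant signals are
alignment-undefined and cycle-free; constant phases give a single-bin
histogram density; zero pulse amplitude flags width/SDC failures; constant
labels make MASE undefined (raised, never silently 0); fewer than two
distortion intervals yield NaN statistics that pass by default.

## What passing tests do and do not show

The synthetic generator emulates the *structure* of paired PPG/ABP cohorts
(landmarks, skewed labels, within-subject correlation, filterable
artifacts), not their physiology: morphology variation across subjects is
parametric and narrow, noise is white and stationary, artifacts are
archetypes, and the PPG–BP relationship in the learnability experiments is
planted (SBP affine in heart rate). Passing the suite therefore
demonstrates that the *harness* is correct — filters remove what they
claim, splits do not leak, metrics obey their identities, selection
recovers planted signal, and leakage inflates scores in the documented
direction — but says nothing about how accurately any model estimates BP
on real patients. Known limitations: no motion-artifact repair or adaptive
filtering (only removal), no resampling beyond plain polyphase decimation,
deep signal-input models enter only through the fit/predict plugin
contract, and the landmark chain assumes a detectable dicrotic complex
(signals without one are removed at the feature-generation step, which is
the intended behaviour).
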
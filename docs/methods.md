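# Methods

`ccepflow` re-implements, as tested and reusable code, an effective-connectivity
analysis of stimulation-evoked intracranial EEG for predicting the outcome of
temporal-lobe-epilepsy surgery. Because the underlying patient data are not
public, the package pairs the analysis pipeline with a calibrated synthetic
cohort generator, so that every stage — electrode localization, signal
conditioning, connectivity features, group statistics, outcome classification,
Shapley attribution — can be exercised end to end and checked against
published cohort-level numbers.

## The analysis model

**Edges and zones.** Depth-electrode contacts are re-referenced to a bipolar
montage; each adjacent same-shaft contact pair defines a channel located at the
pair's midpoint. Channels are labelled by three binary attributes: gray matter
(a 3×3×3-voxel cube around the midpoint voxel must contain ≥ 24 voxels with
gray-matter probability > 0.1), resection membership (the midpoint's nearest
voxel inside the binary resection mask), and clinical SOZ designation (SOZ
channels must lie inside the resection). Single-pulse stimulation of one
bipolar pair and recording at another defines a *directed edge*. Retained
edges exclude the stimulated shaft, non-gray channels, and channels closer
than 10 mm (Euclidean, strict) to the stimulated pair's midpoint.

**Features.** Each retained edge's trial-averaged response is summarized by
the RMS amplitude of the early (N1, 10–50 ms post-pulse) and late (N2,
80–250 ms) components, half-open windows at 1000 Hz (40 and 170 samples).
RMS values are z-scored within patient, per component, over all retained
edges pooled (sample SD). Edges are assigned to three categories by zone —
IR (SOZ ↔ in-resection non-SOZ), OR (SOZ ↔ outside resection), IO
(resection ↔ outside; a strict superset of OR because the SOZ lies inside the
resection) — each split by direction (OUT: stimulated on the source side;
IN: recorded there). A patient's 12 features are the mean z-scored RMS per
category/component/direction. With four numeric and five single-column binary
clinical covariates (age at onset, age at surgery, duration, ASM count;
laterality, hippocampal sclerosis, MRI positivity, GTCS, memory), the
predictor table has exactly 21 columns.

**Statistics.** Continuous two-group comparisons run Shapiro–Wilk normality
checks per group and a median-centred Levene variance check at the 0.05 gate:
all pass → two-sided Student's t; otherwise two-sided Mann–Whitney U
(asymptotic, tie-corrected). Categorical 2×2 tables use the Yates-corrected
chi-square (this choice reproduces all three checkable published p-values:
0.030, 0.442, 1.000). The 12 feature comparisons form one
Benjamini–Hochberg FDR family per run.

**Classifier.** Features are z-scored and split 3:1 (stratified,
largest-remainder rounding: 30/26 → train 23+19, test 7+7). A linear
soft-margin SVM (labels SF→−1, nSF→+1; positive class = recurrence) is tuned
over C ∈ {0.01, 0.1, 1, 10, 100} by mean accuracy over 5 stratified folds
inside the training set, ties to the smallest C. Headline metrics are the CV
fold means (accuracy, sensitivity = nSF recall, specificity, F1) and the
held-out test ROC/AUC from decision scores. Two scaling modes exist:
`train-only` (default; scaler fitted on the training partition) and
`study-literal` (z-scores over the full table *before* splitting — the order
the source procedure describes, which leaks test statistics into the scaler;
it is reproduced deliberately for comparability, never silently "fixed").

**Attribution.** For the linear decision score f(x) = w·x + b with the
training set as background, the Shapley value has the closed form
φᵢ = wᵢ(xᵢ − mean background xᵢ). A model-agnostic Monte-Carlo permutation
estimator with background-replacement imputation (default 2000 permutations,
seeded) is provided alongside and validated against the closed form; local
accuracy (Σφ = f(x) − mean background f) holds exactly in closed form and
within Monte-Carlo error for the estimator. Ranking is by mean |φ|.

## The synthetic cohort

The generator states a world and does not revisit it; all defaults were fixed
before any acceptance measurement.

**Geometry.** Anatomy is abstract: straight shafts in a 1 mm isotropic
synthetic volume (128³ by default, 96³ in the reduced desk-scale
configuration). Shaft count is a rounded normal (11.96 ± 2.00, clipped to
[4, 16]; cohort value), contacts 8–16 per shaft at 3.5 mm pitch (2 mm contact
+ 1.5 mm gap). The resection is a sphere with volume ~ N(17.08, 4.19²) cm³
(clipped to [6, 32]); a gray-matter probability field is a smooth random
field with ~75% of voxels above the 0.1 threshold.

The in-resection channel count is deliberately small and exact: shaft A
grazes the sphere with exactly `n_soz_channels` midpoints inside (the SOZ),
shaft B with `n_ir_channels` inside on roughly the opposite side, and all
other shafts stay clear of the sphere. The reason is a hard feasibility
constraint of the feature definition: with within-patient z-scores over the
pooled edge set, a category holding a fraction f of the pool cannot have a
mean z above √((1−f)/f), and the category means must satisfy
Σ f·z̄² ≤ 1. The published group profile (IO-N2-OUT up to 2.33) therefore
requires resection-crossing edges to be a small minority of the pool. For the
same reason the reduced configuration uses 5–6 shafts (the upper half of the
4–6 band; at 4 shafts the budget is violated and those means are unreachable),
and the between-edge amplitude spread (lognormal CV 0.30 per edge, 0.15
per-patient class jitter) fills the ~0.24 of unit variance the budget leaves.
A verify-and-retry loop guarantees that every one of the 12 categories has at
least one admissible edge (different shaft, ≥ 10 mm, gray recording channel)
and that each zone contains gray channels.

**Signals.** Stimulation follows the published protocol (6 mA biphasic,
300 µs phase — metadata; 40 trials at 0.5 Hz). Each session yields
contact-level epochs (−500…+1000 ms) at 2000 Hz (the acquisition rate is not
stated in the source; 2000 Hz is the simulator default, chosen as the
smallest integer multiple of the 1000 Hz target that respects the 300 Hz
band edge). The evoked response of every bipolar edge is
a1·N1(t) + a2·N2(t): N1 a negative Gaussian (peak 25 ms, σ 8 ms), N2 a
broader Gaussian (centre 160 ms, σ 45 ms) whose onset is tapered to zero
with a raised cosine over 60–80 ms — without the taper, zero-phase filter
ringing smears ~13–15% of the (much larger) late amplitude into the early
window and the two components cannot be calibrated independently. Contact
traces are cumulative sums of the bipolar evoked responses along each shaft,
so the bipolar montage recovers the intended edge waveforms exactly; noise is
per-contact pink (1/f) background (15 µV), line sinusoids at 50 Hz and two
harmonics with random phase (20 µV), and a 5 ms decaying stimulus artifact
scaled by distance (150 µV at the site). Amplitudes are drawn per directed
edge class (stimulated zone → recorded zone), per outcome group.

Because all conditioning steps are linear and RMS is computed on the trial
average, the simulator can emit the trial average directly
(`collapse_trials`): one pseudo-trial with noise scaled by 1/√40. This is
statistically identical to simulating 40 trials and averaging (a consistency
test checks it) and ~40× cheaper; all large runs use it.

**Zero-phase filtering.** The cascade (notches at the line frequency and
harmonics up to 300 Hz at Q = 30, then a 4th-order Butterworth 1–300 Hz
bandpass) is applied with zero phase by multiplying the squared magnitude
response in the frequency domain — the textbook meaning of forward–backward
filtering — which is far cheaper on batched epochs than `sosfiltfilt` and
agrees with it away from epoch edges (tested); `method="sos"` selects the
padded time-domain route. Note one measured property: after the full chain,
~1.3% of white-noise power remains above 320 Hz. That is the 4th-order
filter's own 320–440 Hz shoulder, not decimation aliasing, and is inherent
to the stated filter order.

**Amplitude calibration.** The map from per-class amplitudes to group feature
means is nonlinear and coupled through each patient's pooled mean/SD.
Calibration inverts it in two nested loops. The inner loop is a fixed point
on the six feature-relevant class amplitudes (per component and group) using
a surrogate of the pipeline that is exact up to Monte-Carlo error: unit
templates pushed once through the real filter chain give the window Gram
matrices; the noise floor is measured from a zero-amplitude run of the real
pipeline; lognormal spreads are drawn exactly as the simulator draws them,
with common random numbers frozen across iterations so the map is
deterministic. Updates are leak-aware (the other component's Gram
contribution to the window is subtracted before inverting) with sign-adaptive
per-class step sizes. The outer loop (3 rounds of 96 patients per group) runs
the *real* signal pipeline, measures the residual bias of each category mean,
and shifts the surrogate's targets by the bias, shrunk in proportion to the
measurement's standard error so the one-edge IR categories (per-patient SD
≈ 1.2) do not inject noise. Calibration fails loudly with residuals if the
iteration budget (100 per solve) is exhausted — which happens, by design,
when a target violates the feasibility budget above.

**Feature-level mode.** For model-focused experiments the 12 features are
drawn directly from per-group Gaussians (independent by default; a Gaussian
copula can be configured — the source reports only that no |r| exceeded 0.8).
Targets default to the published profile: the four OUT features of OR/IO
differ between groups (OR-N1 0.72±0.30 → 0.95±0.29; OR-N2 0.96±0.26 →
1.30±0.34; IO-N1 1.43±0.78 → 1.90±0.90; IO-N2 1.77±0.86 → 2.33±1.11); the IN
counterparts get half the OUT group difference (reported as model-relevant
but not univariately significant); IR features are equal across groups
(N1 1.0±0.4, N2 1.3±0.5 — magnitudes not published, chosen as plausible
strong local connectivity). Clinical covariates follow the cohort table:
per-group Bernoulli rates for the binary variables (e.g. GTCS 11/30 vs
18/26), scaled-Beta ages/durations matching the per-group medians and ranges
(no distribution family is published), ASM counts N(3.0, 1.0) / N(3.5, 2.5)
rounded and clipped to [1, 8]. The "null cohort" used for calibration checks
equalizes *all* group-dependent distributions at the whole-cohort rates —
not only GTCS — since laterality/MRI/memory rates also differ between groups
and would otherwise leak outcome signal.

## What a green test does and does not establish

The generator reproduces the *cohort-level stated world*: group means/SDs of
the 12 features, clinical prevalences, sample sizes, protocol constants, and
outcome-independent electrode coverage. It does not emulate real anatomy,
volume conduction, ictal activity, latency/morphology variation,
between-feature correlation (unless configured), or any within-patient
coupling between connectivity and clinical covariates. Green acceptance
tests therefore establish that the *pipeline implements the stated analysis
correctly and that the published cohort-level numbers are consistent with
the published group profiles* — not that the biological claims are true.

One reported finding is *not* reproducible from the printed numbers alone
and its test is deliberately left failing: that the two most important
SHAP features are OR_N2_out and OR_N1_out. In this world OR_N2_out does rank
first in a plurality of replicates, but the binary clinical covariates —
GTCS above all, at the cohort's own 11/30 vs 18/26 rates — carry an effective
standardized effect (~0.65, amplified by the larger mean absolute deviation
of a standardized binary column) that displaces OR_N1_out (~0.62) from rank
2 in most replicates. Forcing the pair would require suppressing covariates
the cohort table itself reports as group-different, or inflating OR_N1_out
beyond its printed value.

## Numerical choices and degenerate inputs

- Midpoint→voxel rounding is half-up (`floor(x+0.5)`), not banker's.
- Gray-matter binarization is strict `> 0.1`; the cube rule is `>= 24` of 27.
- The 10 mm exclusion is strict `<`; exactly 10.0 mm is retained.
- Dice of two empty masks is defined as 1.0 (logged).
- Baseline correction subtracts the mean over [−500, −10) ms.
- Z-scores use the sample SD (ddof = 1); fewer than 2 edges or zero variance
  raise a degenerate-input error, as do empty feature categories (naming
  them).
- Grid-search ties go to the smallest C; the split's largest-remainder ties
  go to the larger class. Split totals are `round(0.75·n)`.
- SVM precision/F1 use the zero-division convention precision = F1 = 0 when
  no positive predictions exist.
- Every random draw derives from one global seed via named per-stage
  `SeedSequence` substreams; reruns are bit-identical (manifest-hash tested).

## Known limitations

- IR category means are estimated from 1–2 edges per patient; their
  calibration accuracy is bounded by measurement noise (per-patient SD
  ≈ 1.2) and they wobble by ~0.1–0.3 around target. OR/IO categories
  calibrate to within ~0.05.
- Ages at onset/surgery and duration are sampled independently; the identity
  age_surgery ≈ age_onset + duration is not enforced.
- The study-literal scaling mode intentionally reproduces a leakage; use the
  default train-only mode for honest error estimates.
- Signal-level runs price at roughly 0.35 s per patient (reduced geometry,
  collapsed trials, one CPU); the calibrated 20-seed acceptance experiment
  takes ~8–10 minutes.
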
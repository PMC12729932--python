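# Methods

This package implements an evaluation framework for preprocessing
pipelines applied to intraoperative microelectrode recordings (MER)
before feature-based classification of the subthalamic nucleus (STN).
The question the framework answers is not "which classifier is best" but
"how much do artifact rejection, outlier management and feature
normalization choices move the classification result" — so every
component is built to be crossed with the others and compared under a
common cross-validation harness.

## The synthetic cohort

Clinical MER datasets of this kind are private, so the framework ships a
generator that emulates the acquisition geometry and the statistical
structure the classifiers rely on, with known ground truth.

Each patient contributes two hemispheres, each explored by three parallel
electrodes (anterior, central, posterior) advancing in 1 mm steps from
+10 mm above the estimated target to −5 mm beyond it; one 10 s trace at
24 kHz is recorded per depth. Per trajectory, an STN interval is drawn
(entry depth uniform in [−1, +1] mm, extent uniform in [3, 5] mm) and
depths inside it are labeled STN. Labels therefore come from the
simulated anatomy, standing in for expert annotation.

A trace is Gaussian background noise plus a Poisson spike train convolved
with a 1.2 ms biphasic (difference-of-Gaussians) template. Class
parameters (defaults): firing rate 35 vs 8 Hz, spike amplitude 4.0 vs 1.5
times the noise SD, noise SD 12 vs 6 µV for STN vs non-STN, and a 20 Hz
(beta-band) sinusoidal amplitude modulation of STN spiking with depth
0.4. The STN parameter set strictly dominates the non-STN one — a
validated config invariant — so the two classes are learnably different;
no quantitative signal model exists for the real contrast, and these
effect sizes are deliberately generous: with them, the default cohorts
are close to perfectly separable, which is the regime the structural and
hygiene checks want (a classifier failure then indicates a harness bug,
not statistical bad luck). Artifacts (expected 0.3 events per trace) are
either 50 Hz mains interference with a 150 Hz harmonic or a
step-plus-exponential-decay mechanical transient, with amplitudes of
5–15 times the trace RMS and exact per-sample ground-truth masks.

What the generator does *not* emulate: per-patient gain and impedance
variability, drift along the trajectory, distinct non-STN structures
(thalamus, zona incerta, substantia nigra all collapse into one NOT_STN
class), non-Poisson firing statistics, and overlapping spike waveforms.
Passing tests on this cohort therefore validate the *machinery* —
detectors, features, harness, statistics — not clinical performance.

## Preprocessing

Traces outside the depth window [−5, +2] mm (boundaries inclusive; the
window improves class balance) are discarded. Repeat recordings at the
same (patient, hemisphere, electrode, depth) are resolved by keeping the
latest timestamp; ties are an error. The analysis band-pass is a
second-order elliptic filter, 300–3000 Hz, 0.5 dB passband ripple, 40 dB
stopband attenuation (ripple/attenuation are conventional choices,
exposed in `PreprocessConfig`), applied forward and backward
(`sosfiltfilt`) for zero phase — effectively a fourth-order magnitude
response. Artifact detection runs *before* the band-pass: the 300 Hz
edge would otherwise hide exactly the mains interference the detectors
look for.

## Artifact detection

Both automatic detectors share a grid of 0.5 s segments (a 10 s trace
gives m = 20; a trailing partial segment is ignored).

**COV (stationarity scan).** Per segment, the biased autocorrelation
r[l] = (1/L) Σ x[n]x[n+l], l = 0…L−1, is computed without normalization
or mean removal — unnormalized so amplitude bursts inflate it; the
signal is band-limited and near zero-mean anyway. v_k is the variance
(over lags, 1/n normalization) of that sequence; the distance between
segments k and l is max(v_k, v_l)/min(v_k, v_l) ≥ 1, and pairs with
distance strictly above Th = 1.8 are marked mutually non-stationary in
an adjacency matrix. The trace is reduced to the longest contiguous run
of segments that are *pairwise* clean (not merely clean against one
reference), found by greedy rightward expansion from every start index
with ties broken to the earliest start. Because a sub-interval of a
clean interval is clean, this greedy search is exactly equivalent to
exhaustive enumeration — the test suite verifies that on random traces.
A segment whose autocorrelation has zero variance gets infinite
distances and can never join a run of length > 1.

**BCK (background-noise detector).** The noise level of a signal is the
median magnitude of its analytic (Hilbert) envelope — for Gaussian noise
of SD σ this is σ√(2 ln 2) ≈ 1.18 σ, the Rayleigh median. A segment is
flagged when its noise level exceeds 20× the whole-trace level
(amplitude check) or when the maximum of its FFT magnitude exceeds 2.5×
the median of per-segment maxima (frequency check); segments are
mean-removed before the FFT so the DC bin never dominates. Flagged
segments are removed and the remainder concatenated in time order,
accepting the resulting spectral discontinuities.

All three thresholds (1.8, 20, 2.5) use strict `>`: a value exactly at
threshold is clean. They are configuration parameters with these
defaults; no threshold optimization is attempted.

**EXP and RAW.** A third path removes whole traces flagged by an
external annotation (for synthetic cohorts, any trace whose ground-truth
mask is non-empty — whole-trace rejection mirrors how expert screening
works, with no artifact timing). RAW passes everything through. After
COV/BCK cleaning, traces with residual length under 4 s (inclusive
boundary: exactly 4 s survives) are dropped.

Detector agreement is computed per segment on the shared grids of the
raw traces: segments neither detector rejects count as agreeing
"clean"; per-patient Cohen's kappa uses the 2×2 verdict table, with the
convention kappa = 1 when both raters are constant and identical (0 if
constant and unequal).

## Features

22 features per surviving trace; counting and summed features are
normalized by the sample count N so residuals of different lengths are
comparable.

Time/amplitude domain: curve length WL = (1/N) Σ|x(n+1) − x(n)| (a
literal "sum of neighbors" variant is available behind
`curve_length_mode="sum"` for comparison, but the first-difference form
is the standard curve-length definition and the default); MAV and MED
(mean and median absolute amplitude); TH = 3 × sample SD (N−1
denominator), the conventional spike-detection threshold; RMS and PWRA
(= RMS², asserted as an identity); amplitude-distribution kurtosis and
skewness with the (N−1) normalization (≈ 3 and 0 for Gaussian noise);
NL, the envelope-median noise level shared with BCK; average non-linear
energy ANE = (1/(N−2)) Σ [x(n)² − x(n−1)x(n+1)]; ZC, zero crossings
counted with a ±NL deadband (an excursion must leave the noise band on
both sides of the crossing); PKS, strict local maxima above TH per
sample. A zero-variance trace yields undefined kurtosis/skewness; such
records are dropped (with a logged count) before outlier handling.

Frequency domain: Welch PSD with 1 s Hann windows and 50% overlap — a
1 Hz grid. The three very-high-frequency relative powers (300–1000,
1000–2000, 2000–3000 Hz) come from the PSD of the signal itself,
normalized by the direct power in 300–3000 Hz, so the three tile to 1.
The two high- (70–220, 220–320 Hz) and five low-frequency bands (1–4,
4–8, 8–13, 13–30, 30–70 Hz) come from the PSD of the mean-subtracted
rectified signal — the envelope spectrum, which exposes firing-rate
modulations below the analysis band — normalized by the rectified power
in 1–320 Hz. Band edges are half-open [lo, hi) on the 1 Hz grid. The
per-family denominators are this package's choice; only the band edges
themselves are given by the feature definitions.

## Outlier management and normalization

Three options: NONE (identity); ORH, quartile fences per (patient,
hemisphere) — linear-interpolation quartiles, a row removed iff *any*
feature lies strictly outside [Q1 − 3·IQR, Q3 + 3·IQR] (the any-rule is
chosen over the all-rule as the interpretation consistent with
fence-based screening of multivariate records); ORM, the local outlier
factor per patient on the raw 22-feature vectors (neighborhood
min(20, group−1), automatic contamination — library defaults, run
before any normalization since outlier handling precedes it in the
pipeline order). Groups too small to estimate fences or densities (< 4
rows for ORH, < 3 for ORM) pass through unfiltered with a loud log.
IQR = 0 collapses the fences to the quartile value, and since removal
requires strict exceedance, nothing is removed.

The independent normalization toggle Min–Max scales each feature to
[0, 1] within each (patient, hemisphere) group before modeling; a
feature constant within a group maps to 0. Crossing
{RAW, EXP, COV, BCK} × {NONE, ORH, ORM} × {plain, normalized} yields the
24 dataset variants.

## Classification harness

Three fixed-hyperparameter classifiers — RBF-kernel SVC (C = 1.0,
gamma = 'scale'), elastic-net logistic regression (l1_ratio = 0.5, SAGA,
max_iter = 10⁴, inverse regularization strength at the library default
1.0), and a 100-tree Gini random forest with unrestricted depth — each
with and without recursive feature elimination: six model configurations.
STN is the positive class (1).

Evaluation is stratified, shuffled 5-fold cross-validation with a shared
seed per variant. Inside each fold, variants not hemisphere-normalized
upstream are Min–Max scaled with parameters fit on the training rows
only. RFE (when enabled) also sees only training rows: features are
eliminated one at a time by model-appropriate importance — |coefficient|
for the elastic net, impurity importance for the forest, and
training-set permutation importance for the SVC, which exposes no
coefficients — and the subset size is picked by internal 3-fold CV
accuracy over the nested subsets, down to a floor of one feature, ties
favoring fewer features (`score_step` can coarsen the size search for
large runs). Accuracy, precision, recall and F1 come from the fold's
confusion matrix with the conventions precision = 0 when nothing is
predicted positive, recall = 0 when no positives exist, F1 = 0 when both
vanish. AUC uses decision-function values for the SVC and class-1
probabilities for the other two.

## Shapley attributions

With no SHAP library available as a dependency, attributions are
computed by an in-package permutation-sampling Shapley estimator with a
single reference point (the training-fold feature mean): for each
sampled feature ordering, a feature's contribution is the change in the
model score when its value switches from reference to explained value
given the features before it have switched. Contributions telescope, so
attributions sum exactly to f(x) − f(reference) for every sampled
permutation, and the estimator is exact for linear models with a single
permutation — the property the test suite uses as its oracle. Scores are
class-1 probabilities for EN/RF and decision values for the SVC. Per
fold, up to 40 test points are explained with 12 permutations (both
configurable); features are ranked by mean |attribution| and the top ten
recorded. Presence percentages count how often each feature makes a
fold's top ten, separately per classifier and per pipeline family
(normalized vs not, feature selection on/off).

## Factor comparison

Pipeline factors are compared by fixed-effects three-way ANOVA on the
fold-level metric values (five observations per grid cell), with the
classifier and the feature-selection toggle always entering as the first
two factors and the factor of interest (DATASET, OUTLIER or
NORMALIZATION) as the third; sums of squares are type II, which reduce
to the classical between-level sums in the balanced grid. Post hoc
pairwise comparisons on the factor of interest use Welch t-tests with
Bonferroni correction. A grid with literally zero metric variance would
produce meaningless F ratios from numerical residuals, so that case is
short-circuited to F = 0, p = 1. Failed grid cells (e.g. a variant left
with one class) are recorded and excluded, never imputed.

## Problem sizes and numerical choices

The acceptance script (`scripts/acceptance.py`) runs the full framework
on a three-patient cohort (144 selected traces, feature tables of
roughly that size) with 25 explained points and 8 permutations per fold
for the attributions and an RFE size-search step of 6 — sizes chosen so
a single-core run of the complete 24 × 6 grid stays in the ten-minute
range while exercising every component. The test suite uses smaller
cohorts at reduced sampling rates for the same reason, except the
end-to-end check, which uses the default eight-patient, 24 kHz cohort.

Degenerate inputs are handled explicitly: empty cohorts are empty
results, silent traces drop out at feature extraction, all-flagged
traces drop at the 4 s rule, variants that lose a class fail their grid
cell visibly. Determinism: cohorts are pure functions of (config, seed);
per-trace random streams are derived from the seed via spawn keys, so
any trace can be regenerated independently of cohort size.

## Known limitations

Synthetic effect sizes make the default cohorts nearly perfectly
classifiable, so the framework's comparative statistics (which pipeline
is better) are exercised structurally rather than discriminatively on
defaults; sharpening the comparison requires configuring weaker class
contrasts. The qualitative direction reported on clinical data —
hemisphere-wise pre-normalization degrading accuracy — is logged for
inspection on synthetic runs but not asserted, since it depends on
patient-level variability the generator only partially emulates. The
SVC permutation importance used inside RFE is a pragmatic stand-in for
coefficient-based ranking and is the slowest part of the grid.
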
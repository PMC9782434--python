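# Methods

## Platform protocol

The support surface rotates about the vertical axis as
`θ(t) = s·A·sin(2πf t)` with `s = +1` for a right start and `−1` for a
left start. Three conditions are modelled: low (0.2 Hz, ±55°), medium
(0.3 Hz, ±55°) and high (0.5 Hz, ±35°). A smoothstep envelope
(`3u² − 2u³` over the ramp) multiplies the carrier for the first and last
`ramp_duration` seconds (default 2 s), so the platform starts and ends at
exactly 0° with continuous velocity; any smooth monotone 0→1 envelope
would do, and the polynomial is preferred over a logistic because it
reaches its endpoints exactly. The sampling rate defaults to 100 Hz
(typical for the wearable-IMU class modelled here) and the trial length to
34 s (30 s of steady state), both configurable. Published peak
angular accelerations for these conditions (0.25–0.50 °/s²) are
inconsistent with `A(2πf)²` for the stated amplitudes and frequencies
(≈87 °/s² for the low condition) and look like a units misprint; the
simulator is therefore parameterized by frequency and amplitude only, and
the test suite checks the physically consistent `A(2πf)²`.

The 18-trial schedule (3 levels × 2 sides × 3 repetitions) is a seeded
permutation; the same seed always reproduces the same order.

## Virtual cohort

Each subject-state is a parameter set, not a biomechanical model:

| parameter | meaning | HC mean (SD) | default contrast |
|---|---|---|---|
| `g_pelvis, g_trunk, g_head` | yaw gain of each link | 0.85 / 0.80 / 0.90 (0.05) | PD pelvis −1.5 SD |
| `φ_pelvis, φ_trunk, φ_head` | phase lag at f (deg) | 8 / 12 / 10 (3) | shared |
| `a_ML` per segment (mm) | ML sway amplitude | 6–9 (1.5) | PD +1.5 SD |
| `a_AP` per segment (mm) | AP sway amplitude | 8–11 (1.5) | shared |
| sway frequencies (Hz) | ML 0.6, AP 0.5 | — | shared |
| sensor noise | accel 0.05 m/s², orientation 0.2° | — | shared |

The yaw chain composes multiplicatively: each link applies its gain and
converts its phase lag into a pure time delay at the perturbation
frequency, so the ground-truth coupling of every link is exactly
`(g, φ)`. Sway is sinusoidal with per-trial random phase; its frequencies
sit well above the 0.2 Hz high-pass cutoff so the extraction can recover
it (ML and AP use different frequencies so the axes stay distinguishable).
Magnitudes follow axial-sway scales typical for standing adults (a few
mm); the group contrasts (PD: larger ML sway, smaller pelvis-link gain)
implement the qualitative clinical picture — increased medio-lateral
displacement and reduced lumbo-sacral transmission — with standardized
effect sizes as free configuration, defaulting to 1.5 SD. No published
numeric HC/PD feature distributions exist for this protocol, so the
defaults are choices, not estimates.

PD subjects carry paired OFF/ON parameter sets; ON is the OFF draw moved
30% of the way toward the HC means (axial postural control is largely
refractory to dopaminergic therapy, so ON ≈ OFF by default; the fraction
is configurable to exercise the OFF-vs-ON experiment both ways).

The virtual IMU reports the segment orientation as a yaw-only quaternion
(plus Gaussian orientation noise as extra yaw), body-frame specific force
`R⁻¹(a_world + g)` with gravity +9.81 m/s² on world Z, and the angular
rate of the rendered orientation. World frame: Z up, X antero-posterior,
Y medio-lateral. The magnetometer and the vendor's sensor-fusion
algorithm are not modelled — orientation is provided directly, as the
real pipeline consumes fused quaternions anyway. What the simulator does
*not* emulate: closed-loop balance control, transient postural reactions,
inter-segment mechanical coupling of sway, soft-tissue artifacts, and
sensor-to-segment misalignment. Passing tests on this cohort therefore
validate the signal path and the statistical machinery, not clinical
effect sizes.

## Feature extraction

Displacement: body accelerations are rotated to the world frame with the
quaternion rotation matrix, gravity subtracted, and each horizontal axis
double-integrated (cumulative trapezoid) with a zero-lag first-order
Butterworth high-pass at 0.2 Hz after each integration to suppress drift.
"Zero-lag" is implemented as forward–backward filtering, so one pass has
the squared first-order magnitude. Numerical choices that matter:

* **Edge transients.** The 0.2 Hz filter's time constant is ≈0.8 s; with
  scipy's default 9-sample padding the start-up transient of the two
  filter stages corrupts several seconds of signal. `filtfilt` is run
  with even-reflection padding over ten time constants, and the analysis
  window is the trajectory's steady segment minus a 2 s guard on each
  side, which brings the worst-case ROM error below 1% (measured against
  analytic sinusoids across 0.4–1.5 Hz and all phases).
* **Passband attenuation.** Two zero-lag first-order stages attenuate a
  0.6 Hz sinusoid to ≈0.81 of its amplitude. ROM (max−min over the
  steady window) is therefore divided by the exact digital two-stage
  response evaluated at the displacement's dominant frequency, putting
  the feature back on the physical mm scale. The correction is exact for
  a sinusoid and approximate for mixed spectra.

Coupling: both yaw series (distal segment from its quaternions, proximal
from the chain below, the platform trajectory for the pelvis) are
mean-detrended and FFT'd over a window cropped to a whole number of
perturbation periods (this puts the fundamental exactly on an rFFT bin and
removes leakage). The fundamental is the maximum-magnitude bin of the
*proximal* spectrum within 0.05–2 Hz, ties broken toward the lower
frequency; the gain ratio is the magnitude ratio there and the phase shift
is the proximal-minus-distal phase difference wrapped to (−180°, 180°], so
a delayed (lagging) distal segment has φ > 0. The coupling chain
pelvis←platform, trunk←pelvis, head←trunk gives each segment exactly one
(G, φ) pair, which is what makes the 4-features-per-segment count work;
the pelvis-vs-platform reference is an inference, as no explicit pairing
is published. A quiet-standing heading calibration is available
(`static_heading_offset`) but constant heading offsets cancel in the
mean-detrending anyway; the full functional sensor-to-segment calibration
used with real hardware is out of scope.

Features are averaged over the three repetitions of each test type
(order-invariant); `average_repetitions: false` instead emits one row per
repetition, since the sampling unit of the original feature table is not
documented and the benchmark treats rows-per-subject as configurable.

## Benchmark

The 13 preset variants follow point-and-click conventions: Decision Trees
with at most 100/20/4 splits (Gini), kNN with k = 1/10/100 (Euclidean),
10-cosine, 10-Minkowski(3), and 10-Euclidean with squared-inverse-distance
weights (k capped at the training-set size), polynomial SVMs of degree
1/2/3 with unit box constraint, and a single-hidden-layer 10-neuron
network with logistic activation, seeded initialization and early
stopping on an inner validation split (early stopping is skipped when the
training fold is too small to carve a two-class validation split).
Features are z-scored inside the CV loop (training folds only) for the
distance- and gradient-based families.

Cross-validation is subject-grouped: all rows of a subject share a fold,
so a patient's ON row can never inform the prediction of their own OFF
row. Folds are stratified by the subject's class where the grouping
allows; subjects whose rows span both classes (OFF vs ON) are spread
round-robin. When k exceeds the number of subject groups it is reduced
with a logged warning — with one row per subject-state the nominal k = 50
effectively becomes leave-one-subject-out, which is also the scheme used
for the ANN throughout. Out-of-fold predictions are pooled into a single
confusion matrix per combination (fold-wise averaging is ill-defined with
single-sample folds); positive-class scores (decision values for SVM,
probabilities/vote fractions for the others) are pooled the same way for
ROC/AUC.

## Selection

Gates are applied in order ACC → TPR → PPV at 80%, on values rounded to
one decimal (inclusive ≥, the natural reading of "equal to or higher
than"); a failed gate blocks the later ones and the report renders blocked
cells as "/". Survivors are categorized by the goodness index (optimum
≤ 0.25 < good ≤ 0.70 < bad); the boundary value 0.70 — the chance-level
reference point, since TPR = TNR = 50% gives G = √0.5 ≈ 0.707 — falls in
"good" under the interval reading. The best classifier per experiment is
the gate-passing one with the lowest G, ties broken by higher accuracy and
then name; experiments without a passer report none. PPV is flagged as
undefined (never silently 0) when no positive predictions were made, and
an undefined PPV fails the precision gate.

`find_consistent_matrices` searches all integer confusion matrices up to a
total count for ones whose rounded metrics match a printed
(ACC, TPR, PPV, G) quadruple — a consistency check of the metric
implementations against published tables when the underlying data are
unavailable. The percent values are matched at their printed one-decimal
rounding; G is matched within an absolute tolerance because a two-decimal
printed index may come from rounding or truncation (the default 0.005
corresponds to strict rounding; 0.01 covers one unit of the last printed
digit).

## Problem sizes and defaults

The committed protocol configuration (`configs/paper_protocol.yaml`) is
the full study design: 20 PD subjects (paired OFF/ON) + 15 HC, 18 trials
per subject-state at 100 Hz × 34 s, 72 features, 52 classifier-experiment
combinations. A complete run (simulate → extract → bench → select) takes
roughly half a minute on one CPU; the end-to-end tests run it at full
scale twice (a strongly contrasted 3 SD cohort and a zero-effect null
cohort). Per-trial sensor CSVs are only written when `save_sessions` is
enabled, as the full protocol's raw streams are ~400 MB; the pipeline is
restartable from the feature table, the benchmark artifacts, or (when
saved) the raw session CSVs.

## Known limitations

* The cohort's effect sizes are configuration, not estimates; absolute
  classification accuracies on synthetic cohorts say nothing about
  clinical accuracy.
* The ROM filter-gain correction assumes a narrowband displacement; broad
  spectra would be under-corrected.
* kNN distance ties are left to scikit-learn's resolution rather than the
  nearest-neighbour rule; ties have probability zero on continuous
  features.
* The ANN is a stochastic learner; its fold-level results are seeded and
  reproducible but sensitive to the seed on small cohorts.
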
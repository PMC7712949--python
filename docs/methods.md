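# Methods

`eegmodwt` implements a complete discriminant pipeline for two-class
resting-state EEG studies — patients ("AD") versus controls ("NC") —
built around the maximal-overlap discrete wavelet transform (MODWT).
This note records the model, the numerical choices, and what the
bundled synthetic cohort does and does not demonstrate.

## Preprocessing

Recordings (16 channels, 125 or 500 Hz) pass through, in order:

1. **Downsampling** to 125 Hz (anti-alias FIR low-pass + decimation;
   integer ratios only; identity when already at 125 Hz).
2. **High-pass at 0.5 Hz**, zero-phase windowed-sinc FIR with a
   0.25–0.5 Hz transition band, removing DC and slow drift (>40 dB)
   while preserving rhythms above 1 Hz within 1%.
3. **50 Hz notch**, zero-phase second-order Butterworth band-stop
   (49–51 Hz, sos form, forward–backward).
4. **Segmentation** into non-overlapping 10-s epochs (1250 samples),
   trailing remainder dropped, per-channel mean subtracted per epoch
   (baseline removal).
5. **Amplitude rejection**: epochs exceeding 100 µV absolute amplitude
   on any channel are discarded. This is an automated stand-in for
   visual artifact screening; it makes no attempt at ICA-style artifact
   correction or bad-channel interpolation, and the threshold is not
   claimed to reproduce expert inspection.

Both filters are applied forward and backward, so a symmetric pulse
stays symmetric (tested numerically) and epoch timing is unaffected.

## MODWT

For a wavelet/scaling pair of width L the MODWT filters are the DWT
filters renormalized by 2^{1/2} per level; the wavelet filter is
derived from the scaling filter via the quadrature-mirror identity
g̃_l = (−1)^{l+1} h̃_{L−1−l}, which therefore holds exactly in floating
point. Coefficients at level j are circular (mod-N) convolutions with
the level-j equivalent filter of width L_j = (2^j − 1)(L − 1) + 1,
computed by the standard pyramid recursion with upsampled filters. The
implementation keeps every coefficient series at length N, satisfies
the energy identity ‖x‖² = Σ_j‖W̃_j‖² + ‖Ṽ_J‖², reconstructs x as the
sum of details plus smooth to <1e−8, and is exactly shift-equivariant.
A direct single-pass evaluation of the defining convolution sums with
explicitly constructed equivalent filters serves as the independent
oracle in the test suite (agreement <1e−10).

The maximum depth for a series of length N is the largest j with
L_j ≤ N — the deepest level at which at least one coefficient is free
of circular wrap-around. At N = 1250 this gives 10 (Haar), 8 (D4) and
7 (D6, D8, LA8, C6) layers.

Filter families: Haar, Daubechies extremal-phase D4/D6/D8, least
asymmetric LA8, Coiflet C6. Coefficients are embedded as constants
from the standard published values and cross-checked against
PyWavelets in the tests.

## Features

Per epoch, with layers j retained (default: all levels except the four
shallowest, i.e. 5..J_max — see "Retained layers" below):

- **VA** (wavelet variance), per channel × layer: the mean of squared
  non-boundary coefficients, (1/M_j) Σ_{t=L_j−1}^{N−1} W̃²_{j,t} with
  M_j = N − L_j + 1. Wavelet coefficients have zero mean by
  construction, so this is the scale-j variance.
- **IQR**, per channel × layer: P75 − P25 of the non-boundary
  coefficients, linear-interpolation quantile rule.
- **PCC**, per unordered channel pair × layer: Pearson correlation of
  the two non-boundary coefficient series.
- **D** (Hoeffding's D), per pair × layer: the classical rank statistic
  of general bivariate dependence scaled by 30, using midranks for ties
  and the bivariate quadrant rank Q_i; D = 30[(n−2)(n−3)D₁ + D₂ −
  2(n−2)D₃] / [n(n−1)(n−2)(n−3)(n−4)] with D₁ = Σ(Q_i−1)(Q_i−2),
  D₂ = Σ(R_i−1)(R_i−2)(S_i−1)(S_i−2), D₃ = Σ(R_i−2)(S_i−2)(Q_i−1).
  Like the other coefficient statistics it is evaluated on the
  non-boundary region, for consistency. The production path computes
  all 120 pairs at once via per-sample Gram matrices of the stacked
  quadrant-indicator matrices; a pure double-loop rank-counting oracle
  verifies it to 1e−12 in the tests.
- **PE** (permutation entropy), per channel, computed on the raw
  preprocessed epoch signal (not the wavelet coefficients): Shannon
  entropy of ordinal-pattern frequencies normalized by ln m!, defaults
  m = 3, τ = 1 (both configurable); ties within a window are ordered by
  occurrence (stable sort).

With 16 channels this yields 272·j + 16 features (e.g. 832 for LA8's
three retained layers, 1104 for D4's four). Undefined values (e.g.
correlation against a flat channel) are imputed with the column median
during table assembly so row counts stay stable; columns undefined
everywhere are dropped.

### Retained layers

Excluding the four *shallowest* layers at 125 Hz keeps only activity
below ≈3.9 Hz (levels 5–7 of LA8 span ≈0.5–3.9 Hz), discarding the
alpha band entirely. This follows the configured default
(`exclude_from="shallow"`); the opposite orientation
(`exclude_from="deep"`, retaining levels 1..J−4) is available when the
higher-frequency bands are of interest. The synthetic cohort's class
contrast is therefore carried into the retained layers through delta
band power and low-frequency coupling, not through the alpha reduction
directly (which still affects PE on the raw signal).

## Selection, cross-validation, classifiers

- **Stepwise selection**: greedy forward, up to 20 features. At each
  step every remaining column is residualized on the intercept and the
  selected set (orthonormal-basis projection), and the candidate with
  the largest two-class one-way-ANOVA F on the residuals enters.
  Columns collinear with the selected set are skipped (so duplicates
  never enter twice); a perfect separator (zero within-class residual
  variance) receives an effectively infinite F and enters immediately.
  The criterion is an explicit interpretation of "stepwise
  discriminant" selection and is pluggable in principle.
- **Subject blocking**: subjects (not epochs) are dealt into five
  stratified folds (shuffled per class, round-robin), so per-class fold
  sizes differ by at most one and no subject's epochs ever straddle a
  train/test boundary; the disjointness is asserted at runtime on every
  fold. One fold assignment is fixed per run and reused by every
  classifier.
- **Selection scope**: fitted inside each training fold by default
  (no leakage); a `global` mode fits it once on all data before
  splitting, mimicking protocols that select features outside CV —
  provided for comparison only, and demonstrably optimistic (the test
  suite shows a label-copy column dominating selection in this mode).
- **Classifiers**: LDA, logistic regression, k-NN, RBF-SVM, random
  forest, Gaussian naive Bayes, AdaBoost, and a one-hidden-layer MLP,
  all via scikit-learn behind a standardize-then-classify pipeline.
  Families with a hyperparameter grid (logreg C, k-NN neighbours,
  SVM C) are tuned by an inner grouped 3-fold grid search on the
  training fold; the other grids are intentionally empty.
- **Evaluation**: epoch-level by default, the patient class positive.
  Accuracy, precision, recall, specificity and F-measure come from the
  fold confusion counts; AUC uses the rank-sum (Mann–Whitney) formula
  on probability scores (decision-function scores where probabilities
  are unavailable) with midranks for ties. Undefined metrics are
  reported as NaN, never as 0. Reports carry mean ± sd over the five
  folds. An optional per-subject majority-vote aggregation exists but
  is off by default.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not the physiology behind it. Per subject, each channel is a weighted
sum of band-limited Gaussian oscillations (delta/theta/alpha/beta,
realized as Butterworth-filtered white noise so spectra are stable and
correlations non-degenerate), plus three shared latent band-limited
sources (delta, theta, alpha) mixed into all channels with weight =
coupling, plus 1/f background noise. Band amplitudes vary log-normally
(sd 0.2 on the log scale) across subjects around class means.

Defaults — the study conditions of the bundled experiments:

| parameter | NC | AD |
|---|---|---|
| delta / theta / alpha / beta relative amplitude | 0.6 / 0.8 / 1.5 / 0.7 | 1.2 / 1.3 / 0.8 / 0.6 |
| coupling | 0.6 | 0.3 |

23 subjects per class, 120 s per recording (12 epochs/subject,
552 epochs before rejection), fs 125 Hz, 16 channels named by the
10–20 montage, pink-noise scale 0.8, overall amplitude scale 5 µV
(≈12 µV signal sd, comfortably below the 100 µV rejection threshold —
the generator simulates artifact-free EEG; artifact simulation is out
of scope). The patient class shows EEG slowing (elevated delta/theta,
reduced alpha) and reduced synchronization, the qualitative
abnormalities this kind of analysis targets; no quantitative clinical
effect sizes are claimed, since none are established for this feature
set — the defaults are chosen so that the class contrast is clearly
detectable at desk scale. Everything is deterministic given the cohort
seed (per-subject seeds derive from it), and generation is bit-stable
across runs.

What passing the end-to-end tests shows: the pipeline detects the kind
of statistical contrast it was designed for, with no subject leakage,
and collapses to chance AUC when subject labels are permuted. What it
does not show: performance on real clinical EEG, robustness to
artifacts, or clinical effect sizes.

## Numerical choices and degenerate inputs

- Circular (mod-N) boundary handling everywhere in the MODWT; no
  reflection variant.
- Boundary coefficients (t < L_j − 1) are excluded from every wavelet
  feature; requesting a statistic with no non-boundary coefficients
  raises.
- Hoeffding's D requires n ≥ 5; PE requires length ≥ (m−1)τ + 2.
- IQR quantiles use linear interpolation; PE ordinal ties break by
  order of occurrence; AUC and Hoeffding ties use midranks.
- Chi-square for 2×2 tables is Pearson's statistic without continuity
  correction.
- Stepwise skips candidates whose residual sum of squares falls below
  1e−12 of the column's original scale.
- Epoch-level problem sizes throughout: feature extraction on the
  default cohort (552 epochs × 832 LA8 features) runs in roughly two
  minutes on one CPU, dominated by the 120-pair Hoeffding statistics.

## Known limitations

- No EDF export (cohorts are written as delimited matrices plus a
  manifest); EDF *reading* is supported when `mne` is installed.
- The amplitude-threshold rejection is a crude artifact proxy.
- The generator has no scalp topography, no artifacts, and no
  within-recording non-stationarity.
- LDA's default (svd) solver ignores directions with zero within-class
  scatter, so a feature that separates classes perfectly and exactly
  can paradoxically contribute nothing to LDA; the stepwise criterion
  still ranks it first, and other families exploit it.
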
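# Methods

`wakebreath` implements a wakefulness screening pipeline for obstructive sleep
apnea (OSA) severity from tracheal breathing sounds (TBS). This note records
the models, the tunable parameters that matter, the numerical choices made
where the design was open, and what the synthetic benchmark does and does not
demonstrate.

## Problem setting

OSA severity is graded by the apnea–hypopnea index (AHI): Non-OSA (AHI < 5),
Mild (5–15), Moderate (15–30), Severe (≥ 30) events/hour. The pipeline
classifies six pairwise severity comparisons from acoustic features of
wakefulness TBS recordings (five deep nose breaths plus five mouth breaths at
10,240 Hz) fused with anthropometric covariates (BMI, age, sex, smoke history,
neck circumference, Mallampati score).

## Synthetic data generator

The generator exists because the pipeline's target recordings are clinical
data that cannot ship with the package. It emulates:

* **Cohort structure** — per-class Gaussian anthropometrics with the published
  group means/SDs (e.g. Severe BMI 39.7 ± 8.7, NC 45.3 ± 3.6), sex and
  Mallampati category frequencies from the published counts, and AHI drawn
  from a moment-matched log-normal truncated to the class interval (Severe
  capped at 120 events/h). Smoke-history prevalence is not published;
  default Bernoulli(0.2), configurable. Missing cells are injected completely
  at random over the six anthropometric fields only.
* **Recording protocol** — five breath cycles (ten alternating
  inspiration/expiration bursts) of band-limited shaped noise over a gentle
  1/f background at a configured SNR (default 25 dB, defined as
  20·log10(phase RMS / background RMS)). Burst onsets use 50 ms raised-cosine
  ramps; the phase duty cycle is kept below 40% of the cycle so log-variance
  segmentation has a bimodal distribution. Default breath rate 10 cycles/min
  (deep, paced breathing), phase durations ≈ 1.1–1.2 s.
* **Severity-dependent acoustic structure** — each class plants a spectral
  tilt (dB/octave) and a turbulence-band (800–1600 Hz) energy gain that is
  non-decreasing with severity (0, 1, 4, 9 dB). Every subject additionally
  draws a personal tilt and gain offset (SD 1.2 dB/octave and 3.5 dB, from a
  stable per-subject stream shared across routes), so classes overlap the
  way heterogeneous cohorts do instead of being point masses in effect
  space. With these SDs the single best band-power feature separates
  Non-OSA from Severe at Cohen's d ≈ 3.3, i.e. a Bayes accuracy near 0.95,
  while Non-OSA vs Mild stays genuinely hard (d ≈ 0.5). The small
  Non-OSA→Mild step and large Non-OSA→Severe step are deliberate: the
  end-to-end benchmark should find the extreme comparison easy and the
  adjacent one hard, matching the qualitative difficulty ordering of
  clinical severity screening. An
  optional coupled-triad flag injects sinusoids at (f1, f2, f1+f2) with
  phases summing, a known positive control for bispectrum estimators.

These effects are *stand-ins*, not estimates of real airway acoustics: no
published quantitative per-class acoustic ground truth exists. Passing the
planted-effect benchmarks shows the pipeline recovers effects of this type
and size; it says nothing about classification accuracy on real patients.

## Preprocessing

* **Screening** — clipping (samples at full scale), narrowband tonal
  contamination (any single periodogram bin holding > 50% of total power,
  e.g. mains hum), and silence are flagged, never raised.
* **Segmentation** — log of the moving variance in non-overlapping 50 ms
  windows, thresholded at the 60th percentile with a one-step bimodal
  refinement (the threshold moves to the midpoint of the two group means the
  quantile induces, placing it between the background and breath clusters
  rather than in a cluster tail). Runs are merged, intervals shorter than
  300 ms dropped, labels alternate starting from inspiration (configurable;
  the protocol starts with an inhalation).
* **SNR screen** — 20·log10(RMS_phase / RMS_background) against the
  complement of the detected intervals; phases below +6 dB are kept but
  flagged `kept=false`. The threshold realizes a qualitative "very low SNR"
  rule and is configurable.
* **Filtering** — 4th-order Butterworth band-pass 75–3000 Hz applied
  forward–backward. Zero-phase filtering was chosen to avoid phase
  distortion of onset features; the analytic magnitude response is exposed
  for testing (forward–backward squares it).
* **Normalization** — stage 1 divides by the smoothed moving-RMS envelope
  (100 ms window, reflection padding, double smoothing pass, floored at 1e-8
  of the peak); stage 2 divides by the standard deviation. Envelope
  correction is only applied when the envelope max/min ratio exceeds 1.2:
  flatter phases are treated as amplitude-stationary. This both avoids
  amplifying estimator noise and makes normalization exactly idempotent.

## Spectral statistics and gap detection

* **PSD** — Welch, 1024-sample Hann windows, 50% overlap (≈10 Hz resolution
  at 10,240 Hz).
* **Parametric band** — per-bin mean and SD over a reference group of
  spectra; bounds μ(f) ± 1.96 σ(f). Because σ is the *cross-subject* SD this
  is a member-coverage (normal-range) band: a fresh spectrum from the same
  population falls inside ≈ 95% of the time (the Monte-Carlo acceptance
  check measures exactly this; with a group of 100 the sample-σ correction
  leaves expected coverage at 2Φ(1.96/√(1+1/100))−1 ≈ 94.9%). The band is
  fitted on training subjects of an experiment's less-severe class and
  frozen for test data.
* **Bispectrum** — direct FFT segment-averaged estimator
  B(f1,f2) = E[X(f1)X(f2)X*(f1+f2)] on a square grid f1,f2 ∈ [0, fs/4]
  (so f1+f2 stays below Nyquist and symmetry holds on the whole grid);
  bicoherence uses the normalization
  |E[X1X2X3*]|² / (E[|X1X2|²] E[|X3|²]), bounded in [0,1] by Cauchy–Schwarz.
  Fewer than 4 segments is an error (estimator variance too high).
* **Bootstrap bounds** — subject-level resampling. The resamples are pooled
  (equivalently: one multinomial weight draw of n·n_boot over subjects) and
  the per-bin weighted empirical α/2 and 1−α/2 quantiles of the member
  distribution are returned, using median-unbiased plotting positions
  ((k−1/3)/(n+1/3) generalized to weights). Averaging per-resample quantiles
  instead would bias the tails inward by several coverage points at n = 60;
  the pooled form converges to the unbiased empirical quantile and keeps
  fresh-member coverage at ≈ 94–95% with no Gaussianity assumption.
  Default n_boot = 500; the resampling unit is the subject, not the segment.
* **Gap detection** — PSD: contiguous out-of-band runs, labelled
  above/below, runs shorter than 3 bins discarded. Bispectrum: out-of-bounds
  mask → 8-connected components → bounding boxes, components smaller than
  9 bins dropped. Both minima suppress single-bin noise and are configurable.

## Feature bank

Families (all toggleable): spectral (PSD shape statistics, full-band and per
detected gap band), bispectral (magnitude/bicoherence statistics, bispectral
entropy, symmetry, gap-box geometry), time (ZCR, RMS, waveform length,
jitter/shimmer on the dominant-period peak sequence, noise-to-harmonic ratio
from the autocorrelation peak, AM depth, autocorrelation and CDF statistics),
time–frequency (13 MFCCs with per-coefficient mean/SD/skew, orthogonal db4
wavelet sub-band energies, constant-Q band statistics, TQWT sub-band
energies, harmonic/percussive energy ratio), nonlinear (Katz and Higuchi
fractal dimensions, DFA Hurst, Rosenstein largest Lyapunov exponent,
sample/approximate entropy, RQA recurrence rate/determinism/laminarity), and
image (GLCM, LBP, a soft probabilistic binary-pattern variant, binary
morphology of the log-spectrogram).

Numerical choices worth noting:

* MFCC, CQT, TQWT and HPSS are implemented in-package from their standard
  definitions (framed power spectra with an HTK-style mel filterbank and
  orthonormal DCT-II; a constant-Q windowed-DFT kernel bank; the tunable-Q
  two-channel filter bank in its undecimated frequency-domain form, whose
  power-complementary Daubechies transition filters conserve energy exactly;
  median-filter STFT masking). The TQWT defaults are Q = 2, redundancy 3,
  6 levels.
* The probabilistic binary pattern has no canonical published formulation;
  here it is LBP with each neighbour comparison replaced by a sigmoid
  probability on the locally z-scored image, summarized by the mean
  bit-probability map. This is labelled a variant, not a reimplementation.
* Nonlinear estimators use embedding dimension 3, delay at the first
  autocorrelation zero, recurrence threshold 10% of the maximum phase-space
  distance; signals are decimated to ≤ 1500 samples (600 for the quadratic
  RQA/Lyapunov estimators) before the O(n²) computations.
* Morphology binarizes at the 75th intensity percentile; GLCM quantizes to 8
  levels at offsets (0,1) and (1,0), averaged.
* Per-subject aggregation is the mean over kept phases of each
  (route × phase-type) stream; mean was chosen over median for smoothness
  under the small per-subject phase counts (≈ 5 per stream).

## Cohort preparation

* **Imputation** — severity-specific kNN (k = 5): neighbours only within the
  same severity class; distance on z-scored mutually observed continuous
  fields plus 0/1 categorical mismatch; mean/mode imputation; class-level
  fallback with a warning when donors are scarce. Observed values are never
  altered, and deleting other-class rows provably cannot change any imputed
  value.
* **Split** — stratified 85/15 with per-class test count round((1−0.85)·n)
  (round-half-to-even reproduces the published per-class test sizes 11/5/8/6
  from group sizes 74/35/50/40), re-drawn until the test means of age, BMI
  and NC fall within one SD of the overall means, 10 reshuffles.
* **K-fold** — joint strata of severity × (age ≥ 50) × (BMI ≥ 35) ×
  (NC > 40) × sex × Mallampati; greedy assignment, largest stratum first,
  each member to the fold minimizing (stratum count, severity-class count,
  total count). Per-stratum fold counts differ by ≤ 1; per-class fold sizes
  stay within the spread of the published fold tables.
* A leakage guard rejects any design matrix containing AHI or severity
  columns.

## Feature selection

Normalization candidates (z-score, min-max, robust median/IQR,
rank/quantile) are fitted on training data only; the winner maximizes the
summed mutual information between normalized features and the binary label
(equal-frequency binning, 10 bins, bits), ties broken by candidate order.
Note MI is invariant under monotone per-feature maps, so with exact
equal-frequency binning the candidates tie and the first wins; in practice
NaN handling and interpolated bin edges break ties — the mechanism is kept
because it is cheap and harmless, and the fitted parameters are frozen.

Three nested stages follow: Welch t-test filter (α = 0.05, no multiplicity
correction — it is a coarse screen; if it leaves fewer survivors than the
acoustic budget the shortfall is backfilled by ascending p-value so the fused
width contract holds), Shapley-attribution ranking of a 200-round depth-3
gradient-boosted-tree scorer, and recursive feature elimination dropping 10%
of features per iteration by RUSBoost importances (100 stumps, per-round
majority undersampling to the minority count). The surviving acoustic
features (default 34) are fused with the 7-column anthropometric block for a
default total of 41. The protocol names six anthropometric variables but
counts seven; the seventh column is a configurable slot defaulting to the
sex × BMI interaction.

Shapley attributions are interventional, estimated by permutation sampling
against a background subsample: marginal contributions telescope along each
permutation, so per-row attributions sum *exactly* to
f(x) − E_background[f], and all d! orders are enumerated when d ≤ 6.

## Classification

Six pairwise experiments; positive class = the more severe of the pair (so
sensitivity measures detection of worse disease). The zoo holds 20
configurations (trees, naïve Bayes, L1/L2 logistic, kNN, LDA, QDA, linear/
RBF/poly-3/5/7/9 SVMs, random forest, bagged trees, gradient boosting,
RUSBoost, subspace kNN, shallow and 3-hidden-layer MLPs) with documented
default search spaces (e.g. SVM C log-uniform 1e-3…1e3, kNN k 1–25, forest
100–500 trees).

Hyperparameters minimize the stratified 5-fold CV misclassification rate via
Bayesian optimization: Matérn-5/2 Gaussian-process surrogate on the
unit-cube encoding, expected improvement with exploration offset ξ = 0.5
that doubles while the incumbent stalls (the "plus" behaviour), default
budget 50 evaluations with 8 random initial points. The fold count clamps to
the minority class size on very small training sets.

Bagging draws B = 50 stratified bootstrap resamples of size N (per-class
counts preserved), passes inverse-class-frequency sample weights to learners
that accept them, and records the integer draw-count membership matrix.
Out-of-bag prediction is the majority vote of learners whose resample
excluded the subject; ties go to the positive class
(screening-conservative); a subject in every resample falls back to the full
vote, flagged. Five independent trials re-seed optimization and bagging and
the best OOB accuracy wins (ties → lowest trial index); across
configurations the best OOB accuracy is final (ties → configuration order).
The test set is touched only after selection; evaluation retrains with fresh
seeds 25 times and reports per-repeat and aggregate accuracy/sensitivity/
specificity (plus inverse-frequency balanced variants).

All randomness flows from one run seed through named substreams.

## Problem sizes

The library defaults are the full protocol sizes (B = 50, budget 50,
5 trials, 25 repeats, 18–20 configurations). The demo configuration and the
test suite use the package's documented reduced sizes — 20 subjects/class,
a 2–4 model zoo, budget ≈ 5, B = 15–25, 2–5 repeats — chosen so the whole
benchmark runs on a laptop-class single core in minutes while leaving every
statistical property measurable. The planted-effect benchmark uses 80
subjects/class for the Non-OSA vs Severe comparison, where the generator's
default effects put the Bayes accuracy near 0.95.

## Known limitations

* The synthetic recordings are stationary shaped noise; they contain no
  heart sounds, swallowing, snoring-like oscillations or microphone motion,
  so the screening and filtering stages are only exercised against
  constructed artifacts.
* Bispectral and image features are computed but not part of the default
  demo feature set (they are the slowest families); enable them via
  `FeatureConfig(families=...)`.
* The bispectrum gap machinery uses magnitude bounds; phase bounds are
  computed and serialized but not used for gap detection (whether real
  deviations are better localized jointly in magnitude and phase is an open
  question the source protocol does not resolve).
* The CI band is per reference class within each experiment; a global band
  is a one-line change but was not selected, as class-referenced bands are
  what make the detected gaps discriminative.
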
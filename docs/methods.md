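# Methods

## Problem setting

The classification unit is a standardized multivariate window
`x ∈ R^{T×D}` of wrist inertial data: D = 6 channels (accelerometer x/y/z
in m/s², gyroscope x/y/z in rad/s) sampled at 50 Hz, with T = 100 or 150
samples (2–3 s, roughly one to a few arm-swing cycles). Labels are
walking-style classes; the package ships an 18-entry synthetic style
vocabulary and uses its first six entries as the default study condition.
Real recordings enter through a plain CSV contract
(`timestamp,accel_x,…,gyro_z`, one row per sample, plus a manifest CSV with
`recording_id,subject_id,class_id,sample_rate_hz`).

## Synthetic gait generator

No public corpus ships with the package, so every experiment runs on
synthetic recordings whose class structure mirrors the contrasts a wrist
sees across walking styles. Each class is a deterministic
sum of harmonically related sinusoids plus i.i.d. Gaussian noise per
channel:

    s_c(t) = baseline_c + g_subj · A_c · Σ_k w_k sin(2π k f_subj t + φ_c) + ε

* `fundamental_hz` — arm-swing cycle rate. Defaults span 0.6–2.9 Hz
  (shuffling to sprinting); normal walking sits near 1 Hz.
* `harmonic_weights` `w_k` — heel-strike transients and wrist rotation put
  energy at integer multiples of the cadence; more intense gaits get
  heavier 2nd/3rd harmonics.
* `amplitude` `A_c` — per-channel swing magnitude (m/s², rad/s). A global
  per-style scale multiplies a fixed base pattern across the six channels.
* `asymmetry ∈ [0,1]` — a loaded hand damps linear arm swing much more than
  wrist rotation, so asymmetry suppresses the three accelerometer channels
  by `(1 − asymmetry)` and leaves the gyro intact.
* Subject variation — per (subject, style): cadence jitter
  `f_subj ~ N(f₀, 0.08² Hz²)` (self-paced speed differs between people) and
  a swing-magnitude scale `g_subj ~ N(1, 0.25²)`, both drawn once.
* Noise — `ε ~ N(0, 0.30²)` per sample and channel while moving; the
  stationary class uses 0.05 because a resting wrist produces almost no
  motion artifact. The stationary class has zero oscillatory amplitude.

Defaults were chosen once so that single-feature marginals (e.g. dominant
frequency, RMS) overlap between subjects of neighboring classes — as they
do in self-paced human cohorts — while a two-feature nearest-centroid
classifier on (band-limited spectral centroid, RMS) still exceeds 90%
accuracy on the default six styles, keeping every downstream learning task
well-posed.

Randomness comes from `numpy` `SeedSequence(seed, spawn_key=(subject,
class))` substreams, so any subset of a campaign regenerates bit-identically
regardless of generation order.

What the generator deliberately does **not** model: biomechanics, gait-phase
locking between channels beyond fixed phase offsets, sensor drift and bias
walk, stair/slope kinematics, magnetometer channels, and within-recording
nonstationarity. Consequently, passing results here show that the pipeline
recovers spectral/amplitude/asymmetry class structure under subject
variation and noise — not that it reaches any particular accuracy on real
smartwatch data.

## Preprocessing

Standardization removes the per-channel mean and scales to unit variance
with the population (÷N) convention, computed over one recording
(per-recording scope is the strictest reading compatible with deploying on
unseen subjects; a pooled-global scope is available via configuration).
Channels with sd < 1e-12 map to zeros. Windows are half-open
`[start, start+T)` at multiples of `step = round(T·(1−overlap))`; the
trailing remainder is dropped because all models need fixed T. Signals are
not aligned to gait phase.

Two split policies: `segment_random` (stratified by class, per-class
proportions within ±1 segment) and `subject_holdout` (whole subjects move
to the test side until the requested fraction of segments is reached),
the latter emulating a blind test on unseen people. The split procedure is
seeded and deterministic.

## Feature branch

The per-channel bank implements 12 families (~36 parameterized features per
axis, ~216 per window): sum, rFFT coefficients (real/imag/magnitude),
autocorrelation, partial autocorrelation (Levinson–Durbin), AR(4)
coefficients, Fourier entropy (binned entropy of the Welch PSD),
change-quantile means, binned entropy, chunked linear trends, permutation
entropy, peak counts, and Lempel–Ziv (LZ76) complexity of the
median-binarized series. All entropies use natural logarithms. Undefined
values (e.g. autocorrelation of a constant series) become NaN and are
median-imputed per column; all-NaN columns become 0.

Per-feature relevance is the minimum over one-vs-rest two-sample
Kolmogorov–Smirnov p-values, Bonferroni-multiplied by the number of classes
and clipped to [0,1]. Selection is the Benjamini–Yekutieli step-up with
harmonic correction `c(m) = Σ_{i≤m} 1/i` — valid under arbitrary feature
dependence — truncated to the `top_k = 180` smallest p-values (ties by
column order). Selection runs on the training partition only. Baselines
(GaussianNB, 100-tree random forest, RBF-SVM) are scikit-learn pipelines
over the selected, re-standardized columns.

## Deep branch

Five architectures share a 64-d embedding head and a softmax output:

* `conv1d`: three same-padded conv blocks (64 channels, kernel 3, stride 1,
  ReLU, max-pool /2), global average pooling, dense+tanh embedding. T must
  be ≥ 8 for the pooling pyramid.
* `lstm` / `gru`: two stacked recurrent layers; the default hidden width is
  `h = T` (an unusual coupling, kept configurable and overridden to 64 in
  the shipped experiments — see "Problem sizes").
* `lstm_att` / `gru_att`: the same encoders plus the bilinear
  (multiplicative) attention head `score(a_T, a_{t'}) = a_T W_a a_{t'}^T`,
  `α = softmax(score)`, context `c_T = Σ α_{t'} a_{t'}`,
  `h̃_T = tanh(W_c [c_T ; a_T])`. The last encoder state is the query since
  classification has no decoder.

The loss is mean categorical cross-entropy (consistent with the softmax
output; probabilities clipped at 1e-12 before the log). Dropout (rate 0.2)
applies to the embedding during training only. Adam uses lr 1e-3, β₁ 0.9,
β₂ 0.999 with global-norm gradient clipping at 5; early stopping watches
validation loss with patience 10 (the canned experiments use shorter
patience). Argmax ties break toward the lowest class index.

Everything runs on a ~350-line reverse-mode autodiff engine over numpy
(`wristgait.autodiff`) written for exactly the operators these networks
need. Gradient correctness is enforced by tests comparing analytic
gradients of the attention + cross-entropy path (and spot checks through
every full architecture) against central finite differences. Because the
backend is plain numpy, training is bit-deterministic given the seed, and
the reproducibility guarantee is exact, not statistical.

Initialization: Glorot-uniform weights, zero biases, LSTM forget-gate bias
1. Checkpoints are `.npz` archives (versioned JSON header + named tensors);
loading validates every shape against the spec.

## Evaluation and interpretability

`score()` computes the confusion matrix (rows = true), per-class
precision/recall/F1 with 0/0 defined as 0 (warned), accuracy, and the
support-weighted F1 `Fm = Σ_c (N_c/N_tot) F1_c`. `Fm` always lies between
the extreme per-class F1 values, and equals accuracy when every class has
P = R.

Attention traces pair α with the segment's raw channels, index-exact
(α_t annotates sample t); rendering stacks the D line plots over a
`Purples` intensity strip whose luminance decreases monotonically in α.
Embeddings export as CSV (64 columns + true/predicted label + subject);
an optional t-SNE projection (scikit-learn, fixed seed, perplexity ≤ 30) is
appended for plotting. t-SNE coordinates are not reproducible across
library versions, so only distance-based summaries are tested.

## Problem sizes in the shipped experiments

The canned experiments (`wristgait.experiments`, the test suite, and
`scripts/acceptance.py`) use desk-scale conditions chosen to finish on a
single CPU:

* class recovery: 6 default styles, 8 subjects × 60 s (tests) or
  5 subjects × 40 s (acceptance script), T = 150, recurrent hidden width 64,
  ≤ 35–60 epochs;
* blind-test comparison: 6 styles, 6 subjects × 30 s, T = 100, `conv1d`;
* quick CLI pipeline: 3 styles, 4 subjects × 30 s, T = 100.

The recurrent width 64 (rather than the h = T default) and these durations
are the package's own problem-size choices; all generator parameters are
the defaults described above.

## Numerical choices and edge cases

* Population-sd standardization, ε = 1e-12 degenerate-channel threshold.
* Softmax computed with max-subtraction; cross-entropy fused with softmax.
* `round()` (banker's rounding) in the window step; steps clamp to ≥ 1.
* KS test p-values from `scipy.stats.ks_2samp(method="auto")`.
* BY thresholds compared with `<=`; stable argsort makes top-k ties
  respect column order.
* A recording shorter than T yields zero windows with a warning, not an
  error; a class with fewer than two segments cannot be stratified.

## Known limitations

* The synthetic generator cannot certify real-world accuracy; its role is
  to make the pipeline testable and its class structure controllable.
* Pure-numpy training is CPU-bound; at h = T = 150 the recurrent models are
  roughly an order of magnitude slower than at h = 64, which is why the
  shipped experiments override the hidden width.
* The feature bank is a curated ~216-feature subset, not an exhaustive
  library-scale extraction; it is sized to make FDR selection meaningful,
  not to maximize baseline accuracy.
* Significance testing assumes exchangeable segments; temporally adjacent
  windows from one recording are correlated, so selected features should be
  read as relevant, not as carrying calibrated error rates.
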
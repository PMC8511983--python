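# wristgait

Fine-grained walking-style recognition from wrist-worn 6-axis inertial
signals.

People walk differently when they jog, shuffle over snow, carry a load in
one hand, keep their hands in their pockets, or stand still — and those
strategies show up directly in how the instrumented wrist moves. `wristgait`
classifies short windows of smartwatch accelerometer + gyroscope data
(D = 6 channels at 50 Hz) into walking-style classes, and explains its
decisions by showing *when* in the window the model was looking.

The package is aimed at researchers in wearable human-activity recognition
who want a complete, reproducible desk-scale pipeline: a controllable
synthetic gait-signal generator, classical feature-based baselines, and
attention-based deep sequence classifiers with built-in interpretability.

## The model

A recording is standardized per channel (zero mean, unit variance), cut into
non-overlapping windows `x ∈ R^{T×D}` (T = 100 or 150 samples ≈ 2–3 s), and
classified by one of five architectures: a temporal ConvNet (`conv1d`,
kernel 3, stride 1), two-layer stacked `lstm` / `gru` encoders, or their
multiplicative-attention variants `lstm_att` / `gru_att`. The attention head
scores every encoder state `a_{t'}` against the last state `a_T` with a
bilinear form and turns the scores into a per-time-step distribution:

    score(a_T, a_{t'}) = a_T W_a a_{t'}^T
    α = softmax(score),      c_T = Σ_{t'} α_{t'} a_{t'}
    h̃_T = tanh(W_c [c_T ; a_T]),      p(y|x) = softmax(W_s h̃_T)

`α` sums to one and can be rendered as a darkness strip under the raw
signal; `h̃_T` is the 64-d embedding used for 2-D visualization. Training
minimizes categorical cross-entropy with Adam (lr 1e-3, β₁ 0.9, β₂ 0.999)
with dropout and early stopping. The whole network runs on a small
numpy reverse-mode autodiff engine, so every run is bit-deterministic
under a fixed seed.

The feature-based branch computes a 12-family per-channel feature bank
(Fourier coefficients, autocorrelation/PACF, AR coefficients, entropies,
Lempel–Ziv complexity, trends, peaks, …), ranks features by one-vs-rest
Kolmogorov–Smirnov tests, keeps those passing a Benjamini–Yekutieli FDR
step-up (top 180), and fits naive Bayes / random forest / RBF-SVM baselines.

Evaluation reports per-class precision/recall/F1, the confusion matrix,
accuracy, and the support-weighted F1 score
`Fm = Σ_c (N_c/N_tot)·F1_c`. A "blind test" is evaluation on held-out
subjects never seen during training.

## Worked example

```python
import wristgait as wg
from wristgait.models import ModelSpec, SequenceClassifier, TrainConfig

cfg = wg.SimConfig(styles=wg.default_style_bank(6), n_subjects=4,
                   duration_s=20.0, seed=1)
dataset = wg.build_segment_set(wg.simulate_dataset(cfg), T=100)
train, test = wg.split(dataset, wg.SplitSpec("segment_random", 0.25, seed=1))

spec = ModelSpec(arch="lstm_att", T=100, D=6, n_classes=6, hidden_size=32)
results = SequenceClassifier(spec).fit(
    train, test, TrainConfig(max_epochs=40, batch_size=32,
                             early_stop_patience=8))
report = wg.evaluate(results, test)
print(report.summary())
```

which prints (exact numbers depend on the seed):

```
class  precision     recall         f1  support
    0     0.7273     0.8000     0.7619       10
    1     1.0000     1.0000     1.0000       10
    2     0.7778     0.7000     0.7368       10
    3     1.0000     1.0000     1.0000       10
    4     1.0000     1.0000     1.0000       10
    5     1.0000     1.0000     1.0000       10

accuracy    0.9167   (n=60)
weighted F1 0.9165
```

i.e. on the default six synthetic styles (walk / jog / shuffle /
arm-constrained / one-hand load / stationary) the attention LSTM separates
the held-out windows almost perfectly at this small training size; the
residual confusion sits exactly where it should — between regular walking
(class 0, ~1 Hz) and shuffling (class 2, ~0.7 Hz), the two most similar
cadences. More subjects or longer recordings (as in the shipped
experiments) push held-out accuracy to 0.96–0.98. `wg.attention_trace(results, test.segments[0])` then
yields the α-vector aligned to the raw window, and
`wg.render_attention(trace, "trace.png")` draws the six channels above the
attention strip (darker = more attention).

The same pipeline runs from the shell:

```sh
wristgait run --config examples/quick.yaml --out results/quick/
wristgait attend --config examples/quick.yaml \
    --checkpoint results/quick/checkpoint.npz --out results/quick/traces/
```

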
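# Methods

`mseienet` implements a multi-scale EEG-inception + self-attention encoder
network (MSEI-ENet) for 4-class motor-imagery EEG decoding, together with the
surrounding experimental machinery: training-set augmentation, evaluation
metrics, subject-independent cross-validation protocols, and a synthetic
ERD/ERS trial generator that makes every stage runnable and testable with no
dataset download.

## The decoding problem

Motor imagery modulates the sensorimotor rhythms recorded over motor cortex:
mu (8–12 Hz) and beta (~18–26 Hz) band power drops contralaterally to the
imagined movement (event-related desynchronization, ERD) and can rise in
other task conditions (ERS). A decoder receives a trial — here a 4 s,
3-channel (C3, Cz, C4) window sampled at 250 Hz, i.e. an `(L=1000, C=3)`
array — and predicts one of M=4 imagery classes (left hand, right hand,
feet, tongue).

## Architecture

**MSEI module.** Three parallel scales process the `(1000, 3, 1)` input.
Each scale starts with a three-branch temporal-convolution block (kernels
`(k,1)`, stride 1, 'same' padding, batch norm, ELU, dropout 0.25) whose
branches see different temporal extents: the Main scale uses kernels
500/250/125 with 8 filters, the auxiliary scales 125/64/32 and 32/16/8 with 4
filters. Each branch then applies a depthwise spatial convolution (kernel
`(1,3)`, depth multiplier 2, no bias) that collapses the electrode axis into
learned spatial filters. Branches are concatenated and average-pooled; the
Main scale adds a second three-branch block (kernels 125/62/31 — the
quarter-size kernels round down — on the 48-channel map) and a second pool.
Each scale ends with efficient channel attention (ECA): global average
pooling to a channel descriptor, a 1-D convolution of adaptive odd kernel
size `k ≈ |log2(C)/γ + b/γ|` (γ=2, b=1; nearest odd, ties up), and a sigmoid
gate per channel. All three scales emit `(125, 1, 24)`; concatenation gives
the `(125, 1, 72)` feature map. The trailing average-pool of the
concatenation is a size-(1,1) no-op kept only for structural fidelity, since
the documented output shape is unchanged by it.

**Encoder module.** The feature map is read as 72 tokens (the feature
channels) of width d_model = 125 (the temporal samples) — the only reading
consistent with the documented 72 × 125 encoder interface. Two identical
post-norm Transformer layers follow: multi-head scaled-dot-product
self-attention (h = 5 heads, d_k = 25, all projections biased) and a
position-wise ReLU feed-forward network, each wrapped as
`LayerNorm(x + SubLayer(x))`. No positional encoding is used (none is
documented), so the encoder is exactly token-permutation-equivariant — a
property the tests exploit. Dropout 0.3 is applied to attention weights and
FFN hidden activations, disabled at inference.

**Output module.** The tokens are folded back to `(125, 1, 72)` and passed
through two temporal convolutions (kernels `(8,1)` and `(4,1)`; filter counts
default to 32 and 12), ELU, dropout 0.25, a flatten and a dense softmax layer
over M classes.

## Parameter accounting

Counting conventions (fixed once, used everywhere): temporal convolutions
carry biases; depthwise convolutions carry none; batch normalization
contributes 4 parameters per channel (scale, shift, and the moving mean and
variance that frameworks report as non-trainable parameters); the ECA 1-D
convolution has k weights plus one bias. Under these conventions the two
auxiliary scales count exactly 1,116 and 456 parameters — matching the
published architecture table — and the layer-plan closed forms equal the
instantiated network's actual array sizes for every configuration in the
test suite (a dual-route check: formula vs. instantiation).

The remaining published per-module counts are reconciliation targets rather
than exact ones, because the original description leaves freedom no
convention choice can remove: the Main scale counts 91,292 here vs. 90,764
published (+0.6%; the residual would require a different kernel rounding or
bias convention that would then break the exact auxiliary counts); no integer
feed-forward width reproduces the published encoder count of 345,750 under
standard layer algebra, so d_ff = 435 was chosen to come closest (345,620,
−0.04%); the output-head filter counts are not documented, so (32, 12) was
chosen to land near the published 25,780 (26,016, +0.9%). Totals: 464,500
vs. 463,866 (+0.14%). `parameter_table()` always prints both columns.

## Augmentation

Training trials (never validation or test trials) are expanded in three
steps: quadratic-spline interpolation from T to U samples (original samples
placed at `t·(U−1)/(T−1)`, knot values preserved), a sliding window of length
w and stride s giving `⌊(U−w)/s⌋+1` windows per trial, and doubling of the
window set by adding i.i.d. Gaussian noise N(0, σ²), σ = 0.005. U is not
documented; it is set to `w + 4s` (1040 for w=1000, s=10) so that exactly 5
windows arise and each raw trial yields 10 training examples, matching the
documented 10N expansion. σ = 0.005 is only meaningful relative to unit-scale
data, which is why `zscore_normalize` (per trial and channel) is applied
before augmentation throughout this package; the original pipeline does not
state its normalization, and this is the reading that makes the noise level
sensible. The published per-class augmented counts (8502/2757/9445) are not
derivable from the stated 10N factor and the raw trial counts; the
implementation exposes its counts transparently instead of forcing those
numbers.

## Metrics

From an M×M confusion matrix (rows = true): one-vs-rest precision, recall
and F1 per class; overall accuracy = trace/total (the binary TP/TN form
generalized); macro-F1 = unweighted mean of the *unrounded* per-class F1;
Cohen's kappa = (P0 − Pe)/(1 − Pe) with P0 = accuracy and Pe from the
marginal products. Display rounding is half-up to two decimals. All printed
cells of the three published confusion-matrix tables reproduce exactly under
these definitions, with three one-ulp artifacts the implementation documents
rather than imitates: the exact pooled multiclass accuracy is 94.3050%
(printed 94.30), the exact both-hands F1 is 144/160 = 90.00% (printed
89.99), and the exact binary kappa is 0.96525 (printed 0.96). Macro-F1 is
additionally reported in the "mean of pre-rounded F1s" order (94.31 vs. the
exact 94.30); the exact value is normative.

## Cross-validation protocols

`global_cv` stratifies raw trials into k folds (k = 5 in the reference
design); per fold, a stratified 10% of the training portion is held out for
early stopping (the validation fraction is not documented; 10% is this
package's choice, recorded in every run), augmentation is applied to the
training portion only, and the untouched test fold is scored. `loso_cv`
holds out one subject at a time and averages per-subject accuracies. Both
protocols operate on raw-trial indices assigned *before* augmentation and
return an audit (`CvPlan.leakage_audit`) proving the folds partition the
trials — windows from one raw trial can never appear on both sides of a
split by construction. `hyperparameter_grid` evaluates a caller-supplied
harness over the documented grid (lr ∈ {1e-3, 5e-4, 1e-4}, dropout 0.1:0.05:0.5).

## Training

Adam (β1 = 0.9, β2 = 0.999) on categorical cross-entropy; reference learning
rates 1e-4 (binary, batch 128) and 5e-4 (multi-task, batch 256); up to 100
epochs with early stopping on validation loss. The early-stopping patience is
not documented; 10 epochs with min-delta 0 is used. Every source of
randomness (initialization, batching, dropout, augmentation noise) is seeded;
identical seeds reproduce loss histories bitwise under single-threaded
execution. Batch-norm momentum is 0.9 so that inference statistics converge
within short runs; predictions use moving statistics and disable dropout.

The layers themselves (convolutions, batch/layer norm, ECA, attention, the
optimizer and backpropagation) are implemented directly on numpy/scipy as
part of this package. Temporal convolutions run in the frequency domain: one
rFFT of the padded input serves the forward cross-correlation and, cached,
both gradient passes. Gradients are verified against central differences in
the test suite, and attention/FFN forwards against brute-force loop oracles.

## Synthetic data

`generate_mi_trials` emulates the ERD/ERS signature: each trial-channel
trace is 1/f^α background noise (α = 1, unit SD) plus unit-variance mu-band
and beta-band oscillators scaled by class- and channel-specific gains
(amplitudes 1.0 and 0.5). The default effect pattern is contralateral: left
hand attenuates C4 by (1 − effect), right hand C3, feet Cz; tongue enhances
mu at C3 and C4 by (1 + effect). Oscillators are band-limited Gaussian noise
(white noise masked to the band in the frequency domain, random phase at
every in-band frequency) rather than single sinusoids: band-limited noise is
the more physiological model of sensorimotor rhythms — they are stochastic,
not tonal — and it ensures the class signal is the band's *power*, not a
memorizable trial-specific frequency. Defaults mirror the reference
geometry: 3 channels, 250 Hz, 4 s, 21 trials per class, effect size 0.8.

What the generator does *not* emulate: volume conduction and channel
correlation, non-stationarity within trials, eye/muscle artifacts, inter-
subject variability beyond what different seeds produce, and 1/f deviations.
Passing the end-to-end tests therefore shows that the implementation can
discover and exploit spatial band-power structure — the core ERD/ERS cue —
not that it attains any particular accuracy on real recordings.

## Desk-scale presets and test design

The `full` preset is the reference architecture. The `reduced` preset
(filter counts halved, one encoder layer, d_ff = 64, head filters 16/6;
113,217 parameters) trains in minutes on one CPU at the full 4 s geometry.
The `tiny` preset shrinks the geometry to 200 samples for protocol tests
where only the mechanics matter. The end-to-end learning check trains the
reduced preset on 100 synthetic trials per class (effect size 0.9) for at
most 20 epochs with lr 1e-3 and batch 16 — lr 1e-3 is taken from the
documented hyperparameter grid because the post-norm encoder needs it to
leave its initial plateau within 20 epochs (at 5e-4 the no-encoder ablation
converges but the full model does not; this mirrors the general observation
that post-norm Transformers are harder to optimize than plain CNNs). Under
these conditions held-out accuracy reaches 100% vs. the 25% chance level,
and with effect size 0 it stays at chance — both asserted in the suite.

## Known limitations

- Real-recording benchmarks (GDF/EDF ingestion, the published accuracy
  tables) are out of scope; users supply arrays produced by standard EEG
  readers.
- The exact published Main-scale/encoder/output parameter counts cannot be
  reproduced from the text (see above); the implementation reports its own
  counts side by side and guarantees the auxiliary counts exactly.
- Training is CPU-bound numpy; it is meant for desk-scale experiments and
  correctness, not large-scale benchmarking.
- `AvgPool` requires exact divisibility of the temporal length; input
  lengths must be divisible by 8 for the default pooling plan, and the token
  width (L/8) must be divisible by the head count.
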
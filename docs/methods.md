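# Methods

## Problem setting

Five-class locomotion-mode recognition (LW, SA, SD, RA, RD) from two
synchronized wearable modalities recorded per trial: 8-channel surface EMG at
2000 Hz and a 7-channel wearable-robot stream (hip encoder angles and
velocities, IMU roll/pitch/yaw) at 71.42857 Hz. Each subject performs each
activity three times. Classification operates on fixed-length windows;
generalization is measured across *subjects*, never across windows of a
person seen in training.

## Preprocessing and segmentation

Raw signals are used without any filtering. Each channel is mapped to
[-1, 1] by global min–max normalization, x ↦ 2(x − min)/(max − min) − 1.
The extrema are computed **only on training-split recordings** and applied
unchanged to validation/test data, with out-of-range values clipped; a
constant training channel maps to 0. Whether the original normalization was
global, per subject, or per recording is not recoverable from available
descriptions; per-channel training-global statistics were chosen because
they make test-time behavior well defined and leak nothing across splits.
Per-recording normalization is available via
`compute_normalization_stats([rec])` for sensitivity checks.

Windows are 1.76 s with overlap ratio 0.9, read as the fraction of a window
shared with its successor, so the stride is floor(W·(1 − overlap)) samples:
352 for EMG (W = 3520) and 12 for the robot stream (W = 125). Window lengths
use floor — 71.42857 Hz × 1.76 s = 125.71 → 125, which is what the published
window shapes imply. Trials shorter than one window yield zero windows and a
warning.

For multi-head training the two modalities are windowed as *pairs*: window i
starts at time i·0.176 s, and each modality takes the window starting at
floor(t·rate) samples. The start times then agree within one robot sample
period, which a uniform per-modality sample-domain stride cannot achieve
(352/2000 s ≠ 12/71.42857 s, so uniform strides drift by ~10 robot samples
over a typical trial). Single-modality segmentation keeps the conventional
uniform stride. Trailing windows that fit only one modality are dropped from
both.

Splits are drawn at the subject level at an 8:1:1 ratio; validation and test
sizes are round(N/10) and the remainder goes to train, giving 400/50/50 for
N = 500. Assembly asserts pairwise-disjoint subject sets on every dataset it
produces.

## Synthetic gait generator

The generator's contract is *structural* fidelity, not waveform realism: the
right channel counts and rates, time-aligned modalities, three trials per
activity per subject, and per-activity trial-duration and gait-cycle-period
distributions matching the study's published statistics (durations, mean
(SD) s: LW 4.81 (1.52), SA 4.65 (1.12), SD 4.6 (1.1), RA 4.9 (1.36), RD
4.34 (1.3); cycle periods from the left-heel-strike statistics: 1.40 (0.33),
1.57 (0.40), 1.51 (0.32), 1.93 (0.47), 1.62 (0.48)).

Signal model per trial: hip angles are sinusoids at the sampled cycle period
with activity-specific amplitude and offset and a subject-specific phase;
the right leg is π out of phase (alternating gait); velocities are the
analytic derivative rescaled to rpm; roll/yaw are small zero-mean
oscillations; pitch carries an activity-specific offset (positive on
ascents, negative on descents — ±4.3° for the ramps, matching a 4.3° slope,
±8° for stairs) plus a square-wave ripple on stairs that separates SA/SD
from RA/RD. EMG channels are zero-mean Gaussian noise amplitude-modulated by
periodic per-muscle burst envelopes (wrapped Gaussian bumps at
activity-specific gains; left/right legs half a cycle apart). Additive robot
noise is clipped at ±3σ so angle channels stay within offset ± amplitude ±
3·noise_sd.

`class_separation` linearly interpolates every activity-specific parameter
— including the duration and cycle-period distributions — between the
across-activity pooled value (0: all activities statistically identical,
classifiers can only reach the 0.2 chance level) and the configured
per-activity value (1, the default). Held-out performance of a fixed
classifier is non-decreasing in this dial, which the tests check at three
levels.

Durations are drawn Normal(mean_a, sd_a) and clamped below at one window
length (1.76 s) so segmentation never produces an empty trial. Clamping was
chosen over resampling-style truncation deliberately: the floor sits 2–2.6
SD below the means, where resampling inflates the pooled mean by ≈ 0.045 s
(≈ 3 standard errors at 7,500 trials) while clamping biases it by only
≈ +0.01 s, keeping the generator calibrated to the published pooled mean of
4.66 s. Trial randomness derives from a per-(seed, subject, activity, trial)
seed sequence, so any trial is reproducible independently of generation
order.

What passing tests on this generator do **not** show: performance on real
EMG (no motor-unit physiology, no electrode artifacts), robustness to
transitions between activities, or the real data's published F-measures,
which require the original dataset.

## Architecture family and benchmarks

The family fixes kernel 3, stride 1, same padding, batch-norm + ReLU after
every convolution, pool size 2 (max or average, valid padding — a trailing
odd timestep is dropped), and softmax over 5 classes. Free structure:
blocks per head 1–3, convolutions per block 1–3, filters in {16, 32, 64,
128}, dense layers 1–3 with widths in {32, 64, 128, 256, 512}. Adjacent
parameterized layers must differ by exactly a factor of two; equality is
permitted only at block boundaries and only when explicitly enabled.
Whether batch-norm also follows dense layers is not pinned by the published
table ("batch normalization: yes" without placement); it is a config flag,
default off. Multi-head instances concatenate flattened per-modality head
outputs before the shared dense stack.

The published reference instances fix block/dense structure but not
per-layer filters (the architecture figures are not machine-readable), so
this package's reference instances use ascending twofold chains: EMG — 3
blocks × 2 convs (16,32 | 64,128 | 64,128), one 512-unit dense layer, lr
1e-4, batch 128; robot — same conv structure with dense 128 then 256, lr
1e-4, batch 32; two-head — an EMG head of 2 blocks × 1 conv and a robot
head of 2 blocks × 3 convs with one 128-unit dense layer.
`nets.solve_family_spec` enumerates the discrete space for instances
matching a given exact (trainable, non-trainable) pair, as a
constraint-satisfaction aid for published totals.

Benchmark internals were fixed by solving their published parameter totals
against their stated layer structure:

* **DeepConvLSTM**: 4 × conv(64 filters, kernel 5, valid) + ReLU, LSTM(128)
  × 2, dense softmax. Closed forms conv k·c_in·f + f and LSTM
  4((d + u)u + u) give 295,301 / 294,981 trainable on the 3520×8 / 125×7
  shapes, matching the published totals exactly; no batch-norm (0
  non-trainable).
* **LSTM-CNN**: L(32)–L(32)–C(64, k5)–maxpool(2)–C(128, k3)–GAP–BN–softmax.
  The kernel sizes (5 then 3) are the unique pair in this structure
  reproducing 49,477 / 49,349 trainable, and the single batch-norm on the
  128-wide GAP output carries the published 256 non-trainable parameters.
* **DDLMI**: 4 × [conv + ReLU + max-pool], dense, batch-norm, dropout,
  softmax. Its filter counts and dense width are not recoverable; they are
  config-driven with defaults (16, 32, 64, 128 filters, kernel 5, dense
  288) whose batch-norm width reproduces the published 576 non-trainable
  parameters. Its trainable totals are deliberately not treated as
  verifiable constants.
* **Dual-head variants** cut each branch immediately before its classifier,
  concatenate (128 + 128 = 256 wide for both recurrents), and add a single
  softmax layer — the only merge point that reproduces the published
  590,277 (DeepConvLSTM) and 98,821 (+512 non-trainable, LSTM-CNN) exactly.

Parameter accounting is always double-checked: a closed-form path over the
spec and a count over the instantiated weight tensors must agree to the
integer.

## Neural-network engine

The engine is a purpose-built minimal numpy implementation: conv1d via an
im2col matrix product, batch-norm over the channel axis (momentum 0.99, eps
1e-3; 2c trainable + 2c running-moment parameters), max/average pooling,
LSTM (sigmoid gates, tanh cell, forget bias 1), dense, dropout (inverted),
softmax cross-entropy, and Adam (β₁ 0.9, β₂ 0.999, eps 1e-7). All backward
passes are hand-derived and verified against central-difference numeric
gradients to < 1e-6 in the test suite. Initialization: He-normal for
convolutions (ReLU-followed), Glorot-uniform elsewhere; all randomness flows
through explicit `numpy.random.Generator` objects.

## Training protocol and metrics

Final models train with Adam on categorical cross-entropy for up to 200
epochs. "Improvement" means a strictly lower validation loss than the best
seen; after 10 consecutive epochs without improvement the learning rate is
multiplied by 0.9 (the wait counter resets on improvement and after each
reduction; the factor can fire repeatedly, with no lower bound). The weights
of the minimum-validation-loss epoch are restored at the end. The loss is
categorical cross-entropy, implied by the softmax output; non-finite losses
abort with a diagnostic.

Metrics come from the 5×5 confusion matrix (rows true, columns predicted)
via one-vs-rest counts. Macro averaging is the default, with the
parenthesized dispersion read as the across-class standard deviation of the
per-class metric (population SD, ddof 0). Accuracy is primarily
trace/total; the mean per-class one-vs-rest accuracy is reported alongside
as `accuracy_macro_ovr`. Classes never predicted (never present) get
precision (recall) 0, logged. The confusion-matrix construction itself is
delegated to scikit-learn; the formulas on top of it are implemented and
oracle-tested here.

## Structural search

The search space is conditional — per-block choices exist only for
instantiated blocks — and every dimension is categorical. Chains of filter
and dense widths are encoded as a starting width plus up/down twofold moves
that reflect at the ends of the allowed sets, so every sampled point
satisfies the adjacency constraint by construction and every legal structure
is reachable.

The optimizer is a categorical TPE: after 10 startup trials, finished trials
split at the γ = 0.25 quantile of the score into good/bad sets; each active
dimension gets Laplace-smoothed categorical densities l(x) and g(x); 24
candidates are drawn from l and the maximizer of Σ log l/g is evaluated.
These defaults (γ, startup count, candidate count) follow common TPE
practice and are recorded with each trial log. The budget is exact: a
50-evaluation search calls the objective exactly 50 times; trials whose
architecture cannot be built for the given window shape (temporal collapse
under pooling) score −inf and the search continues. Trial scoring trains
the candidate for 20 epochs at its sampled learning rate and batch size and
measures validation macro F-measure; ties break by lower validation loss,
then lower trial index. Single- vs multi-head is part of the space only
when two modalities are supplied.

## Problem sizes used in tests

The test suite exercises the full pipeline at reduced scale chosen to keep
the properties sharp: generator calibration uses the full 7,500-trial
duration model; the end-to-end classification property uses 20 subjects
(≈ 5,400 robot windows), the robot reference architecture and an 8-epoch
budget (the protocol allows up to 30 here; convergence occurs by epoch
3–4); the chance-level property at zero separation uses 3 epochs; search
properties run on a deterministic discrete surrogate with brute-force
enumeration as the oracle plus a 1-epoch smoke of the real objective.

## Known limitations

* Published per-split *window counts* are not reproducible under any
  consistent reading of the stated window/overlap semantics and trial
  durations (they imply ~5.5 windows per trial where the stated 0.9 overlap
  on ~4.7 s trials yields ~18); this package implements the standard
  semantics and makes no attempt to match those totals.
* DDLMI's trainable parameter totals and the proposed models' exact filter
  configurations are under-determined by their descriptions; both are
  exposed as configuration rather than hard-coded guesses.
* LSTM training is supported by the engine but slow in pure numpy; the
  benchmarks are primarily inference/accounting references, and the trained
  models in tests are CNN-family instances.
* The generator's EMG is statistically, not physiologically, realistic; see
  the generator section for what conclusions it does and does not support.
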
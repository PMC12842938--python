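# Methods

## Model

The classifier maps a pair of feature matrices — audio `T_a × D_a`, video
`T_v × D_v`, rows are time steps — to two class probabilities (class 1 is
the positive class everywhere).

### Multi-scale temporal encoding (per modality)

Each modality matrix is split into univariate channels. Every channel is
sliced into overlapping patches at two resolutions; with patch length `P`
and stride `Str` the number of windows is `N = ⌊(L − P)/Str⌋ + 1` and
trailing steps not covered by a full window are dropped (the count formula
is exact only under flooring; no padding). The patch-to-stride resolution
`R = P/Str` quantifies overlap; configuration validation enforces
`R_long < R_short`, i.e. the long-range scale is the low-resolution one.
Shipped geometry: long `P=16, Str=16` (R=1), short `P=4, Str=1` (R=4).

*Long-range expert.* Patches are linearly embedded to `d_model` and run
through a selective state-space block: LayerNorm → Linear up-projection →
causal depthwise conv (left padding `K−1`, so no future leakage) → SiLU →
per-step parameters `Δ = softplus(Linear)`, `B = Linear`, `C = Linear` →
discretization `Ā = exp(Δ ⊗ A)`, `B̄ = Δ ⊗ B` → sequential scan
`h_t = Ā_t ⊙ h_{t−1} + B̄_t x_t`, `y_t = ⟨C_t, h_t⟩` → SiLU gate →
down-projection → residual. The readout uses the state (`y_t = C_t·h_t`);
the memoryless alternative would make the recurrence irrelevant. `A` is
diagonal per hidden channel, parameterized `A = −exp(a_log)` with `a_log`
initialized to `log(1..state_dim)`, so `|Ā| < 1` and the recurrence is a
contraction; `a_log` is trainable with a freeze switch. The scan is
implemented as the literal sequential loop over the (short) patch axis —
correctness is defined by a plain-numpy oracle and the differentiable scan
is tested against it; an associative-scan schedule would be an optimization,
not a semantic change. Cost is linear in sequence length (asserted with an
operation counter, never a clock).

*Short-range expert.* Patches are embedded, given learnable additive
positional encodings, and run through pre-norm transformer blocks whose
self-attention is restricted to a symmetric band `|i − j| ≤ ⌊w/2⌋`
(truncated at the edges; classification has no reason to be causal).
Masked pairs receive −1e9 before the softmax, so each attention row is a
distribution over allowed positions only. The banded form is computed per
diagonal offset, making the per-layer operation count O(N·w); it matches
the dense masked reference to rounding. Stacking `l` blocks grows the
receptive field to about `l·w`. Defaults `w = 5`, `l = 2` are package
choices (no published value exists).

*Long-short routing.* Per channel, a global context vector is the time
mean mapped through a linear layer; a two-way softmax yields
`p_long + p_short = 1`. The two token sequences are scaled by their weights
and concatenated along the token axis (`N_long + N_short` tokens). Channel
token matrices are averaged into one matrix per modality, keeping token
count independent of the channel dimension; the router is shared across a
modality's channels.

### Dynamic fusion

*Modality level.* A light audio probe (depthwise conv → mean pool → linear
to 512) feeds a gating MLP (512→256→ReLU→Dropout 0.2→4→softmax). Four
pathways of increasing cost are available: E1 audio-only; E2 audio plus
video compressed by a fixed seeded Gaussian random projection of the
feature dimension to `min(d, max(8, d/4))` with `1/√r` scaling (squared
norms preserved in expectation; measurement without reconstruction — a
reconstruction step would re-add the cost the pathway exists to avoid);
E3 audio + full video with one bidirectional cross-attention round; E4 with
three rounds. Exactly one expert executes per sample. Inference selection
is either plain argmax or the thresholded policy (default): above
confidence 0.75 take the argmax, except that a non-audio argmax with
confidence ≤ 0.9 escalates one tier (capped at 4); below 0.75, fall back to
path 2 when the audio-only score exceeds 0.4, else path 4. Argmax ties
break to the lowest index. The nominal per-expert costs 0.6/1.0/1.6/2.3
GFLOPs drive the resource-aware loss by default; an analytic
elementary-operation counter (strictly increasing over the tiers by
construction) is available behind a config switch.

*Fusion level.* `N` fusion cells (default 4) each hold four candidate
operations mirroring the pathway strategies: O1 audio-internal aggregation
(provably never reads video), O2 gated single-head cross-attention at
reduced dimension, O3 bidirectional 4-head cross-attention with residuals,
O4 a 3-level co-attention stack plus a self-attention decoder block. A
single global gating head emits all per-unit decisions at once from pooled
modality features. Only the selected operation executes.

When the video modality is entirely absent the forward clamps the path to
E1 and every cell to O1 rather than erroring; partially missing time steps
are handled upstream by the masking/imputation protocol.

### Training

Loss: `L = L_task + λ·(Σ p_i C(E_i) + Σ_j Σ_k π_{j,k} C(O_k))` with the
gate probabilities taken before argmax. `L_task` is cross-entropy or focal
loss `−α_y (1−p_y)^γ log p_y` (γ = 2, α = inverse class frequency,
probability clamped at 1e-12). λ defaults to 0.01 (no published value).
Discrete decisions are straight-through Gumbel-Softmax samples on the
gate logits; the temperature anneals geometrically from 5.0 to 0.1 over the
scheduled epochs. Validation and early stopping run in hard (deployable)
mode. Optimization: Adam, learning rate 1e-4, batch 16, patience 15 within
at most 120 epochs, fixed seed 42 — all configurable. Samples sharing a
pathway are executed as one sub-batch; gathers and concatenations are
exact, so grouping changes nothing numerically. The final tokens are
mean-pooled over time before the linear classifier (pooling is otherwise
unspecified; the mean is the neutral choice).

Splits are by sample id with largest-remainder apportionment of the
ratios (default 7:1:2) after a seeded shuffle, so splitting is a pure
function of (ids, ratios, seed).

## Synthetic data

The generator emulates the *shapes* of behavioral features (defaults: 25
audio channels, 136 video channels, 128 steps — the scale of frame-level
acoustic descriptor and facial landmark/AU/gaze/pose exports), not their
real statistics. Labels are i.i.d. Bernoulli(positive_fraction). On a
seeded quarter of the channels of each informative modality:

* trend — positives get a linear ramp of total rise `trend_strength` plus a
  slow random-phase sinusoid at 0.15× that amplitude (kept small so the
  least-squares slope separates the classes; at larger amplitudes the
  phase jitter dominates the slope statistic);
* fluctuation — a period-4..8 sinusoid, amplitude `2×fluctuation_strength`
  inside ~3 random bursts covering about half the steps for positives,
  versus a weak (0.3×) flat-envelope carrier for negatives, so the class
  signal at this scale is the burst modulation, readable from local
  variance.

The non-informative modality always receives the negative-class signal, so
its distribution carries no label information. I.i.d. Gaussian noise
(`noise_sd`, feature z-score units) is added everywhere. An optional
label-independent per-sample baseline offset (`baseline_offset_sd`,
default 0) emulates session/calibration shifts; with it enabled, absolute
level is uninformative and only temporal structure discriminates.
Perturbation protocols: additive Gaussian noise per modality; truncation
(keep first `⌈(1−rate)·T⌉` rows); resampling (linear down-interpolation to
`⌈(1−rate)·T⌉` points and back, information loss at preserved shape);
shuffling (a seeded fraction of rows permuted among themselves); missing
values (a seeded fraction of rows zeroed); modality masking (whole time
steps flagged and zeroed, matching frame-level tracking dropouts) with
zero or per-feature-mean imputation.

What passing tests on this generator do **not** show: real acoustic and
facial features are cross-correlated, non-stationary and non-Gaussian;
class signals are far weaker and entangled across scales; and corpus-scale
accuracies cannot be inferred from desk-scale synthetic separability.

## Numerical and scale choices

Everything runs in float64 on a small reverse-mode autodiff engine
(`dynmodal.nn`); softmax subtracts a detached row max; gradient
correctness is spot-checked against finite differences. The
elementary-operation counter hooks every tensor primitive, which is how
all complexity claims and the analytic cost model are measured. Tests and
the acceptance script use a scaled-down study configuration (sequence
length 48, 4+4 channels, `d_model` 12, hidden 24, state 4, 1–2 fusion
units, 96–400 samples, learning rate 3e-3, ≤20 epochs) chosen as the
smallest setting at which every mechanism is exercised end to end;
published recipe values remain the shipped defaults.

## Known limitations

* The directional preference of the long-short router (higher `p_long` on
  trend-only data than on fluctuation-only data) does not emerge reliably
  at desk scale: the scale weights act as a global gain the classifier can
  compensate, so their optimum is weakly identified. The suite asserts the
  router's end-to-end trainability (gradients flow, parameters move,
  routing departs from the symmetric init) instead of the direction.
* Nominal expert costs are constants taken at face value; the analytic
  counter measures this implementation, not the published architectures.
* The sequential scan favors clarity over speed; long sequences pay a
  Python-loop constant even though the operation count is linear.
* No text modality, no pretrained feature extractors, no GAN/autoencoder
  recovery of missing modalities (zero/mean imputation only).
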
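# Methods

## Problem setting

Scalp EEG is routinely contaminated by physiological artifacts — eye movement,
muscle activity, cardiac signal, motion — that occupy irregular stretches of
individual channels. `eegimpute` treats artifact correction as masked
multivariate time-series imputation: a trial is a `(T × D)` matrix in
microvolts with artifact samples encoded as `NaN`, and the task is to replace
exactly those cells with predicted values while leaving every observed cell
untouched. Which samples *are* artifacts is assumed known (detection by ICA,
bad-channel inspection, or any external pipeline is out of scope); the package
also synthesizes artifacts itself by removing observed values, which makes the
prediction quality measurable against held-out truth on any recording.

## Model

The imputer is a bidirectional recurrent network over one trial. Let
`m_t ∈ {0,1}^D` be the observation mask at step `t`, `δᵗ_t ∈ ℝ^D` the
per-channel count of samples since the last observation (the temporal gap),
and `δᵈ` the matrix of Euclidean distances between electrode positions on a
unit head sphere. Per step and direction:

```
β_t = exp(−max(0, W_β δᵗ_t + b_β))          temporal decay factor, ∈ (0,1]^H
η_t = exp(−max(0, W_η s_t  + b_η))          spatial decay factor,  ∈ (0,1]^H
γ_t = β_t + λ η_t                           combined discount, λ ∈ [0,1]
ĥ   = h_{t−1} ⊙ γ_t                         discounted history
x̂_t = W_x ĥ + b_x                           per-channel estimate
x_t = m_t ⊙ x_t + (1−m_t) ⊙ x̂_t             masked input filling
h_t = tanh(W_xh (x_t ⊕ y) + W_hh ĥ + b_h)   recurrent update
```

`s_t` is a per-step spatial summary: the mean distance profile of the channels
currently missing — the channels that must borrow from neighbors — so the
spatial gate discounts history more when the missing channels sit far from
informative context. `y` is a per-trial state vector describing the
experimental condition (stimulus class); `⊕` is concatenation. The backward
direction runs the same machinery on the time-reversed trial with its own
weights (temporal gaps recomputed on the reversed mask), and the final
estimate is the arithmetic mean of the two directional estimates. The
completed series is `m ⊙ x + (1−m) ⊙ x̂`; observed cells are preserved
bit-exactly by construction.

Two properties are worth stating explicitly:

- the estimate at step `t` is produced from discounted *history only*, so no
  cell's prediction ever conditions on its own value;
- both gate outputs lie in `(0, 1]` for every input and every parameter value
  (exponential of a nonpositive number), so the discount can suppress but
  never amplify or sign-flip the hidden state.

### Recurrent cell

The update above is a plain tanh recurrence with the discount applied to the
previous hidden state. This is deliberately the printed form of the update
equations rather than a full LSTM cell: the decay gates already provide the
forgetting mechanism an LSTM's gates would supply, the trials are short
(~1 s epochs), and the simple cell admits a line-by-line independent oracle,
which the test suite exploits (hand-fixed weights on a 2-channel, 3-step,
H = 2 fixture must match straight-line arithmetic to 1e−10). Gradients are
hand-derived reverse-mode through the full graph (gates, filling, recurrence,
bidirectional averaging, state embedding) and are checked against central
finite differences for every parameter array.

### State vector

The state encoder is pluggable:

- **label** (default): a learned embedding row per class label; with an
  identity table this is a one-hot condition code.
- **conv**: time-binned averages of the observed trial, linearly projected
  and squashed — a lightweight learned trial-feature extractor.
- **external**: pass-through of any per-trial feature vector computed
  elsewhere (e.g. the penultimate layer of a separately trained EEG
  classifier), length-checked against the configured state dimension.

### Electrode geometry

Coordinates live on a unit-radius sphere (+z through the vertex Cz, +x
through the nose). Midline and circumferential-ring electrodes of the
10-20/10-10 system are placed at their standard inclinations/azimuths
(ring at 72°, 18° steps); intermediate electrodes are interpolated along the
circular arc joining their row's lateral anchor to the midline. This yields
exact sagittal mirror symmetry for homologous pairs and Cz exactly at the
apex. Distances are unitless (sphere radius 1): only relative geometry
matters, the gate weights absorb scale, and distances are invariant to any
rigid rotation of the frame (tested to 1e−9). Fixtures for a 32-channel cap
and the 22-channel motor-imagery layout are built in; arbitrary montages load
from JSON.

## Training

Training is self-supervised. Each batch hides an additional fraction
(`hold_out_rate`, default 0.10) of the *observed* cells — drawn fresh every
epoch — and minimizes the mean squared estimate error over exactly those
held-out cells (the scored-cell count is the loss normalizer). Cells that
were already missing in the input have no truth and are never scored. This
makes the training loss computable on real artifact-bearing data, where the
truth under real artifacts is unknown.

- Optimizer: Adam, learning rate 0.001, batch size 32 (in-package
  implementation; gradients clipped at global norm 5 to guard recurrent
  blow-ups).
- Mixing weight λ = 0.8 by default.
- Validation: 15 % of the trials, split once per run; the validation hold-out
  masking is *fixed* (seeded once) so the early-stopping criterion is a
  consistent estimator across epochs. Training stops after `patience`
  (default 10) non-improving epochs, capped at `max_epochs` (default 300),
  and returns the weights of the best validation epoch, never the last.
- Normalization: per-channel z-scoring computed from the observed cells of
  the training split, stored in the model artifact and inverted on output.
  Recurrent training on raw microvolt scales is numerically fragile.
- Determinism: all randomness flows from `numpy` seed sequences derived from
  the config seed; identical dataset + config reproduce byte-identical
  histories and weights.

### Ablation arms

Structural switches mirror the model's two additions over the
mask + temporal-decay backbone: `no_state` drops the state vector
(zero-length concatenation), `no_space` removes the spatial gate and forces
λ = 0, `no_state_space` does both — leaving exactly the backbone, which the
tests verify by parameter-count and output equality. The ablation harness
trains all four arms on the same trials and scores them on the same corrupted
evaluation trials.

## Evaluation protocol

Corruption removes `⌊rate × n_observed⌋` cells uniformly without replacement
(pointwise mode; a burst mode removes contiguous single-channel runs, closer
to real artifact morphology, and overshoots the target by at most one burst).
Removed values are retained as ground truth. MAE and RMSE are computed over
masked cells only — scoring observed cells would reward copying the input —
and RMSE ≥ MAE is asserted on every report. The mean-imputation baseline
fills each masked cell with its channel's observed within-trial average
(trial-global mean for a fully masked channel). The standard rate grid is
{2.5, 5, 7.5, 10, 12.5, 15, 17.5, 20} %.

## Synthetic benchmark

The generator emulates the structure the model exploits in evoked-response
data: each class carries a Gaussian-windowed half-sine deflection at a
class-specific latency, strongest at a class-specific focal electrode and
decaying across the scalp as `exp(−distance/scale)`; background noise mixes a
spatially correlated component (kernel `exp(−δᵈ/scale)` over the montage)
with white sensor noise, optionally AR(1)-colored in time; trials carry
amplitude and latency jitter. Defaults: 8 µV peak, 2 µV noise, kernel scale
0.8, 10 % amplitude jitter, 2-sample latency jitter, white noise.

Problem sizes used by the tests and the acceptance script: a 200-trial,
T = 128, 32-channel, 3-class benchmark (160 fit / 40 evaluation trials,
H = 32, ≤ 60 epochs) for the model-vs-baseline comparison and the rate sweep;
a 150-trial, T = 96, 22-channel fixture with strong, spatially broad class
waveforms (20 µV peak, 1.5 µV noise, kernel scale 1.5, H = 24, ≤ 50 epochs,
3 seeds) for the ablation study, where condition information has to matter
for the state arm to separate from its ablation.

What passing on this benchmark does *not* show: real EEG has 1/f background
spectra, non-stationary artifacts that occupy long windows, inter-subject
variability, and volume-conduction structure richer than a distance kernel.
The synthetic results demonstrate mechanism (the gates and conditioning are
wired correctly and help when the emulated structure is present), not
clinical performance.

A known consequence of the uniform-removal protocol: the mean baseline's
expected per-cell error is almost independent of the artifact rate (the only
rate-dependent term is the O(1/n_obs) variance inflation of the per-channel
mean), so its error-vs-rate curve is flat to within Monte-Carlo noise at
these problem sizes. On real recordings, where removal interacts with real
artifact structure, baselines degrade visibly with rate; the synthetic
protocol does not reproduce that trend, and the rate-sweep test records this
honestly rather than asserting around it.

## Numerical choices and degenerate inputs

- Hidden activation tanh; output projection linear (targets are unbounded
  microvolt values). Initial hidden state zero. Weights uniform
  ±1/√H (gates ±0.05, biases zero), seeded.
- Gap spacing is 1 sample (uniformly sampled trials); an optional flag scales
  the decay matrix to seconds.
- The mask is always derived from NaN positions, never user-supplied, so mask
  and values cannot disagree.
- A fully masked channel is imputed from temporal/spatial/state context; a
  fully masked trial is an error (nothing to condition on). A trial whose
  first samples are masked has gap 0 at t = 1 by definition.
- Corruption counts use floor; pointwise mode hits the count exactly.
- Tie-breaking/rounding in the validation split uses `round(fraction·N)` with
  both sides required nonempty.

## Limitations

- No attention/transformer variant, no GPU path, no multi-trial joint
  imputation; trials are imputed independently given their state vector.
- The spatial summary (mask-weighted mean distance profile) is one consistent
  resolution of how per-channel distance profiles should gate an H-dimensional
  hidden state; alternatives (per-channel gating, attention over neighbors)
  are plausible and unexplored here.
- The cell state question (whether a gated cell's internal state should also
  be discounted) does not arise for the simple recurrence; a future LSTM cell
  would need that choice made explicit.
- EDF support is read-only and epochs around annotation markers; BrainVision/
  FIF/GDF and streaming input are out of scope.
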
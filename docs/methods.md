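# Methods

## Problem and representation

Camera-based (remote) photoplethysmography infers vital signs from the
minute color modulation cardiac and respiratory activity imprints on facial
skin. We work on the spatial–temporal map (STMap) representation: the face
region of interest is partitioned into a grid of blocks (default 8×8), each
block's per-channel spatial mean per frame becomes one row, and rows are
min–max normalized per channel over the analysis window. The result is an
`H×W×3` image whose `W` axis is time (default 64 rows × 256 frames ≈ 8.5 s
at 30 Hz; both dimensions must be divisible by 32 for the backbone's five
halvings). Face detection and landmarking are out of scope: the API takes a
caller-supplied ROI rectangle, and heterogeneous inputs are aligned by
cubic-spline resampling onto a uniform 30 Hz grid (scipy's not-a-knot
boundary conditions: the interior error on band-limited physiological
signals is ~1e-4 relative, vs ~0.1 endpoint error for natural boundary
conditions).

## Network

The estimator is a hierarchical hybrid of three mechanisms with distinct
inductive biases, applied in order of decreasing resolution:

* **Convolutions** (stem + residual blocks) extract local spatio-temporal
  texture cheaply at high resolution. Residual layers follow
  `α̂ = GELU(BN(Conv3×3(α)))`, `α ← BN(Conv3×3(α̂)) + α`; downsamplers are
  stride-2 3×3 convolutions with batch norm, doubling channels at each
  halving (C, 2C, 4C, 8C at strides 4/8/16/32).
* **Selective state-space scans** propagate information along the sequence
  in linear time. The continuous system `ψ' = Aψ + Bρ, φ = Cψ` is
  discretized by the zero-order hold `Ā = exp(ΔA)`,
  `B̄ = (ΔA)^{-1}(exp(ΔA)−I)(ΔB)`, `C̄ = C`; a truncated-series evaluation of
  the equivalent integral `(∫₀^Δ e^{sA}ds)B` replaces the inverse when
  `‖ΔA‖ < 1e-6`, removing the singularity at `A → 0` (the branch taken is
  recorded on the result). In the network the scan is input-dependent
  (Mamba-style): per token, `Δ = softplus(Linear(x) + bias)`, `B_t` and
  `C_t` are linear projections of the token, and `A` is a shared
  negative-real diagonal initialized to `−1…−n` per channel (state width
  n = 16 by default, 8 in the desk model). With constant `Δ, B, C` the layer
  reduces exactly to the time-invariant recurrence, which is what the
  equivalence tests exploit.
* **Attention** restores global, order-free interactions late, where the
  token count is small. Standard pre-norm multi-head self-attention with
  `1/√d_head` logit scaling.

Each stage stacks ⌈N/2⌉ integrator layers then ⌊N/2⌋ attention layers
(N = 2 by default; odd N is allowed in the sweep harness with the extra
layer going to the integrator half). The integrator is a two-path mixer:
the main path is Linear(C→C/2) → depthwise non-causal conv (k=3) → SiLU →
scan; the vice path is the same without the scan, keeping an unfiltered
view of the sequence; their concatenation is projected back to width C
(the projection is necessarily C→C since its input is two C/2 halves).
Tokens are flattened row-major so the scan runs along the temporal axis.
No positional embedding is added by default — convolutions and the scan
carry order, and the attention layers' permutation equivariance is tested —
but a learnable embedding can be switched on.

Global average pooling and a linear layer produce the task-shared vector
`r` (D_r = 128 default). Per scalar task a gate
`σ = Sigmoid(LN(Linear(ReLU(LN(Linear(r))))))` masks the shared features,
`r' = σ ⊙ r`, and a single linear head regresses the (z-scored) target.
The BVP head cannot read the pooled vector — a waveform needs a temporal
axis — so it projects the flattened stage-2 pre-pooling tokens linearly to
a length-T waveform.

## Loss

`L = θ·(w₁ L_SpO2 + w₂ L_RR + w₃ L_BVP) + L_HR`, with L1 losses on the
z-scored scalars (smoothed as √(e²+1e-24) for differentiability at 0) and
`L_BVP = 1 − ρ(pred, ref)` (negative Pearson; scale-free, matching the
waveform's arbitrary units). `θ = min(1, step/(warmup·total))` ramps the
auxiliary tasks in after a warm-up (default 10% of training), so early
gradients concentrate on the primary HR task. The waveform term is optional
(`include_bvp`, default on) for settings without a BVP reference. The
large-scale recipe uses w₁ = w₂ = w₃ = 1e-4 at batch 60, 20 000 Adam
iterations and learning rate 1e-5 (`TrainConfig.published()`); the desk-scale
defaults — batch 8, 500 iterations, learning rate 1e-3, equal unit weights —
are sized so the tiny configuration (C=8, N=2, D_r=32, ~380 k parameters)
trains in minutes on one CPU while all four tasks receive usable gradient.
Scalar targets are z-scored by the training set's statistics (stored on the
model and inverted for metrics) to balance gradient magnitudes across tasks
whose units differ by an order of magnitude.

## Synthetic data

The generator emulates exactly the statistical structure the method relies
on, not the appearance of video:

* **Pulse**: harmonics at `f_hr = hr/60` with amplitude decay 1 : 0.5 : 0.2
  and random phases, standardized.
* **Respiration**: joint amplitude modulation (10%) and frequency
  modulation (3%) of the pulse at `f_rr = rr/60`, plus a low-frequency
  baseline at `f_rr` common to all rows — so RR is recoverable both from
  sidebands and from the baseline line.
* **SpO2**: the red/blue AC-to-DC ratios are set so the classical
  pulse-oximetry ratio-of-ratios satisfies `spo2 = 110 − 25·R`. This
  two-wavelength calibration is a generator-internal convention that makes
  SpO2 learnable from the maps; real RGB cameras do not follow it exactly.
* **Nuisance**: i.i.d. Gaussian noise (noise_sd, as a fraction of the green
  AC amplitude; 0.3 by default) and a sinusoidal illumination drift at
  0.05–0.15 Hz that deliberately overlaps the respiration band. Per-row
  phase delays up to 100 ms mimic pulse-transit spread across the face.

Vitals are drawn uniformly from hr 50–140 beats/min, rr 8–24 breaths/min,
spo2 85–100% — a resting adult population. A sample is fully determined by
(config, seed, draw index). An independent spectral oracle (Welch
periodogram, band-limited argmax; optional zero-padding for sub-bin
resolution) verifies on every clean sample that the label is encoded; the
generator refuses to emit a clean sample whose oracle HR is off by more
than 3 beats/min.

What passing the synthetic tests does **not** show: robustness to motion,
skin-tone optics, codec artifacts, or detector jitter — none of which are
modelled. The synthetic results demonstrate that the architecture and the
training loop can extract the encoded physiology, not that they match
published performance on real video corpora.

## Numerical and engineering choices

* No deep-learning framework is used: the network runs on a compact
  reverse-mode autodiff engine over NumPy (tape of closures, ~15 primitive
  ops, hand-written backward passes for conv2d, depthwise conv1d and the
  diagonal selective scan). Float64 by default; the training loop casts the
  model and batches to float32 for a ~2× speed-up. Everything is
  deterministic given the seeds (no threading, no atomics).
* ZOH quadrature, scan equivalence and the vectorized selective scan are
  validated against independent references: fine Riemann-sum integration,
  impulse-response identities, and naive per-step loops written separately
  from the production path.
* Batch norm requires batch ≥ 2 in training mode and uses running
  statistics in evaluation, so batch-1 inference is well defined.
  Degenerate STMap blocks (zero temporal range) become the neutral value
  0.5 with a warning rather than NaN.
* The attention softmax guards against non-finite logits and reports the
  failing stage/layer; training aborts on a non-finite loss, keeping the
  history collected so far.
* Checkpoints are a single `.npz` archive with a JSON manifest (config,
  parameter count, metric snapshot) — loadable without executing pickled
  code.

## Problem sizes used in the shipped verification runs

Scan equivalence uses 50 random strictly-stable systems with state width
≤ 8 and sequence length ≤ 64. The overfit sanity run memorizes one fixed
batch of 8 samples for 500 steps (θ fixed at 1 and learning rate 3e-3, the
appropriate setting for a capacity check). The recovery experiment trains
the tiny model on 200 moderate-noise samples for 500 steps and evaluates on
50 held out, repeated over 3 seeds in the test-suite; the layer sweep runs
N ∈ {1, 2} on a reduced budget to exercise the harness end to end without
asserting a depth trend (at that budget the models are far from converged).

## Known limitations

* Scalar heads read a pooled representation; very short windows (< 5 s)
  under-resolve the low respiratory frequencies.
* The spectral RR oracle is confounded by the illumination drift sharing
  its band — intentional, since separating them is precisely what the
  learned model is for.
* The BVP head is a linear readout of coarse (stride-32) tokens: it
  captures phase and rate, not fine waveform morphology (dicrotic notch).
* Python-loop selective scan in `ssm_core` is for verification at small
  sizes; the network path is vectorized but still CPU-bound NumPy, not a
  GPU kernel.
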
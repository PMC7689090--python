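# Methods

## Model

`glsnn` trains multi-layer feedforward spiking networks without
backpropagation, by combining three ingredients: a conductance-based
leaky integrate-and-fire (LIF) forward pass carrying a real-valued
*surrogate* signal, global targets delivered by fixed random feedback
from the output error, and a local differential-STDP weight update.

### Neuron dynamics

Each neuron integrates a membrane potential `V` and an excitatory
conductance `g_E` in discrete time (explicit Euler, step `dt`):

    V(t+1)   = V(t) − (dt/τ_m)·[(V − V_L) + (g_E/g_L)·(V − V_E)]
    g_E(t+1) = g_E(t) + (dt/τ_E)·(−g_E + Σ_j w_{j,i} S_j)
    δ(t+1)   = 1 and V := V_reset   if V(t+1) > V_th   (strict)
    S(t+1)   = Σ_j w_{j,i} S_j + τ_s·δ(t+1)

The canonical ordering within a step is: voltage update using the
*pre-update* conductance, then conductance relaxation toward the current
drive, then threshold/reset, then the surrogate output. The surrogate
`S` — the weighted input plus a small spike bonus `τ_s` — is the signal
passed between layers and used by learning; it is residual-style in that
the raw drive passes through unchanged when the neuron is silent.

Two closed forms anchor the implementation and are verified continuously
in the tests:

- the conductance recursion is linear, so `g*(drive) = drive` and
  `|g_E(t) − drive|` decays geometrically with factor `1 − dt/τ_E`,
  exactly;
- under constant drive with an unreachable threshold the voltage settles
  at `V* = (g_L·V_L + g*·V_E)/(g_L + g*)`; with the default constants and
  drive 20 this is exactly 0.1.

Default constants: `V_E = 0.2`, `V_L = 0`, `V_th = 0.0009`,
`V_reset = 0`, `τ_m = 0.5`, `τ_E = 0.2`, `τ_s = 0.01`, `g_L = 20`,
`dt = 0.01`, `T = 0.1` (so 10 simulation steps). The tiny threshold
relative to the drive scale means active neurons typically begin to
spike within a few steps of the window. There is no inhibitory channel,
no refractory period and no adaptive threshold; the model is simulated
in double precision because `V_th` is small enough that single-precision
accumulation error would be comparable to it.

### Forward simulation

Inputs are vectors in [0, 1] (e.g. flattened grayscale images scaled by
1/255, or the synthetic clusters below) clamped as layer 0's surrogate
output at every step — a constant-current-style encoding, not Poisson
spike coding, since `S` is real-valued by construction. Within each
global step the layers advance once in ascending order, each consuming
the upstream surrogate just computed in that step. Learning uses the
surrogates of the final step only. A network with more weight layers
than simulation steps is rejected (with `T/dt = 10`, at most 9 weight
matrices), so that every layer's conductance sees several steps of
input-driven activity inside the window.

### Global feedback targets

For a batch with one-hot targets `S^T` (amplitude 1.0 by default), the
loss is the summed squared distance `Σ‖S_out − S^T‖²`, and the per-sample
signed error is its gradient `e = 2(S_out − S^T)`. Targets are:

- output layer: `S^T` itself (the top weight matrix trains toward it);
- penultimate layer: `Ŝ = S − η_t · e·Wᵀ`, the error pulled back through
  the transpose of the last forward weights (`η_t = 0.5` by default);
- every deeper hidden layer `l`: `Ŝ_l = S_l − (B_l·e + b_l)` with a
  *fixed random* matrix `B_l` and bias `b_l`, drawn once and never
  trained. The error reaches each hidden layer directly — no
  layer-by-layer chaining — and the backward path needs no copy of the
  forward weights (no weight transport).

`e` is kept per-sample when forming targets, so `Ŝ` always has the same
shape as `S`; batch aggregation happens only in the weight update.

### Local plasticity

For the weights between layers `l` and `l+1`:

    ΔW = S_lᵀ·(S_{l+1} − Ŝ_{l+1}) / M        (mean over the M samples)
    W  = W − η_w·ΔW                           (η_w = 0.015)

All matrices update simultaneously from one frozen forward trace per
minibatch; there is no re-simulation between layer updates, no momentum,
no weight decay, clipping or normalisation. The mean batch reduction
makes `η_w` invariant to batch size (a `sum` reduction is available).

## Parameter choices made here

Two defaults in the feedback pathway were genuinely open and are this
package's own choices:

- **Feedback scale.** By default `B_l` entries are zero-mean Gaussian
  with standard deviation `η_t/√(width_l)`. This makes the per-neuron
  hidden target shift `B_l·e` the same magnitude as the penultimate
  layer's analytic pullback `η_t·e·Wᵀ` under (semi-)orthogonal forward
  weights, at any depth and output width. Larger scales (for example a
  standard deviation of `1/√n_out`, which is ≈ 0.58 with 3 output
  classes) produce target shifts several times the surrogate scale; the
  misaligned components of the random-feedback learning loop then grow
  faster than forward–feedback alignment can catch up, and deep networks
  diverge. An explicit `scale` argument overrides the default with
  `std = scale/√n_out`.
- **Feedback bias.** `b_l` defaults to zero. A nonzero fixed bias shifts
  every hidden target even when the output error is exactly zero, which
  breaks the zero-error fixed point (a perfectly predicting network
  should stop moving) and injects a permanent, error-independent drift
  into the weights. The bias term is implemented and serialised, and a
  nonzero `bias_scale` can be requested, but the coherent default is 0.
- **One-hot amplitude** defaults to 1.0; with output surrogates of order
  1 under the default initialisation, this keeps initial errors O(1).

Weight initialisation is (semi-)orthogonal by default (QR of a Gaussian
with sign fix; orthogonality holds on the smaller dimension), following
difference-target-propagation practice; a fan-scaled uniform scheme
(bound `√(6/(fan_in+fan_out))`) is available.

## Ablation semantics

`n_feedback_layers = k` grants random-feedback targets to the deepest
`k` hidden layers among those eligible for them (layers 1 … L−3),
proceeding deep to shallow. The penultimate layer's transpose-pullback
target needs no feedback connection and is always computed, so at
`k = 0` the top two weight matrices still learn while all shallower
matrices stay bit-identical to their initial values (their post-synaptic
layers have no target, hence zero update by construction). Full feedback
is reached at `k = L−3`; the value `L−2` is accepted as a synonym for
"all hidden layers targeted".

## Synthetic data

`make_blobs` emulates what the learner needs from MNIST-like data —
bounded inputs in [0, 1] with class-conditional cluster structure — not
images. Class centers are drawn on a sphere of radius
`separation·noise_sd` around the cube center, redrawn until all pairwise
distances reach `separation·noise_sd`; samples are center + isotropic
Gaussian noise (`noise_sd` per coordinate), mapped by the fixed
affine-clip map `x ↦ clip(x + ½, 0, 1)`; the train/test split is 2:1.
The standard task used throughout the tests is 3 classes in 20
dimensions, 600 training / 300 test samples, separation 6, noise 0.05 —
"6" meaning the between-class signal is about six noise standard
deviations along the discriminant direction, so a nearest-centroid
oracle scores ≥ 99% and any residual learner failure is attributable to
the learner.

What passing on this generator does *not* show: robustness to the heavy
class overlap, manifold structure, and label noise of real image data.
The synthetic task is near-linearly separable; it validates the learning
machinery (credit assignment, stability, determinism), not
state-of-the-art accuracy. Image-scale behaviour can be checked by
pointing the CLI at IDX files of MNIST or Fashion-MNIST.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use: 100 epochs with a
[20-64-64-3] network for the learning check (three seeds); 50 epochs
with a [20-32-32-32-32-3] network, feedback counts 0–3 and five seeds
for the ablation staircase; 50 random networks of up to 4 layers and 8
neurons per layer for the scalar-loop oracle comparison; 20 000 steps
for the voltage fixed point. These sizes were chosen so the full
pipeline (forward dynamics, feedback targets, plasticity, evaluation) is
exercised end to end in a few minutes on one CPU core.

## Numerical and degenerate-input choices

- Threshold comparison is strict (`V > V_th`); ties at exactly `V_th`
  do not spike.
- Prediction is the argmax of the final output surrogates; ties break
  to the lowest class index.
- State (V, g_E, spikes, surrogates) is fully reset between batches and
  between samples; batch elements never interact.
- Training aborts with a diagnostic naming the epoch and batch if the
  loss or any drive becomes non-finite (e.g. at absurd learning rates).
- Determinism: the weight draw, feedback draw, and each epoch's shuffle
  use generators seeded from `(seed, stream)` tuples; two runs with the
  same config and seed agree bit-for-bit in weights and history.
- An empty feedback set is valid for networks with ≤ 3 layers (the
  penultimate/output targets cover all weights).

## Known limitations

- No inhibitory conductance, refractory period, or adaptive threshold.
- Fully connected layers only; no convolutional or recurrent structure.
- The surrogate pathway is linear in the inputs up to the small spike
  bonus, so depth adds little representational nonlinearity on tasks
  like the synthetic clusters; the value of depth shows on data with
  richer structure.
- Feedback matrices are frozen; no inverse/decoder training.
- CPU, dense numpy only; the per-step per-layer loop is vectorised over
  the batch but not parallelised across layers.
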
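# glsnn

Multi-layer spiking neural networks trained **without backpropagation**:
a discrete-time conductance-based leaky integrate-and-fire (LIF) forward
pass, per-layer activity targets delivered by *fixed random feedback*
projections of the output error, and weight changes by a *local
differential-STDP* rule. The package is for researchers in
computational neuroscience and brain-inspired learning who want a small,
fully deterministic, CPU-only testbed for global-feedback / local-plasticity
credit assignment on image-vector classification data.

## The model

Each neuron integrates a membrane potential and an excitatory
conductance in discrete time and carries a residual-style *surrogate
output* between layers:

    V(t+1)   = V(t) − (dt/τ_m)·[(V − V_L) + (g_E/g_L)·(V − V_E)]
    g_E(t+1) = g_E(t) + (dt/τ_E)·(−g_E + Σ_j w_{j,i} S_j)
    δ(t+1)   = 1, V := V_reset        if V(t+1) > V_th
    S(t+1)   = Σ_j w_{j,i} S_j + τ_s·δ(t+1)

After `T/dt` simulation steps the final-step surrogates feed learning.
With one-hot targets `S^T`, the loss is `Σ‖S_out − S^T‖²` with signed
error `e = 2(S_out − S^T)`; the penultimate layer's target is the
transpose pullback `Ŝ = S − η_t·e·Wᵀ`, and every deeper hidden layer
gets its target *directly* from the output error through a fixed random
matrix, `Ŝ_l = S_l − (B_l·e + b_l)` — no weight transport, no
layer-by-layer error chaining. Weights update locally:

    ΔW = S_preᵀ·(S_post − Ŝ_post)/M,      W ← W − η_w·ΔW

Defaults follow the standard operating point (`η_t = 0.5`,
`η_w = 0.015`, batch size 10, `V_E = 0.2`, `V_th = 0.0009`, `τ_m = 0.5`,
`τ_E = 0.2`, `τ_s = 0.01`, `g_L = 20`, `dt = 0.01`, `T = 0.1`).
See `docs/methods.md` for assumptions, parameter rationale, and
limitations.

## Worked example

```python
from glsnn import GLSNN, make_blobs

# 3 Gaussian classes in 20 dimensions, 600 train / 300 test,
# six noise standard deviations between class centers
train, test = make_blobs(n_per_class=200, dim=20, n_classes=3,
                         separation=6.0, noise_sd=0.05, seed=0)

model = GLSNN(train, test, layer_sizes=(20, 64, 64, 3), seed=0)
res = model.fit(epochs=100)
print(res.summary())
```

```
GLSNN Results
==========================================================
Architecture:               [20-64-64-3]
Trainable weights:          5568
Epochs:                     100
Batch size:                 10
Target learning rate:       0.5
Weight learning rate:       0.015
Feedback layers:            all
Weight init:                orthogonal
Seed:                       0
Simulation steps (T/dt):    10
----------------------------------------------------------
Final train accuracy (%):   100.00
Final test accuracy (%):    100.00
Final training loss:        0.05357
==========================================================
```

`res.history` holds the per-epoch table; on this task the network
starts near chance and is essentially converged within ten epochs:

```
 epoch  train_acc   test_acc     loss
     1  45.666667  48.666667 0.716995
    10 100.000000  99.666667 0.198133
   100 100.000000 100.000000 0.053570
```

Accuracy is the percentage of samples whose maximal output surrogate at
simulation end matches the label; the loss is the mean per-sample
squared distance between output surrogates and their one-hot targets.
`res.predict(X)`, `res.plot_history()`, `res.plot_raster(X)` (spike
rasters), `res.layer_activations(X)` (for embedding/visualisation
exports) and `res.save("model.npz")` hang off the results object.

The ablation knob `n_feedback_layers` grants random-feedback targets to
the deepest *k* hidden layers only; layers without targets keep their
incoming weights bit-frozen, so `k = 0` trains just the top two weight
matrices:

```python
from glsnn import TrainConfig, run_ablation
cfg = TrainConfig(layer_sizes=(20, 32, 32, 32, 32, 3), epochs=50, seed=0)
results = run_ablation(cfg, [0, 1, 2, 3], train, test)
```

## Command line

Every library entry point has a CLI twin working on IDX files (the
MNIST container format); `make-synthetic` writes Gaussian-blob datasets
in the same layout:

```bash
glsnn make-synthetic --out-dir data --n-per-class 200 --dim 20 --n-classes 3
glsnn train --layer-sizes 20,64,64,3 --epochs 100 --seed 0 \
      --train-images data/train-images.idx --train-labels data/train-labels.idx \
      --test-images  data/test-images.idx  --test-labels  data/test-labels.idx \
      --out model.npz
glsnn eval --model model.npz --images data/test-images.idx --labels data/test-labels.idx
glsnn ablate --layer-sizes 20,32,32,32,32,3 --feedback-counts 0,1,2,3 ... 
glsnn sweep  --layer-sizes 20,64,3 --depths 1,2,3,4,5 --hidden-width 64 ...
```

A config file (INI with `[neuron]`, `[network]`, `[train]` sections) can
preload any option via `--config run.ini`; explicit flags override it.
To train on real MNIST or Fashion-MNIST, download the four IDX files
and pass them to `glsnn train` (e.g. `--layer-sizes 784,800,800,800,10
--epochs 100`); nothing in the package downloads data itself.

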
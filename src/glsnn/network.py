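"""Multi-layer feedforward simulation of LIF layers.

A network is the list of layer widths plus one weight matrix per
consecutive layer pair.  ``simulate_forward`` clamps the input vector as
layer 0's surrogate output, then advances every LIF layer once per
global step in ascending order (each layer consumes the upstream
surrogate just computed within the same step), for T/dt steps.  Learning
consumes the surrogates of the final step only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .lif import LayerState, NeuronParams, init_layer_state, lif_step

__all__ = ["Network", "ForwardTrace", "init_network", "simulate_forward", "export_rasters"]


@dataclass
class Network:
    """Layer widths and forward weights.

    ``weights[l]`` has shape ``(layer_sizes[l], layer_sizes[l+1])`` and
    maps layer ``l`` surrogate outputs to layer ``l+1`` drives.  No bias
    terms on the forward path.
    """

    layer_sizes: list[int]
    weights: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.layer_sizes) - 1:
            raise ValueError(
                f"{len(self.layer_sizes)} layers need {len(self.layer_sizes) - 1} "
                f"weight matrices, got {len(self.weights)}"
            )
        for l, W in enumerate(self.weights):
            want = (self.layer_sizes[l], self.layer_sizes[l + 1])
            if W.shape != want:
                raise ValueError(f"weights[{l}] has shape {W.shape}, expected {want}")
            if not np.all(np.isfinite(W)):
                raise ValueError(f"weights[{l}] contains non-finite entries")

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes)

    def copy(self) -> "Network":
        return Network(list(self.layer_sizes), [W.copy() for W in self.weights])


@dataclass
class ForwardTrace:
    """What the forward pass leaves behind for learning and inspection.

    ``S_layers[l]`` is layer ``l``'s surrogate output at the final
    simulation step, shape ``(batch, layer_sizes[l])``; ``S_layers[0]``
    is the clamped input.  ``spikes`` (when recorded) holds one binary
    array of shape ``(n_steps, batch, width)`` per layer beyond the
    input; ``spike_counts`` the per-neuron, per-sample totals.
    """

    S_layers: list[np.ndarray]
    spikes: list[np.ndarray] | None = None
    spike_counts: list[np.ndarray] | None = None


def init_network(
    layer_sizes: list[int], seed: int, scheme: str = "orthogonal"
) -> Network:
    """Draw reproducible forward weights.

    ``orthogonal`` (the default, following difference-target-propagation
    practice): each matrix is (semi-)orthogonal — W^T W = I when the
    input side is the smaller dimension, W W^T = I otherwise.
    ``scaled_uniform``: zero-mean uniform on ±sqrt(6/(fan_in+fan_out)).
    """
    layer_sizes = [int(n) for n in layer_sizes]
    if len(layer_sizes) < 2:
        raise ValueError("a network needs at least 2 layers")
    if any(n < 1 for n in layer_sizes):
        raise ValueError(f"all layer sizes must be >= 1, got {layer_sizes}")
    if scheme not in ("orthogonal", "scaled_uniform"):
        raise ValueError(f"unknown init scheme {scheme!r}")

    rng = np.random.default_rng(seed)
    weights = []
    for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        if scheme == "orthogonal":
            W = _orthogonal(n_in, n_out, rng)
        else:
            bound = np.sqrt(6.0 / (n_in + n_out))
            W = rng.uniform(-bound, bound, size=(n_in, n_out))
        weights.append(W)
    return Network(layer_sizes, weights)


def _orthogonal(n_in: int, n_out: int, rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian with sign fix gives a Haar-distributed orthogonal factor
    big, small = max(n_in, n_out), min(n_in, n_out)
    A = rng.standard_normal((big, small))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    return Q if n_in >= n_out else Q.T


def simulate_forward(
    net: Network,
    X: np.ndarray,
    params: NeuronParams,
    record_spikes: bool = False,
) -> ForwardTrace:
    """Run a batch of input vectors through the network for T/dt steps.

    ``X`` has shape ``(batch, layer_sizes[0])`` with entries in [0, 1];
    each row is held constant as layer 0's surrogate output at every
    step (constant-current-style encoding).  Samples never interact:
    each row evolves independently.

    Raises
    ------
    ValueError
        On input-width mismatch, or when the network has more weight
        layers than simulation steps (the per-step pipeline cannot feed
        the deepest layers within the window).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != net.layer_sizes[0]:
        raise ValueError(
            f"input width {X.shape[1]} does not match layer 0 size {net.layer_sizes[0]}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains non-finite entries")
    n_steps = params.n_steps
    n_weight_layers = len(net.weights)
    if n_weight_layers > n_steps:
        raise ValueError(
            f"{n_weight_layers} weight layers exceed the {n_steps} simulation "
            f"steps available under T={params.T}, dt={params.dt}; "
            "increase T or use a shallower network"
        )

    batch = X.shape[0]
    states: list[LayerState] = [
        init_layer_state((batch, n), params) for n in net.layer_sizes[1:]
    ]
    spikes = (
        [np.zeros((n_steps, batch, n)) for n in net.layer_sizes[1:]]
        if record_spikes
        else None
    )

    for t in range(n_steps):
        S_prev = X
        for l, W in enumerate(net.weights):
            drive = S_prev @ W
            states[l] = lif_step(states[l], drive, params)
            if spikes is not None:
                spikes[l][t] = states[l].delta
            S_prev = states[l].S

    S_layers = [X] + [st.S for st in states]
    counts = [sp.sum(axis=0) for sp in spikes] if spikes is not None else None
    return ForwardTrace(S_layers=S_layers, spikes=spikes, spike_counts=counts)


def export_rasters(trace: ForwardTrace, out_dir: str | Path, prefix: str = "raster") -> list[Path]:
    """Write recorded spike trains as delimited text rasters.

    One file per (sample, layer): a binary matrix of shape
    (time steps x neurons), tab-separated, named
    ``{prefix}_sample{i}_layer{l}.tsv`` (layer numbering starts at 1,
    the first spiking layer).  Returns the written paths.
    """
    if trace.spikes is None:
        raise ValueError("trace was recorded without spikes; rerun with record_spikes=True")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for l, sp in enumerate(trace.spikes, start=1):
        for i in range(sp.shape[1]):
            path = out_dir / f"{prefix}_sample{i}_layer{l}.tsv"
            np.savetxt(path, sp[:, i, :], fmt="%d", delimiter="\t")
            written.append(path)
    return written
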
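"""Global feedback: output error and per-layer activity targets.

The output layer's target is the one-hot label vector.  The penultimate
layer's target is reached by projecting the signed output error back
through the transpose of the last forward weight matrix, scaled by the
target learning rate eta_t.  Every other hidden layer receives its
target *directly* from the output error through a fixed random matrix —
no layer-by-layer chaining, and the feedback weights are never trained.
This sidesteps the weight-transport problem: the backward path needs no
copy of the forward weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ForwardTrace, Network

__all__ = [
    "FeedbackParams",
    "TargetSet",
    "l2_loss",
    "prediction_error",
    "penultimate_target",
    "hidden_target",
    "init_feedback",
    "compute_all_targets",
]


@dataclass
class FeedbackParams:
    """Fixed random direct-feedback projections.

    ``B[l]`` (shape ``(width_l, n_out)``) and ``b[l]`` (shape
    ``(width_l,)``) exist for each hidden layer ``l`` in 1 … L−3 and map
    output-error vectors to layer-l target shifts.  Frozen after
    initialization.  ``eta_t`` scales only the penultimate-layer
    projection.
    """

    B: dict[int, np.ndarray] = field(default_factory=dict)
    b: dict[int, np.ndarray] = field(default_factory=dict)
    eta_t: float = 0.5

    def __post_init__(self) -> None:
        if set(self.B) != set(self.b):
            raise ValueError("B and b must cover the same layers")
        for l, B_l in self.B.items():
            if self.b[l].shape != (B_l.shape[0],):
                raise ValueError(
                    f"b[{l}] shape {self.b[l].shape} does not match B[{l}] {B_l.shape}"
                )


@dataclass
class TargetSet:
    """Per-layer activity targets for one batch.

    ``S_hat[l]`` is the target for hidden layer ``l`` (same shape as the
    forward surrogate); only layers granted feedback appear.  ``S_T`` is
    the output-layer one-hot target batch.
    """

    S_hat: dict[int, np.ndarray]
    S_T: np.ndarray


def l2_loss(S_out: np.ndarray, S_T: np.ndarray) -> float:
    """Sum over samples of the squared Euclidean distance ||S_out − S^T||²."""
    S_out = np.atleast_2d(np.asarray(S_out, dtype=np.float64))
    S_T = np.atleast_2d(np.asarray(S_T, dtype=np.float64))
    if S_out.shape != S_T.shape:
        raise ValueError(f"shape mismatch: {S_out.shape} vs {S_T.shape}")
    return float(np.sum((S_out - S_T) ** 2))


def prediction_error(S_out: np.ndarray, S_T: np.ndarray) -> np.ndarray:
    """Signed per-sample error e = 2·(S_out − S^T), the gradient of the
    squared-distance loss with respect to the output surrogate."""
    S_out = np.atleast_2d(np.asarray(S_out, dtype=np.float64))
    S_T = np.atleast_2d(np.asarray(S_T, dtype=np.float64))
    if S_out.shape != S_T.shape:
        raise ValueError(f"shape mismatch: {S_out.shape} vs {S_T.shape}")
    return 2.0 * (S_out - S_T)


def penultimate_target(
    S_pen: np.ndarray, W_out: np.ndarray, e: np.ndarray, eta_t: float
) -> np.ndarray:
    """Ŝ_pen = S_pen − eta_t · e · W_outᵀ (error pulled back through the
    transpose of the last forward weights)."""
    S_pen = np.atleast_2d(np.asarray(S_pen, dtype=np.float64))
    e = np.atleast_2d(np.asarray(e, dtype=np.float64))
    if e.shape[1] != W_out.shape[1] or S_pen.shape[1] != W_out.shape[0]:
        raise ValueError(
            f"shapes inconsistent: S_pen {S_pen.shape}, W_out {W_out.shape}, e {e.shape}"
        )
    return S_pen - eta_t * (e @ W_out.T)


def hidden_target(
    S_l: np.ndarray, B_l: np.ndarray, b_l: np.ndarray, e: np.ndarray
) -> np.ndarray:
    """Ŝ_l = S_l − (B_l·e + b_l): direct random projection of the output error."""
    S_l = np.atleast_2d(np.asarray(S_l, dtype=np.float64))
    e = np.atleast_2d(np.asarray(e, dtype=np.float64))
    if B_l.shape != (S_l.shape[1], e.shape[1]):
        raise ValueError(
            f"B shape {B_l.shape} inconsistent with S_l {S_l.shape} and e {e.shape}"
        )
    return S_l - (e @ B_l.T + b_l)


def init_feedback(
    layer_sizes: list[int],
    seed: int,
    scale: float | None = None,
    bias_scale: float = 0.0,
    eta_t: float = 0.5,
) -> FeedbackParams:
    """Draw the fixed feedback projections, one per hidden layer 1 … L−3.

    ``B[l]`` entries are zero-mean Gaussian.  When ``scale`` is given,
    their standard deviation is ``scale / sqrt(n_out)``.  By default
    (``scale=None``) the standard deviation is ``eta_t / sqrt(width_l)``,
    which makes the per-neuron target shift ``B_l·e`` the same magnitude
    as the penultimate layer's transpose pullback ``eta_t·e·Wᵀ`` under
    (semi-)orthogonal forward weights — target shifts stay commensurate
    with surrogate magnitudes at any depth, which keeps the
    feedback-alignment loop stable.  ``b[l]`` entries are zero-mean
    Gaussian with standard deviation ``bias_scale``.  Networks with
    fewer than 3 layers get an empty (valid) feedback set.
    """
    L = len(layer_sizes)
    n_out = layer_sizes[-1]
    rng = np.random.default_rng(seed)
    B: dict[int, np.ndarray] = {}
    b: dict[int, np.ndarray] = {}
    for l in range(1, L - 2):
        if scale is None:
            std = eta_t / np.sqrt(layer_sizes[l])
        else:
            std = scale / np.sqrt(n_out)
        B[l] = rng.standard_normal((layer_sizes[l], n_out)) * std
        b[l] = rng.standard_normal(layer_sizes[l]) * bias_scale
    return FeedbackParams(B=B, b=b, eta_t=eta_t)


def compute_all_targets(
    trace: ForwardTrace,
    net: Network,
    fb: FeedbackParams,
    labels: np.ndarray,
    amplitude: float = 1.0,
    n_feedback_layers: int | None = None,
) -> TargetSet:
    """Build every layer target for one batch.

    One-hot encodes ``labels`` into the output target S^T, forms the
    signed error, applies the transpose pullback to the penultimate
    layer and the fixed random projections to deeper hidden layers.
    Layer 0 (the input) never receives a target.

    ``n_feedback_layers`` restricts the random-feedback targets to the
    *deepest* that many hidden layers (the ablation knob); ``None``
    means all.  The penultimate layer's target needs no feedback
    connection and is always computed.
    """
    from .data import one_hot  # local import to avoid a cycle

    L = net.n_layers
    n_out = net.layer_sizes[-1]
    S_T = one_hot(labels, n_out, amplitude=amplitude)
    S_out = trace.S_layers[-1]
    if S_T.shape != S_out.shape:
        raise ValueError(
            f"labels produce target shape {S_T.shape}, output is {S_out.shape}"
        )
    e = prediction_error(S_out, S_T)

    S_hat: dict[int, np.ndarray] = {}
    if L >= 3:
        pen = L - 2
        S_hat[pen] = penultimate_target(
            trace.S_layers[pen], net.weights[pen], e, fb.eta_t
        )

    fb_layers = sorted(fb.B)  # 1 … L-3
    if n_feedback_layers is not None:
        if n_feedback_layers < 0 or n_feedback_layers > L - 2:
            raise ValueError(
                f"n_feedback_layers must be in [0, {L - 2}], got {n_feedback_layers}"
            )
        fb_layers = fb_layers[len(fb_layers) - min(n_feedback_layers, len(fb_layers)):]
    for l in fb_layers:
        S_hat[l] = hidden_target(trace.S_layers[l], fb.B[l], fb.b[l], e)

    return TargetSet(S_hat=S_hat, S_T=S_T)
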
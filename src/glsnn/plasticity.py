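"""Local differential-STDP weight updates.

The plasticity rule is local: the update for the weights into layer
``l+1`` needs only the pre-synaptic surrogate S_l, the post-synaptic
forward surrogate S_{l+1}, and that layer's target Ŝ_{l+1}:

    ΔW ∝ S_preᵀ (S_post − Ŝ_post)        (outer product per sample)
    W' = W − eta_w · ΔW

All layers update simultaneously from one frozen forward trace per
batch; there is no re-simulation between layer updates, no momentum,
no clipping, decay or normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .feedback import TargetSet
from .network import ForwardTrace, Network

__all__ = ["UpdateConfig", "stdp_delta", "apply_update", "update_all_layers"]


@dataclass(frozen=True)
class UpdateConfig:
    """eta_w: weight learning rate; batch_reduction: 'mean' (default,
    batch-size invariant) or 'sum' over samples."""

    eta_w: float = 0.015
    batch_reduction: str = "mean"

    def __post_init__(self) -> None:
        if self.eta_w < 0:
            raise ValueError(f"eta_w must be >= 0, got {self.eta_w}")
        if self.batch_reduction not in ("mean", "sum"):
            raise ValueError(f"batch_reduction must be 'mean' or 'sum', got {self.batch_reduction!r}")


def stdp_delta(
    S_pre: np.ndarray,
    S_post: np.ndarray,
    S_post_hat: np.ndarray,
    reduction: str = "mean",
) -> np.ndarray:
    """Per-sample outer product of pre-activity with the forward/target
    difference, combined over the batch; shape (n_pre, n_post) to match W."""
    S_pre = np.atleast_2d(np.asarray(S_pre, dtype=np.float64))
    S_post = np.atleast_2d(np.asarray(S_post, dtype=np.float64))
    S_post_hat = np.atleast_2d(np.asarray(S_post_hat, dtype=np.float64))
    if S_post.shape != S_post_hat.shape:
        raise ValueError(f"shape mismatch: S_post {S_post.shape} vs target {S_post_hat.shape}")
    if S_pre.shape[0] != S_post.shape[0]:
        raise ValueError(
            f"batch mismatch: {S_pre.shape[0]} pre vs {S_post.shape[0]} post samples"
        )
    dW = S_pre.T @ (S_post - S_post_hat)
    if reduction == "mean":
        dW /= S_pre.shape[0]
    elif reduction != "sum":
        raise ValueError(f"unknown reduction {reduction!r}")
    return dW


def apply_update(W: np.ndarray, dW: np.ndarray, eta_w: float) -> np.ndarray:
    """Plain gradient step W' = W − eta_w·dW; the input W is left untouched."""
    if W.shape != dW.shape:
        raise ValueError(f"shape mismatch: W {W.shape} vs dW {dW.shape}")
    return W - eta_w * dW


def update_all_layers(
    net: Network,
    trace: ForwardTrace,
    targets: TargetSet,
    cfg: UpdateConfig = UpdateConfig(),
) -> Network:
    """One plasticity step over the whole network.

    Every weight matrix whose post-synaptic layer has a target is
    updated from the same pre-update trace; the top matrix uses the
    one-hot output target.  Matrices into layers without targets are
    returned untouched (bit-identical) — this is how ablation freezes
    shallow layers.  Returns a new Network.
    """
    L = net.n_layers
    if len(trace.S_layers) != L:
        raise ValueError(
            f"trace has {len(trace.S_layers)} layers, network has {L}"
        )
    new_weights = []
    for l, W in enumerate(net.weights):
        post = l + 1
        if post == L - 1:
            target = targets.S_T
        elif post in targets.S_hat:
            target = targets.S_hat[post]
        else:
            new_weights.append(W)
            continue
        dW = stdp_delta(
            trace.S_layers[l], trace.S_layers[post], target, cfg.batch_reduction
        )
        new_weights.append(apply_update(W, dW, cfg.eta_w))
    return Network(list(net.layer_sizes), new_weights)
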
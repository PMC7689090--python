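"""Functional training front end: train / evaluate / ablate / sweep.

Thin wrappers over :class:`~glsnn.model.GLSNN`; useful when a run is
specified by a :class:`~glsnn.model.TrainConfig` rather than built
interactively.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import Dataset
from .model import GLSNN, GLSNNResults, TrainConfig, evaluate

__all__ = ["TrainConfig", "train", "evaluate", "run_ablation", "depth_sweep"]


def train(
    cfg: TrainConfig,
    train_set: Dataset,
    test_set: Dataset | None = None,
    verbose: bool = False,
) -> GLSNNResults:
    """Run one full training job described by ``cfg``."""
    model = GLSNN(train_set, test_set, layer_sizes=cfg.layer_sizes,
                  **{k: v for k, v in vars(cfg).items() if k != "layer_sizes"})
    return model.fit(verbose=verbose)


def run_ablation(
    base_cfg: TrainConfig,
    feedback_counts: list[int],
    train_set: Dataset,
    test_set: Dataset | None = None,
    verbose: bool = False,
) -> list[GLSNNResults]:
    """Train one network per feedback count, sharing seed and data order.

    Each count says how many hidden layers (deepest first) receive
    random direct-feedback targets; hidden layers without targets keep
    their incoming weights frozen at their initial values.
    """
    L = len(base_cfg.layer_sizes)
    for c in feedback_counts:
        if not (0 <= c <= L - 2):
            raise ValueError(f"feedback count {c} invalid for {L}-layer network")
    return [
        train(base_cfg.replace(n_feedback_layers=c), train_set, test_set, verbose)
        for c in feedback_counts
    ]


def depth_sweep(
    base_cfg: TrainConfig,
    hidden_layer_counts: list[int],
    hidden_width: int,
    train_set: Dataset,
    test_set: Dataset | None = None,
    verbose: bool = False,
) -> pd.DataFrame:
    """Train networks of increasing depth at a fixed hidden width.

    Returns a table with one row per depth: depth, architecture, final
    train/test accuracy and final loss.  Depths whose layer count
    exceeds the simulation-step budget are rejected up front.
    """
    n_in = base_cfg.layer_sizes[0]
    n_out = base_cfg.layer_sizes[-1]
    n_steps = base_cfg.neuron.n_steps
    rows = []
    for depth in hidden_layer_counts:
        if depth < 1:
            raise ValueError(f"depth must be >= 1, got {depth}")
        sizes = (n_in, *([hidden_width] * depth), n_out)
        if len(sizes) - 1 > n_steps:
            raise ValueError(
                f"depth {depth} needs {len(sizes) - 1} weight layers but only "
                f"{n_steps} simulation steps are available (T/dt)"
            )
        res = train(base_cfg.replace(layer_sizes=sizes), train_set, test_set, verbose)
        rows.append(
            {
                "hidden_layers": depth,
                "architecture": "-".join(map(str, sizes)),
                "train_acc": res.final_train_accuracy,
                "test_acc": res.final_test_accuracy,
                "loss": float(res.history["loss"].iloc[-1]),
            }
        )
    return pd.DataFrame(rows)
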
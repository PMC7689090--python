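"""The GLSNN model object and its fitted results.

``GLSNN`` is built from data (a training :class:`~glsnn.data.Dataset`,
optionally a test set) plus architecture and learning hyperparameters;
``fit()`` runs the full training loop — forward LIF simulation, global
feedback targets, local differential-STDP updates — and returns a
:class:`GLSNNResults` carrying the trained weights, the per-epoch
accuracy/loss history, and diagnostics.

The training loop per minibatch:

1. simulate the batch forward for T/dt steps and keep the final
   surrogates (the frozen forward trace);
2. one-hot the labels, form the signed output error, and project it into
   per-layer activity targets (transpose pullback for the penultimate
   layer, fixed random direct feedback for deeper hidden layers);
3. update all weight matrices simultaneously from the frozen trace by
   the local outer-product rule, plain SGD, no momentum or decay.

Everything is deterministic given the seed: weight and feedback draws,
and the per-epoch shuffle, all derive from it.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import Dataset
from .feedback import FeedbackParams, compute_all_targets, init_feedback, l2_loss
from .lif import NeuronParams
from .network import Network, init_network, simulate_forward
from .plasticity import UpdateConfig, update_all_layers

__all__ = ["TrainConfig", "GLSNN", "GLSNNResults", "evaluate"]


@dataclass(frozen=True)
class TrainConfig:
    """Everything that determines a training run.

    ``n_feedback_layers`` is the ablation knob: how many hidden layers,
    counted from the deepest eligible one, receive random direct-feedback
    targets.  ``None`` means all of them.  Hidden layers without a
    target keep their incoming weights frozen; the penultimate layer's
    transpose-pullback target is always available, so even at 0 the top
    two weight matrices still learn.
    """

    layer_sizes: tuple[int, ...]
    epochs: int = 100
    batch_size: int = 10
    eta_t: float = 0.5
    eta_w: float = 0.015
    seed: int = 0
    n_feedback_layers: int | None = None
    init_scheme: str = "orthogonal"
    neuron: NeuronParams = field(default_factory=NeuronParams)
    batch_reduction: str = "mean"
    feedback_scale: float | None = None
    bias_scale: float = 0.0
    target_amplitude: float = 1.0
    record_spikes: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "layer_sizes", tuple(int(n) for n in self.layer_sizes))
        L = len(self.layer_sizes)
        if L < 2:
            raise ValueError("layer_sizes needs at least input and output layers")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.n_feedback_layers is not None and not (
            0 <= self.n_feedback_layers <= L - 2
        ):
            raise ValueError(
                f"n_feedback_layers must be in [0, {L - 2}], got {self.n_feedback_layers}"
            )

    def replace(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


def evaluate(net: Network, params: NeuronParams, X: np.ndarray, y: np.ndarray) -> float:
    """Classification accuracy (%) by output-surrogate argmax.

    The predicted class is the index of the maximal output-layer
    surrogate at simulation end; ties break to the lowest index.
    """
    X = np.atleast_2d(np.asarray(X))
    y = np.asarray(y).ravel()
    if len(X) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    if len(X) != len(y):
        raise ValueError(f"{len(X)} samples but {len(y)} labels")
    trace = simulate_forward(net, X, params)
    pred = np.argmax(trace.S_layers[-1], axis=1)
    return 100.0 * float(np.mean(pred == y))


class GLSNN:
    """A multi-layer spiking network classifier built from data.

    Parameters
    ----------
    train_data : Dataset
        Training samples in [0, 1] with integer labels.
    test_data : Dataset, optional
        Held-out set evaluated after every epoch.
    layer_sizes : sequence of int, optional
        Full architecture [n_in, hidden..., n_classes].  If omitted,
        built as [n_in, *hidden, n_classes] from ``hidden``.
    hidden : sequence of int
        Hidden-layer widths used when ``layer_sizes`` is omitted.
    **config
        Any :class:`TrainConfig` field (epochs, batch_size, eta_t,
        eta_w, seed, n_feedback_layers, init_scheme, neuron, ...).

    Examples
    --------
    >>> train, test = make_blobs(seed=0)
    >>> model = GLSNN(train, test, hidden=(64, 64), seed=0)
    >>> res = model.fit(epochs=100)
    >>> res.test_accuracy[-1]
    """

    def __init__(
        self,
        train_data: Dataset,
        test_data: Dataset | None = None,
        *,
        layer_sizes=None,
        hidden=(64, 64),
        **config,
    ):
        self.train_data = train_data
        self.test_data = test_data
        n_in = train_data.X.shape[1]
        n_out = train_data.n_classes
        if layer_sizes is None:
            layer_sizes = (n_in, *hidden, n_out)
        layer_sizes = tuple(int(n) for n in layer_sizes)
        if layer_sizes[0] != n_in:
            raise ValueError(
                f"layer_sizes[0]={layer_sizes[0]} does not match input dim {n_in}"
            )
        if layer_sizes[-1] != n_out:
            raise ValueError(
                f"layer_sizes[-1]={layer_sizes[-1]} does not match {n_out} classes"
            )
        if test_data is not None and test_data.X.shape[1] != n_in:
            raise ValueError("test set width differs from training set")
        self.config = TrainConfig(layer_sizes=layer_sizes, **config)

    @classmethod
    def from_datasets(cls, train_data, test_data=None, **kw) -> "GLSNN":
        return cls(train_data, test_data, **kw)

    def _init_state(self) -> tuple[Network, FeedbackParams]:
        cfg = self.config
        net = init_network(list(cfg.layer_sizes), np.random.default_rng([cfg.seed, 0]).integers(2**31), cfg.init_scheme)
        fb = init_feedback(
            list(cfg.layer_sizes),
            np.random.default_rng([cfg.seed, 1]).integers(2**31),
            scale=cfg.feedback_scale,
            bias_scale=cfg.bias_scale,
            eta_t=cfg.eta_t,
        )
        return net, fb

    def fit(self, epochs: int | None = None, verbose: bool = False) -> "GLSNNResults":
        """Train for the configured number of epochs and return results.

        Raises
        ------
        RuntimeError
            If the training loss becomes non-finite (names the epoch and
            batch where it happened).
        """
        cfg = self.config if epochs is None else self.config.replace(epochs=epochs)
        net, fb = self._init_state()
        upd = UpdateConfig(eta_w=cfg.eta_w, batch_reduction=cfg.batch_reduction)
        X, y = self.train_data.X, self.train_data.y
        n = len(y)

        rows = []
        for epoch in range(1, cfg.epochs + 1):
            tic = time.perf_counter()
            order = np.random.default_rng([cfg.seed, 2, epoch]).permutation(n)
            batch_losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                Xb, yb = X[idx], y[idx]
                try:
                    trace = simulate_forward(net, Xb, cfg.neuron, cfg.record_spikes)
                except FloatingPointError as exc:
                    raise RuntimeError(
                        f"diverged at epoch {epoch}, batch starting at sample "
                        f"{start}: {exc}; lower eta_w or check the input scaling"
                    ) from exc
                targets = compute_all_targets(
                    trace,
                    net,
                    fb,
                    yb,
                    amplitude=cfg.target_amplitude,
                    n_feedback_layers=cfg.n_feedback_layers,
                )
                loss = l2_loss(trace.S_layers[-1], targets.S_T) / len(yb)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, "
                        f"batch starting at sample {start}; "
                        "lower eta_w or check the input scaling"
                    )
                batch_losses.append(loss)
                net = update_all_layers(net, trace, targets, upd)

            train_acc = evaluate(net, cfg.neuron, X, y)
            test_acc = (
                evaluate(net, cfg.neuron, self.test_data.X, self.test_data.y)
                if self.test_data is not None
                else np.nan
            )
            rows.append(
                {
                    "epoch": epoch,
                    "train_acc": train_acc,
                    "test_acc": test_acc,
                    "loss": float(np.mean(batch_losses)),
                    "seconds": time.perf_counter() - tic,
                }
            )
            if verbose:
                print(
                    f"epoch={epoch} train_acc={train_acc:.2f} "
                    f"test_acc={test_acc:.2f} loss={rows[-1]['loss']:.5f}"
                )

        history = pd.DataFrame(rows)
        return GLSNNResults(model=self, config=cfg, network=net, feedback=fb, history=history)


@dataclass
class GLSNNResults:
    """A fitted GLSNN: trained weights, history, and diagnostics.

    ``history`` has one row per epoch with columns ``epoch``,
    ``train_acc``, ``test_acc``, ``loss`` (mean per-sample squared output
    error over training batches) and ``seconds`` (wall clock,
    informational only).
    """

    model: GLSNN
    config: TrainConfig
    network: Network
    feedback: FeedbackParams
    history: pd.DataFrame

    @property
    def train_accuracy(self) -> np.ndarray:
        return self.history["train_acc"].to_numpy()

    @property
    def test_accuracy(self) -> np.ndarray:
        return self.history["test_acc"].to_numpy()

    @property
    def loss(self) -> np.ndarray:
        return self.history["loss"].to_numpy()

    @property
    def final_test_accuracy(self) -> float:
        return float(self.history["test_acc"].iloc[-1])

    @property
    def final_train_accuracy(self) -> float:
        return float(self.history["train_acc"].iloc[-1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted class labels by output-surrogate argmax."""
        trace = simulate_forward(self.network, np.atleast_2d(X), self.config.neuron)
        return np.argmax(trace.S_layers[-1], axis=1)

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        """Accuracy (%) of the trained network on new data."""
        return evaluate(self.network, self.config.neuron, X, y)

    def layer_activations(self, X: np.ndarray) -> list[np.ndarray]:
        """Final-step surrogate outputs of every layer (input first)."""
        return simulate_forward(self.network, np.atleast_2d(X), self.config.neuron).S_layers

    def simulate(self, X: np.ndarray, record_spikes: bool = True):
        """Re-run the forward pass on given inputs (spike rasters by default)."""
        return simulate_forward(self.network, np.atleast_2d(X), self.config.neuron, record_spikes)

    def save(self, path) -> None:
        """Serialize weights, feedback projections and config to a .npz archive."""
        from .serialize import save_model

        save_model(path, self.network, self.feedback, self.config)

    def summary(self) -> str:
        """Human-readable fit summary, statsmodels style."""
        cfg = self.config
        n_params = sum(W.size for W in self.network.weights)
        arch = "-".join(str(n) for n in cfg.layer_sizes)
        nfb = cfg.n_feedback_layers
        lines = [
            "GLSNN Results",
            "=" * 58,
            f"{'Architecture:':<28}[{arch}]",
            f"{'Trainable weights:':<28}{n_params}",
            f"{'Epochs:':<28}{len(self.history)}",
            f"{'Batch size:':<28}{cfg.batch_size}",
            f"{'Target learning rate:':<28}{cfg.eta_t}",
            f"{'Weight learning rate:':<28}{cfg.eta_w}",
            f"{'Feedback layers:':<28}{'all' if nfb is None else nfb}",
            f"{'Weight init:':<28}{cfg.init_scheme}",
            f"{'Seed:':<28}{cfg.seed}",
            f"{'Simulation steps (T/dt):':<28}{cfg.neuron.n_steps}",
            "-" * 58,
            f"{'Final train accuracy (%):':<28}{self.final_train_accuracy:.2f}",
            f"{'Final test accuracy (%):':<28}{self.final_test_accuracy:.2f}",
            f"{'Final training loss:':<28}{self.history['loss'].iloc[-1]:.5f}",
            "=" * 58,
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Accuracy and loss curves over epochs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["train_acc"], label="train")
        if self.history["test_acc"].notna().any():
            ax.plot(self.history["epoch"], self.history["test_acc"], label="test")
        ax.set_xlabel("epoch")
        ax.set_ylabel("accuracy (%)")
        ax2 = ax.twinx()
        ax2.plot(self.history["epoch"], self.history["loss"], color="gray", alpha=0.5)
        ax2.set_ylabel("loss")
        ax.legend()
        return ax

    def plot_raster(self, X: np.ndarray, sample: int = 0, ax=None):
        """Spike raster (time x neuron) of every hidden/output layer for one sample."""
        import matplotlib.pyplot as plt

        trace = self.simulate(X, record_spikes=True)
        n_layers = len(trace.spikes)
        if ax is None:
            _, axes = plt.subplots(n_layers, 1, sharex=True, squeeze=False)
            axes = axes.ravel()
        else:
            axes = [ax]
        for l, (sp, a) in enumerate(zip(trace.spikes, axes), start=1):
            t_idx, n_idx = np.nonzero(sp[:, sample, :])
            a.scatter(t_idx, n_idx, s=4, marker="|")
            a.set_ylabel(f"layer {l}")
        axes[-1].set_xlabel("time step")
        return axes
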
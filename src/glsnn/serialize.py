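"""Model archives: weights + feedback projections + config in one .npz.

Feedback matrices must round-trip bit-exact so a run can be resumed or
re-evaluated reproducibly; float64 arrays in npz satisfy that.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .feedback import FeedbackParams
from .lif import NeuronParams
from .network import Network

__all__ = ["save_model", "load_model"]


def save_model(path, net: Network, fb: FeedbackParams, config=None) -> None:
    """Write a single .npz archive with the network, feedback set and
    (optionally) the training config echo."""
    arrays = {"layer_sizes": np.asarray(net.layer_sizes, dtype=np.int64)}
    for l, W in enumerate(net.weights):
        arrays[f"W_{l}"] = W
    arrays["fb_layers"] = np.asarray(sorted(fb.B), dtype=np.int64)
    for l in fb.B:
        arrays[f"B_{l}"] = fb.B[l]
        arrays[f"b_{l}"] = fb.b[l]
    arrays["eta_t"] = np.float64(fb.eta_t)
    meta = {}
    if config is not None:
        meta = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
            if k != "neuron"
        }
        meta["neuron"] = config.neuron.to_dict()
    arrays["config_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path) -> tuple[Network, FeedbackParams, dict]:
    """Read an archive back; returns (network, feedback, config dict).

    The config dict contains a ``neuron`` sub-dict suitable for
    :meth:`NeuronParams.from_dict` when a config was stored.
    """
    path = Path(path)
    with np.load(path) as z:
        layer_sizes = [int(n) for n in z["layer_sizes"]]
        weights = [z[f"W_{l}"] for l in range(len(layer_sizes) - 1)]
        B = {int(l): z[f"B_{l}"] for l in z["fb_layers"]}
        b = {int(l): z[f"b_{l}"] for l in z["fb_layers"]}
        eta_t = float(z["eta_t"])
        cfg = json.loads(bytes(z["config_json"]).decode("utf-8"))
    net = Network(layer_sizes, weights)
    fb = FeedbackParams(B=B, b=b, eta_t=eta_t)
    return net, fb, cfg
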
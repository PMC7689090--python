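"""Flat key-value config files (INI) with [neuron], [network], [train] sections.

Example::

    [neuron]
    V_E = 0.2
    V_th = 0.0009
    dt = 0.01
    T = 0.1

    [network]
    layer_sizes = 784,800,800,800,10
    init_scheme = orthogonal

    [train]
    epochs = 100
    batch_size = 10
    eta_t = 0.5
    eta_w = 0.015
    seed = 0
"""

from __future__ import annotations

import configparser
from pathlib import Path

from .lif import NeuronParams
from .model import TrainConfig

__all__ = ["load_config", "save_config"]

_TRAIN_INT = {"epochs", "batch_size", "seed", "n_feedback_layers"}
_TRAIN_FLOAT = {"eta_t", "eta_w", "feedback_scale", "bias_scale", "target_amplitude"}
_TRAIN_BOOL = {"record_spikes"}
_TRAIN_STR = {"init_scheme", "batch_reduction"}


def load_config(path: str | Path, **overrides) -> TrainConfig:
    """Read a config file into a TrainConfig; keyword overrides win.

    ``layer_sizes`` may live in [network] (alongside ``init_scheme``);
    learning settings in [train]; LIF constants in [neuron].
    """
    cp = configparser.ConfigParser()
    cp.optionxform = str  # keys like V_th are case-sensitive
    read = cp.read(path)
    if not read:
        raise FileNotFoundError(f"config file not found: {path}")

    kw: dict = {}
    if cp.has_section("neuron"):
        kw["neuron"] = NeuronParams.from_dict(dict(cp.items("neuron")))
    if cp.has_section("network"):
        sec = dict(cp.items("network"))
        if "layer_sizes" in sec:
            kw["layer_sizes"] = tuple(
                int(s) for s in sec.pop("layer_sizes").replace(" ", "").split(",")
            )
        if "init_scheme" in sec:
            kw["init_scheme"] = sec.pop("init_scheme")
        if sec:
            raise ValueError(f"unknown [network] key(s): {sorted(sec)}")
    if cp.has_section("train"):
        for key, raw in cp.items("train"):
            if key in _TRAIN_INT:
                kw[key] = int(raw)
            elif key in _TRAIN_FLOAT:
                kw[key] = float(raw)
            elif key in _TRAIN_BOOL:
                kw[key] = raw.strip().lower() in ("1", "true", "yes", "on")
            elif key in _TRAIN_STR:
                kw[key] = raw.strip()
            else:
                raise ValueError(f"unknown [train] key: {key}")

    kw.update({k: v for k, v in overrides.items() if v is not None})
    if "layer_sizes" not in kw:
        raise ValueError("config must provide layer_sizes ([network] section or override)")
    return TrainConfig(**kw)


def save_config(path: str | Path, cfg: TrainConfig) -> None:
    cp = configparser.ConfigParser()
    cp.optionxform = str
    cp["neuron"] = {k: repr(v) for k, v in cfg.neuron.to_dict().items()}
    cp["network"] = {
        "layer_sizes": ",".join(map(str, cfg.layer_sizes)),
        "init_scheme": cfg.init_scheme,
    }
    train = {
        k: str(v)
        for k, v in vars(cfg).items()
        if k not in ("neuron", "layer_sizes", "init_scheme") and v is not None
    }
    cp["train"] = train
    with open(path, "w") as fh:
        cp.write(fh)
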
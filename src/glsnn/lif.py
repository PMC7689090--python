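"""Discrete-time conductance-based leaky integrate-and-fire dynamics.

The neuron model: membrane potential ``V`` leaks toward the resting
potential ``V_L`` and is pulled toward the excitatory reversal potential
``V_E`` by a conductance ``g_E`` that relaxes toward the weighted
pre-synaptic drive.  When ``V`` crosses the firing threshold the neuron
emits a spike and resets.  The per-neuron *surrogate output*

    S = drive + tau_s * spike

carries a real-valued residual-style signal between layers: the weighted
input plus a small spike bonus.  Learning operates on ``S``, never on raw
spike trains.

One simulation step (the canonical ordering; ``g_E`` in the voltage line
is the pre-update conductance):

    V'   = V - (dt/tau_m) * [(V - V_L) + (g_E/g_L) * (V - V_E)]
    g_E' = g_E + (dt/tau_E) * (-g_E + drive)
    spike where V' > V_th (strict), then V' := V_reset there
    S    = drive + tau_s * spike
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "NeuronParams",
    "LayerState",
    "init_layer_state",
    "lif_step",
    "surrogate_output",
    "conductance_fixed_point",
]


@dataclass(frozen=True)
class NeuronParams:
    """All LIF and simulation constants.

    Defaults are the standard operating point for image-vector
    classification: a tiny firing threshold relative to the drive scale,
    so active neurons spike within a few steps of the 10-step window.

    Parameters
    ----------
    V_L : float
        Leak (resting) potential (a.u.).
    V_E : float
        Excitatory reversal potential (a.u.); must satisfy ``V_L <= V_E``.
    V_th : float
        Firing threshold; comparison is strict (``V > V_th``).
    V_reset : float
        Post-spike reset potential; must satisfy ``V_reset <= V_th``.
    tau_m : float
        Membrane time constant (= C_m / g_L), in time units.
    tau_E : float
        Excitatory conductance decay constant, in time units.
    g_L : float
        Leak conductance (a.u.).
    tau_s : float
        Surrogate spike amplitude (dimensionless) added to the drive when
        the neuron fires.
    dt : float
        Simulation step, in time units.  ``dt/tau_m`` and ``dt/tau_E``
        must not exceed 1 (explicit-Euler stability).
    T : float
        Total simulation time; ``T/dt`` must be a positive integer.
    """

    V_L: float = 0.0
    V_E: float = 0.2
    V_th: float = 0.0009
    V_reset: float = 0.0
    tau_m: float = 0.5
    tau_E: float = 0.2
    g_L: float = 20.0
    tau_s: float = 0.01
    dt: float = 0.01
    T: float = 0.1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.T < self.dt:
            raise ValueError(f"T ({self.T}) must be >= dt ({self.dt})")
        steps = self.T / self.dt
        if abs(steps - round(steps)) > 1e-9 * max(1.0, steps):
            raise ValueError(f"T/dt = {steps} is not a positive integer")
        if self.tau_m <= 0 or self.tau_E <= 0 or self.g_L <= 0:
            raise ValueError("tau_m, tau_E and g_L must be positive")
        if self.dt / self.tau_m > 1 or self.dt / self.tau_E > 1:
            raise ValueError("dt/tau_m and dt/tau_E must be <= 1 for stability")
        if self.V_reset > self.V_th:
            raise ValueError(f"V_reset ({self.V_reset}) must be <= V_th ({self.V_th})")
        if self.V_L > self.V_E:
            raise ValueError(f"V_L ({self.V_L}) must be <= V_E ({self.V_E})")

    @property
    def n_steps(self) -> int:
        """Number of simulation steps, T/dt."""
        return int(round(self.T / self.dt))

    def to_dict(self) -> dict[str, float]:
        """Flat key-value form (keys: V_L, V_E, V_th, V_reset, tau_m,
        tau_E, g_L, tau_s, dt, T)."""
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown neuron parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def replace(self, **kw) -> "NeuronParams":
        return replace(self, **kw)


@dataclass
class LayerState:
    """Per-neuron state of one layer at one time step.

    ``V``: membrane potential; ``g_E``: excitatory conductance;
    ``delta``: 0/1 spike indicator; ``S``: surrogate output.
    All four arrays share a trailing neuron axis (and, batched, a leading
    sample axis).
    """

    V: np.ndarray
    g_E: np.ndarray
    delta: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.V.shape, self.g_E.shape, self.delta.shape, self.S.shape}
        if len(shapes) != 1:
            raise ValueError(f"LayerState field shapes differ: {shapes}")


def init_layer_state(shape: int | tuple[int, ...], params: NeuronParams) -> LayerState:
    """Fresh resting state: V = V_reset, g_E = 0, no spikes, S = 0.

    State is fully reset between samples; nothing leaks across them.
    """
    z = np.zeros(shape, dtype=np.float64)
    return LayerState(V=z + params.V_reset, g_E=z.copy(), delta=z.copy(), S=z.copy())


def lif_step(state: LayerState, drive: np.ndarray, params: NeuronParams) -> LayerState:
    """Advance one layer by one simulation step.

    ``drive`` is the weighted pre-synaptic input sum_j w_{j,i} S_j per
    neuron.  The voltage update uses the PRE-update conductance; the
    conductance then relaxes toward ``drive``; spiking neurons reset to
    ``V_reset``; the surrogate output is ``drive + tau_s * delta``.
    Returns a new state; the input state is not mutated.

    Raises
    ------
    ValueError
        If ``drive``'s shape differs from the state or contains
        non-finite values.
    """
    drive = np.asarray(drive, dtype=np.float64)
    if drive.shape != state.V.shape:
        raise ValueError(
            f"drive shape {drive.shape} does not match state shape {state.V.shape}"
        )
    if not np.all(np.isfinite(drive)):
        raise FloatingPointError("non-finite drive passed to lif_step")

    p = params
    V = state.V - (p.dt / p.tau_m) * (
        (state.V - p.V_L) + (state.g_E / p.g_L) * (state.V - p.V_E)
    )
    g_E = state.g_E + (p.dt / p.tau_E) * (-state.g_E + drive)
    spiked = V > p.V_th
    V = np.where(spiked, p.V_reset, V)
    delta = spiked.astype(np.float64)
    S = surrogate_output(drive, delta, p.tau_s)
    return LayerState(V=V, g_E=g_E, delta=delta, S=S)


def surrogate_output(drive: np.ndarray, delta: np.ndarray, tau_s: float) -> np.ndarray:
    """Residual-style surrogate output S = drive + tau_s * delta."""
    drive = np.asarray(drive, dtype=np.float64)
    delta = np.asarray(delta, dtype=np.float64)
    if drive.shape != delta.shape:
        raise ValueError(
            f"drive shape {drive.shape} does not match delta shape {delta.shape}"
        )
    return drive + tau_s * delta


def conductance_fixed_point(drive: np.ndarray) -> np.ndarray:
    """Fixed point of the conductance recursion g' = g + (dt/tau_E)(-g + drive).

    The recursion is linear, so g* = drive exactly, and the gap
    ``|g(t) - g*|`` shrinks geometrically with factor ``1 - dt/tau_E``
    per step.  Exposed as an analytic reference for the dynamics.
    """
    drive = np.asarray(drive, dtype=np.float64)
    if not np.all(np.isfinite(drive)):
        raise FloatingPointError("non-finite drive")
    return drive.copy()
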
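"""Pluggable membrane kinetics: ionic current I_ion(v, s) and state dynamics.

A membrane model exposes the ionic current density I_ion (uA/cm^2, positive
outward) and the dynamics of its state vector s.  State components are
partitioned into *gates*, which follow Hodgkin–Huxley relaxation
ds/dt = (s_inf(v) - s)/tau(v) and are advanced with the exponential
Rush–Larsen update (exact for frozen voltage, unconditionally keeps gates in
[0, 1]), and *non-gates*, advanced by forward Euler.

Two models ship with the package:

* :class:`PassiveMembrane` — a linear leak, used for exact algebraic and
  differential-equation oracles.
* :class:`MitchellSchaeffer` — the two-current minimal ventricular model of
  Mitchell & Schaeffer, rescaled to physiological units (mV, ms), with a
  smooth sigmoidal gate.  It reproduces the qualitative AP features that the
  network-level experiments need (threshold, fast upstroke, plateau,
  refractoriness) without tracking individual ion species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "MembraneModel",
    "PassiveMembrane",
    "MitchellSchaeffer",
    "rush_larsen_step",
    "get_model",
    "register_model",
    "MODEL_REGISTRY",
]


class MembraneModel:
    """Interface for membrane kinetics.

    Subclasses define ``n_states``, ``gate_idx`` (indices of gate
    components), ``v_rest`` (mV), ``s_rest`` and the three callables below.
    All voltage/state arguments are vectorized: ``v`` has shape (N,) and
    ``s`` shape (n_states, N).
    """

    name: str = "abstract"
    n_states: int = 0
    gate_idx: np.ndarray = np.empty(0, dtype=int)
    v_rest: float = -80.0

    @property
    def s_rest(self) -> np.ndarray:
        raise NotImplementedError

    @property
    def nongate_idx(self) -> np.ndarray:
        mask = np.ones(self.n_states, dtype=bool)
        mask[self.gate_idx] = False
        return np.nonzero(mask)[0]

    def ionic_current(self, v: np.ndarray, s: np.ndarray) -> np.ndarray:
        """I_ion in uA/cm^2, positive outward."""
        raise NotImplementedError

    def gate_inf_tau(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Steady states and time constants of the gate components at v."""
        raise NotImplementedError

    def state_derivatives(self, v: np.ndarray, s: np.ndarray) -> np.ndarray:
        """ds/dt for non-gate components (full-shape array; gate rows ignored)."""
        return np.zeros_like(s)

    def resting_state(self, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
        v = np.full(n_nodes, self.v_rest, dtype=float)
        s = np.tile(self.s_rest.reshape(-1, 1), (1, n_nodes)) if self.n_states else np.empty((0, n_nodes))
        return v, s

    def _validate(self, v: np.ndarray, s: np.ndarray) -> None:
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite membrane potential")
        if s.shape[0] != self.n_states:
            raise ValueError(f"state dimension {s.shape[0]} != {self.n_states}")
        if self.n_states and not np.all(np.isfinite(s)):
            raise ValueError("non-finite membrane state")


@dataclass
class PassiveMembrane(MembraneModel):
    """Linear leak membrane: I_ion = g_leak * (v - e_leak), no state.

    g_leak in mS/cm^2; with the default 0.05 mS/cm^2 and C_m = 1 uF/cm^2 the
    membrane time constant is 20 ms.
    """

    g_leak: float = 0.05
    e_leak: float = -80.0
    name: str = "passive"
    n_states: int = 0

    def __post_init__(self) -> None:
        self.v_rest = self.e_leak
        self.gate_idx = np.empty(0, dtype=int)

    @property
    def s_rest(self) -> np.ndarray:
        return np.empty(0)

    def ionic_current(self, v, s):
        v = np.asarray(v, dtype=float)
        self._validate(v, np.asarray(s).reshape(0, v.size))
        return self.g_leak * (v - self.e_leak)

    def gate_inf_tau(self, v):
        empty = np.empty((0,) + np.shape(v))
        return empty, empty


@dataclass
class MitchellSchaeffer(MembraneModel):
    """Two-current minimal model (Mitchell & Schaeffer 2003) in mV/ms units.

    The dimensionless potential V = (v - v_rest)/amplitude obeys
    dV/dt = h V^2 (1 - V)/tau_in - V/tau_out plus stimulus, and the single
    recovery gate h relaxes toward a sigmoid of V (open below v_gate, closed
    above) with time constant tau_open / tau_close.  The ionic current is
    reported for C_m = 1 uF/cm^2 so that -I_ion/C_m reproduces the model's
    dV/dt; the smooth gate (width ``k_gate``) replaces the original
    discontinuous switch so that convergence-order measurements are clean.

    Default time constants are chosen for an atrial-like AP (fast upstroke,
    APD near 150 ms) whose excitation threshold places strongly uncoupled
    cell-to-cell junctions near the discrete propagation-failure regime,
    where cell-based and homogenized tissue descriptions visibly diverge.
    """

    tau_in: float = 0.2
    tau_out: float = 3.5
    tau_open: float = 100.0
    tau_close: float = 100.0
    v_gate: float = 0.13
    k_gate: float = 0.02
    amplitude: float = 100.0
    v_rest: float = -80.0
    name: str = "mitchell-schaeffer"
    n_states: int = 1

    def __post_init__(self) -> None:
        self.gate_idx = np.array([0])

    def _dimensionless(self, v: np.ndarray) -> np.ndarray:
        return (np.asarray(v, dtype=float) - self.v_rest) / self.amplitude

    @property
    def s_rest(self) -> np.ndarray:
        h_inf, _ = self.gate_inf_tau(np.array([self.v_rest]))
        return np.array([float(h_inf[0, 0])])

    def ionic_current(self, v, s):
        v = np.asarray(v, dtype=float)
        s = np.atleast_2d(np.asarray(s, dtype=float))
        self._validate(v, s)
        h = s[0]
        V = self._dimensionless(v)
        dVdt = h * V * V * (1.0 - V) / self.tau_in - V / self.tau_out
        return -self.amplitude * dVdt  # uA/cm^2 at C_m = 1 uF/cm^2

    def gate_inf_tau(self, v):
        V = self._dimensionless(np.asarray(v, dtype=float))
        # open below the gate voltage, closed above, smooth switch
        h_inf = 1.0 / (1.0 + np.exp((V - self.v_gate) / self.k_gate))
        tau = self.tau_close + (self.tau_open - self.tau_close) * h_inf
        return h_inf[np.newaxis, ...], tau[np.newaxis, ...]


def rush_larsen_step(model: MembraneModel, v: np.ndarray, s: np.ndarray, dt: float) -> np.ndarray:
    """Advance the membrane state by dt at frozen voltage v.

    Gates use the exponential closed form s' = s_inf + (s - s_inf) e^{-dt/tau};
    non-gates use forward Euler on the model's derivatives.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if model.n_states == 0:
        return s
    v = np.asarray(v, dtype=float)
    s_new = np.array(s, dtype=float, copy=True)
    gates = model.gate_idx
    if gates.size:
        s_inf, tau = model.gate_inf_tau(v)
        s_new[gates] = s_inf + (s[gates] - s_inf) * np.exp(-dt / tau)
    others = model.nongate_idx
    if others.size:
        ds = model.state_derivatives(v, s)
        s_new[others] = s[others] + dt * ds[others]
    return s_new


MODEL_REGISTRY: dict[str, Callable[..., MembraneModel]] = {
    "passive": PassiveMembrane,
    "mitchell-schaeffer": MitchellSchaeffer,
}


def register_model(name: str, factory: Callable[..., MembraneModel]) -> None:
    """Register a custom membrane model factory under ``name``."""
    MODEL_REGISTRY[name] = factory


def get_model(name: str, **overrides) -> MembraneModel:
    """Instantiate a registered membrane model, applying parameter overrides."""
    try:
        factory = MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown membrane model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        ) from None
    return factory(**overrides)
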
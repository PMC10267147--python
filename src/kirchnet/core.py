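"""Assembly and time stepping of the Kirchhoff network system.

State of the tissue is the membrane potential v^k and extracellular
potential u_e^k per node plus the membrane state s^k.  The intracellular
potential is eliminated via u_i = v + u_e.  Each step applies first-order
(Godunov) operator splitting:

1. reaction substep — Rush–Larsen/Euler update of s and explicit update of
   v by the ionic + stimulus current density;
2. network substep — backward-Euler solve of the coupled linear system

       A_m C_m (v' - v*) / dt = -[L_i (v' + u_e')]        (charge balance)
       L_i v' + (L_i + L_e) u_e' = 0                      (current conservation)

   where L_i, L_e are the conductance-weighted graph Laplacians and rows of
   the conservation block at grounded (Dirichlet) compartments are replaced
   by u_e = 0.

The same machinery integrates the finite-difference bidomain scheme, which
is expressed as a :class:`~kirchnet.geometry.Network` (see
:mod:`kirchnet.bidomain`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Network

__all__ = [
    "SimState",
    "LinearSystem",
    "Trace",
    "SolverError",
    "NoDirichletError",
    "edge_currents",
    "kirchhoff_residual",
    "assemble",
    "step",
    "simulate",
]


class SolverError(RuntimeError):
    """Linear network solve failed to converge."""


class NoDirichletError(ValueError):
    """The extracellular potential is ungrounded (singular system)."""


@dataclass
class SimState:
    """Snapshot of the tissue at time t: v, u_e (mV) and membrane state s."""

    t: float
    v: np.ndarray
    u_e: np.ndarray
    s: np.ndarray

    def copy(self) -> "SimState":
        return SimState(self.t, self.v.copy(), self.u_e.copy(), self.s.copy())


def edge_currents(state: SimState, net: Network) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge intracellular and extracellular currents (uA).

    Edge (j, k) carries I_i = G_i (u_i^j - u_i^k) and I_e = G_e (u_e^j -
    u_e^k), positive when charge flows from j to k; both are antisymmetric
    under swapping the endpoints.
    """
    j, k = net.edges[:, 0], net.edges[:, 1]
    u_i = state.v + state.u_e
    return net.g_i * (u_i[j] - u_i[k]), net.g_e * (state.u_e[j] - state.u_e[k])


def kirchhoff_residual(state: SimState, net: Network) -> np.ndarray:
    """Per-node defect of current conservation (uA), zero at grounded nodes.

    residual_k = sum_j I_i^{j,k} + sum_j I_e^{j,k}; after a converged
    network substep this is at solver-tolerance level.  Diagnostic only.
    """
    l_i = net.laplacian(net.g_i)
    l_e = net.laplacian(net.g_e)
    res = -(l_i @ (state.v + state.u_e) + l_e @ state.u_e)
    res[net.dirichlet] = 0.0
    return res


def _residual_scale(state: SimState, net: Network) -> float:
    """Max per-node total incident current magnitude (uA), floored at 1."""
    i_i, i_e = edge_currents(state, net)
    mag = np.zeros(net.n_nodes)
    np.add.at(mag, net.edges[:, 0], np.abs(i_i) + np.abs(i_e))
    np.add.at(mag, net.edges[:, 1], np.abs(i_i) + np.abs(i_e))
    return max(1.0, float(mag.max(initial=0.0)))


@dataclass
class LinearSystem:
    """Prefactored backward-Euler operator for the network substep.

    Depends only on the network, C_m and dt, so one assembly serves every
    step.  ``solver`` is "direct" (sparse LU, default) or "gmres"
    (relative tolerance ``tol``); both satisfy the same conservation
    contract.
    """

    net: Network
    c_m: float
    dt: float
    tol: float
    solver: str
    matrix: sp.csc_matrix
    _lu: spla.SuperLU | None = field(default=None, repr=False)
    _d_over_dt: np.ndarray | None = field(default=None, repr=False)

    def solve(self, v_star: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = self.net.n_nodes
        rhs = np.zeros(2 * n)
        rhs[:n] = self._d_over_dt * v_star
        if self.solver == "direct":
            x = self._lu.solve(rhs)
        else:
            x, info = spla.gmres(self.matrix, rhs, rtol=self.tol, atol=0.0, maxiter=20 * n)
            if info != 0:
                raise SolverError(f"GMRES failed to converge (info={info}, n={n})")
        v, u_e = x[:n], x[n:]
        u_e = u_e.copy()
        u_e[self.net.dirichlet] = 0.0  # enforce grounding exactly
        return v, u_e


def assemble(net: Network, c_m: float = 1.0, dt: float = 0.01, *,
             solver: str = "direct", tol: float = 1e-10) -> LinearSystem:
    """Assemble the coupled (v, u_e) backward-Euler system for time step dt (ms)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if c_m <= 0:
        raise ValueError("c_m must be positive")
    if solver not in ("direct", "gmres"):
        raise ValueError(f"unknown solver {solver!r}")
    if not np.any(net.dirichlet):
        raise NoDirichletError(
            "no grounded extracellular node: the (v, u_e) system is singular; "
            "flag at least one boundary compartment as Dirichlet"
        )
    n = net.n_nodes
    l_i = net.laplacian(net.g_i)
    l_e = net.laplacian(net.g_e)
    d_over_dt = net.a_m * c_m / dt  # uF/ms = mS

    keep = sp.diags((~net.dirichlet).astype(float))
    ident_dir = sp.diags(net.dirichlet.astype(float))
    a11 = sp.diags(d_over_dt) + l_i
    a12 = l_i
    a21 = keep @ l_i
    a22 = keep @ (l_i + l_e) + ident_dir
    matrix = sp.bmat([[a11, a12], [a21, a22]], format="csc")

    system = LinearSystem(net=net, c_m=c_m, dt=dt, tol=tol, solver=solver, matrix=matrix)
    system._d_over_dt = d_over_dt
    if solver == "direct":
        system._lu = spla.splu(matrix)
    return system


def step(state: SimState, system: LinearSystem, model, stim_density, dt: float) -> SimState:
    """One split step: reaction substep then implicit network substep.

    ``stim_density`` is a per-node depolarizing stimulus current density
    (uA/cm^2, array or scalar 0) held fixed over the step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    from .membrane import rush_larsen_step

    s_new = rush_larsen_step(model, state.v, state.s, dt) if model.n_states else state.s
    i_ion = model.ionic_current(state.v, s_new)
    v_star = state.v + dt * (-i_ion + stim_density) / system.c_m
    v, u_e = system.solve(v_star)
    return SimState(state.t + dt, v, u_e, s_new)


@dataclass
class Trace:
    """Time series of a simulation plus activation bookkeeping.

    ``activations`` holds, per node, the sorted list of upward
    threshold-crossing times detected at full step resolution; each event
    stores the step-end time and a linearly interpolated crossing time.
    ``last_above`` is the last time each node's v was at/above threshold.
    """

    times: np.ndarray
    v: np.ndarray          # (n_snapshots, n_nodes)
    u_e: np.ndarray
    positions: np.ndarray  # (n_nodes, 2), um
    activations_step: list
    activations_interp: list
    last_above: np.ndarray
    threshold: float
    final_state: SimState
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    @property
    def duration(self) -> float:
        return float(self.final_state.t)

    def activation_times(self, node: int, *, interpolate: bool = False) -> np.ndarray:
        events = self.activations_interp[node] if interpolate else self.activations_step[node]
        return np.asarray(events, dtype=float)

    def first_activation(self, node: int, *, interpolate: bool = False) -> float | None:
        times = self.activation_times(node, interpolate=interpolate)
        return float(times[0]) if times.size else None

    def activation_count(self, node: int, after: float = -np.inf) -> int:
        times = self.activation_times(node)
        return int(np.count_nonzero(times >= after))

    def to_activation_csv(self, path) -> None:
        import pandas as pd

        rows = []
        for node in range(self.n_nodes):
            for idx, (t_step, t_int) in enumerate(
                zip(self.activations_step[node], self.activations_interp[node])
            ):
                rows.append((node, idx, t_step, t_int))
        pd.DataFrame(rows, columns=["node", "event", "t_step_ms", "t_interp_ms"]).to_csv(
            path, index=False
        )

    def to_npz(self, path) -> None:
        """Structured binary snapshot container (schema version 1)."""
        import json

        np.savez_compressed(
            path,
            schema_version=1,
            times_ms=self.times,
            v_mV=self.v,
            u_e_mV=self.u_e,
            positions_um=self.positions,
            threshold_mV=self.threshold,
            config_json=json.dumps(self.meta.get("config", {}), default=str),
        )


def simulate(
    net: Network,
    model,
    protocol=None,
    *,
    dt: float = 0.01,
    duration: float = 50.0,
    c_m: float = 1.0,
    snapshot_every: float = 1.0,
    threshold: float = -20.0,
    stop_after_all_activated: float | None = None,
    solver: str = "direct",
    tol: float = 1e-10,
    v0: np.ndarray | None = None,
    s0: np.ndarray | None = None,
    config: dict | None = None,
) -> Trace:
    """Run the split scheme for ``duration`` ms and record a Trace.

    Snapshots are taken every ``snapshot_every`` ms; activation detection
    (upward crossings of ``threshold``) runs at full dt resolution.  If
    ``stop_after_all_activated`` is set, the run ends that many ms after
    every node has activated at least once (used by conduction-velocity
    drivers to avoid simulating past the wavefront).  A stimulus entry is
    active on steps whose midpoint lies in [onset, onset + duration).
    """
    if duration < 0:
        raise ValueError("duration must be nonnegative")
    n = net.n_nodes
    v, s = model.resting_state(n)
    if v0 is not None:
        v = np.array(v0, dtype=float)
    if s0 is not None:
        s = np.array(s0, dtype=float).reshape(model.n_states, n)
    state = SimState(0.0, v, np.zeros(n), s)

    n_steps = int(round(duration / dt)) if duration > 0 else 0
    snap_stride = max(1, int(round(snapshot_every / dt))) if n_steps else 1

    times = [0.0]
    v_snaps = [state.v.copy()]
    ue_snaps = [state.u_e.copy()]
    act_step: list[list[float]] = [[] for _ in range(n)]
    act_interp: list[list[float]] = [[] for _ in range(n)]
    last_above = np.full(n, -np.inf)
    above0 = state.v >= threshold
    last_above[above0] = 0.0
    armed = ~above0
    activated = above0.copy()
    max_res_norm = 0.0
    stop_at = np.inf

    system = assemble(net, c_m, dt, solver=solver, tol=tol) if n_steps else None

    for istep in range(n_steps):
        t_mid = state.t + 0.5 * dt
        stim = protocol.current_density(t_mid, net) if protocol is not None else 0.0
        v_prev = state.v
        state = step(state, system, model, stim, dt)

        res = kirchhoff_residual(state, net)
        res_norm = float(np.abs(res).max(initial=0.0)) / _residual_scale(state, net)
        if res_norm > max_res_norm:
            max_res_norm = res_norm

        above = state.v >= threshold
        crossed = armed & above
        if crossed.any():
            for node in np.nonzero(crossed)[0]:
                act_step[node].append(state.t)
                dv = state.v[node] - v_prev[node]
                frac = (threshold - v_prev[node]) / dv if dv > 0 else 1.0
                act_interp[node].append(state.t - dt + min(max(frac, 0.0), 1.0) * dt)
            activated |= crossed
        armed = ~above
        last_above[above] = state.t

        if (
            stop_after_all_activated is not None
            and stop_at == np.inf
            and activated.all()
        ):
            stop_at = state.t + stop_after_all_activated

        if (istep + 1) % snap_stride == 0 or istep == n_steps - 1:
            times.append(state.t)
            v_snaps.append(state.v.copy())
            ue_snaps.append(state.u_e.copy())

        if state.t >= stop_at:
            break

    return Trace(
        times=np.array(times),
        v=np.array(v_snaps),
        u_e=np.array(ue_snaps),
        positions=net.positions,
        activations_step=act_step,
        activations_interp=act_interp,
        last_above=last_above,
        threshold=threshold,
        final_state=state,
        meta={
            "config": dict(config or {}),
            "dt_ms": dt,
            "duration_ms": duration,
            "solver": solver,
            "tol": tol,
            "max_residual_norm": max_res_norm,
            "net_meta": dict(net.meta),
        },
    )
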
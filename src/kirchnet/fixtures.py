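"""Deterministic test fixtures and independent reference solutions.

Everything here is generated programmatically (no stored data): a dense
differential-algebraic reference solve of the passive network equations
(the brute-force oracle that the split backward-Euler scheme is checked
against), a synthetic planar-wave trace with analytically placed activation
times, and a synthetic rotating-phase trace that mimics sustained reentry.
The synthetic traces are stand-ins constructed from closed-form activation
maps, not simulator output, and are labelled as such in their metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .core import SimState, Trace
from .geometry import CellGeometry, Network, TissueParams, build_grid_network
from .membrane import PassiveMembrane

__all__ = [
    "two_node_network",
    "dense_reference_solution",
    "planar_wave_trace",
    "rotating_reentry_trace",
    "generate_fixtures",
]


def two_node_network(geom: CellGeometry | None = None,
                     params: TissueParams | None = None) -> Network:
    """Two coupled compartments; the left one grounded."""
    return build_grid_network(2, 1, geom or CellGeometry(), params or TissueParams())


def dense_reference_solution(
    net: Network,
    model: PassiveMembrane,
    v0: np.ndarray,
    t_eval: np.ndarray,
    *,
    c_m: float = 1.0,
    stim_density: np.ndarray | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
):
    """Brute-force solve of the passive network equations on a small network.

    Eliminates u_e through the conservation constraint (dense solve with
    Dirichlet rows) and integrates the reduced stiff ODE for v with an
    implicit high-accuracy integrator.  Returns (v(t), u_e(t)) sampled at
    ``t_eval``; intended for <= ~5 nodes.
    """
    n = net.n_nodes
    l_i = net.laplacian(net.g_i).toarray()
    l_e = net.laplacian(net.g_e).toarray()
    keep = np.diag((~net.dirichlet).astype(float))
    a22 = keep @ (l_i + l_e) + np.diag(net.dirichlet.astype(float))
    a21 = keep @ l_i
    # u_e(v) = -a22^{-1} a21 v  (constraint rows; Dirichlet rows give u_e = 0)
    ue_map = -np.linalg.solve(a22, a21)
    d = net.a_m * c_m
    stim = np.zeros(n) if stim_density is None else np.asarray(stim_density, dtype=float)

    def rhs(_t, v):
        u_e = ue_map @ v
        coupling = -(l_i @ (v + u_e))
        return coupling / d + (-model.ionic_current(v, np.empty((0, n))) + stim) / c_m

    sol = solve_ivp(rhs, (float(t_eval[0]), float(t_eval[-1])), v0, t_eval=t_eval,
                    method="Radau", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"reference integration failed: {sol.message}")
    v_t = sol.y.T
    ue_t = v_t @ ue_map.T
    return v_t, ue_t


def _trace_from_activation_map(
    positions: np.ndarray,
    activation_times: list[list[float]],
    *,
    duration: float,
    threshold: float = -20.0,
    apd: float = 100.0,
    label: str,
) -> Trace:
    """Assemble a synthetic Trace whose crossings follow a prescribed map."""
    n = positions.shape[0]
    last_above = np.array([
        (max(times) + apd) if times else -np.inf for times in activation_times
    ])
    final = SimState(duration, np.full(n, -80.0), np.zeros(n), np.empty((0, n)))
    return Trace(
        times=np.array([0.0, duration]),
        v=np.full((2, n), -80.0),
        u_e=np.zeros((2, n)),
        positions=positions,
        activations_step=[list(t) for t in activation_times],
        activations_interp=[list(t) for t in activation_times],
        last_above=last_above,
        threshold=threshold,
        final_state=final,
        meta={"config": {"synthetic": True, "fixture": label}},
    )


def planar_wave_trace(
    cv_cm_s: float = 50.0,
    n_cells: int = 15,
    cell_length_um: float = 120.0,
    *,
    t0: float = 1.0,
    apd: float = 100.0,
) -> Trace:
    """Synthetic 1D trace of a single planar wave at exactly ``cv_cm_s``.

    Activation times are placed analytically: t_k = t0 + x_k / cv, so any
    two-point velocity measurement must return the construction parameter.
    """
    x = (np.arange(n_cells) + 0.5) * cell_length_um
    positions = np.column_stack([x, np.zeros(n_cells)])
    times = [[t0 + (xi * 1e-4) / cv_cm_s * 1e3] for xi in x]  # um->cm, s->ms
    duration = max(t[0] for t in times) + apd + 10.0
    return _trace_from_activation_map(positions, times, duration=duration,
                                      apd=apd, label="planar-wave")


def rotating_reentry_trace(
    n_x: int = 20,
    n_y: int = 20,
    *,
    t_s2: float = 240.0,
    period: float = 120.0,
    n_turns: int = 3,
    cell_length_um: float = 120.0,
    cell_width_um: float = 18.0,
) -> Trace:
    """Synthetic 2D trace of a rotor: activation phase rotates about the center.

    Every node re-activates once per ``period`` for ``n_turns`` rotations
    after the S2 time, emulating sustained spiral-wave reentry.
    """
    ix, iy = np.meshgrid(np.arange(n_x), np.arange(n_y), indexing="xy")
    positions = np.column_stack([
        (ix.ravel() + 0.5) * cell_length_um, (iy.ravel() + 0.5) * cell_width_um
    ])
    cx, cy = (n_x - 1) / 2.0, (n_y - 1) / 2.0
    phase = np.arctan2(iy.ravel() - cy, ix.ravel() - cx)  # (-pi, pi]
    offset = (phase + np.pi) / (2 * np.pi) * period
    activation = [
        [t_s2 + off + turn * period for turn in range(n_turns)] for off in offset
    ]
    duration = t_s2 + n_turns * period + period
    return _trace_from_activation_map(positions, activation, duration=duration,
                                      apd=60.0, label="rotating-reentry")


def generate_fixtures(outdir) -> list[Path]:
    """Write the deterministic fixtures to ``outdir``; returns the paths.

    Outputs are bit-identical across runs (no randomness): the 2-node
    passive network with its dense-oracle trajectory (JSON), and activation
    CSVs of the two synthetic traces.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    net = two_node_network()
    v0 = np.array([-60.0, -80.0])
    t_eval = np.linspace(0.0, 5.0, 51)
    v_ref, ue_ref = dense_reference_solution(net, PassiveMembrane(), v0, t_eval)
    oracle_path = outdir / "two_node_passive_oracle.json"
    oracle_path.write_text(json.dumps({
        "description": "2-node passive network, dense DAE reference trajectory",
        "v0_mV": v0.tolist(),
        "t_ms": t_eval.tolist(),
        "v_mV": np.round(v_ref, 12).tolist(),
        "u_e_mV": np.round(ue_ref, 12).tolist(),
        "network": json.loads(net.to_json()),
    }, indent=1))
    written.append(oracle_path)

    for trace, name in (
        (planar_wave_trace(), "planar_wave_activations.csv"),
        (rotating_reentry_trace(), "rotating_reentry_activations.csv"),
    ):
        path = outdir / name
        trace.to_activation_csv(path)
        written.append(path)

    manifest = outdir / "manifest.json"
    manifest.write_text(json.dumps({
        "fixtures": [p.name for p in written],
        "deterministic": True,
        "note": "synthetic fixtures built from closed-form activation maps",
    }, indent=1))
    written.append(manifest)
    return written
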
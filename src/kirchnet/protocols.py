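"""Stimulus protocols, conduction-velocity measurement and experiment drivers.

Stimulus regions are defined by spatial intervals in um so that one protocol
definition applies to both the cell network (nodes at cell centers) and the
finite-difference bidomain grid (nodes at control-volume centers): a node is
stimulated when its center falls inside the region.  The standard S1
stimulus covers the leftmost column of cells; S2 covers the lower-left
quarter of the domain after a coupling interval.

Conduction velocity follows the two-point definition: distance between the
centers of two measurement cells divided by the difference of their first
upward crossings of a voltage threshold (default -20 mV, cells 3 and 13 on
the 15-cell strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Trace, simulate
from .geometry import Network

__all__ = [
    "StimulusEntry",
    "StimulusProtocol",
    "NoPropagationError",
    "s1_protocol",
    "s1_s2_protocol",
    "nearest_nodes",
    "conduction_velocity",
    "detect_reentry",
    "convergence_study",
    "cv_rg_sweep",
    "strand_cv",
    "reentry_experiment",
]

STIM_AMPLITUDE = 40.0  # uA/cm^2
STIM_DURATION = 2.0    # ms
CV_THRESHOLD = -20.0   # mV
S2_DELAY_SEARCH = (240.0, 220.0, 260.0, 200.0, 280.0)  # ms


class NoPropagationError(RuntimeError):
    """A measurement cell never crossed the activation threshold."""


@dataclass(frozen=True)
class StimulusEntry:
    """One stimulus: region given as x/y intervals (um), depolarizing amplitude."""

    x_range: tuple[float, float]
    y_range: tuple[float, float] | None
    amplitude: float = STIM_AMPLITUDE
    onset: float = 0.0
    duration: float = STIM_DURATION

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.x_range[1] <= self.x_range[0]:
            raise ValueError("empty stimulus x-interval")

    def mask(self, net: Network) -> np.ndarray:
        x, y = net.positions[:, 0], net.positions[:, 1]
        m = (x >= self.x_range[0]) & (x < self.x_range[1])
        if self.y_range is not None:
            m &= (y >= self.y_range[0]) & (y < self.y_range[1])
        if not m.any():
            raise ValueError("stimulus region contains no node")
        return m

    def active(self, t_mid: float) -> bool:
        return self.onset <= t_mid < self.onset + self.duration


@dataclass
class StimulusProtocol:
    """Sequence of stimuli; evaluates the per-node current density at a time."""

    entries: list[StimulusEntry] = field(default_factory=list)
    _masks: dict = field(default_factory=dict, repr=False)

    def current_density(self, t_mid: float, net: Network):
        total = None
        for i, entry in enumerate(self.entries):
            if entry.active(t_mid):
                key = (i, id(net))
                if key not in self._masks:
                    self._masks[key] = entry.mask(net)
                contrib = entry.amplitude * self._masks[key]
                total = contrib if total is None else total + contrib
        return 0.0 if total is None else total

    @property
    def last_offset(self) -> float:
        return max((e.onset + e.duration for e in self.entries), default=0.0)


def _domain_um(net: Network) -> tuple[float, float, float, float]:
    meta = net.meta
    lx = meta["cell_length_um"] * meta.get("n_x", 1) if meta.get("kind") == "knm" else None
    if "domain_um" in meta:
        dom = meta["domain_um"]
        return float(dom[0]), float(dom[1]), meta["cell_length_um"], meta["cell_width_um"]
    n_x, n_y = meta["n_x"], meta["n_y"]
    return (
        n_x * meta["cell_length_um"],
        n_y * meta["cell_width_um"],
        meta["cell_length_um"],
        meta["cell_width_um"],
    )


def s1_protocol(net: Network, *, amplitude: float = STIM_AMPLITUDE,
                duration: float = STIM_DURATION) -> StimulusProtocol:
    """S1: stimulate the leftmost cell (1D) / leftmost column of cells (2D).

    The region is x in [0, one cell length), all y, at t = 0.
    """
    _, _, cell_len, _ = _domain_um(net)
    return StimulusProtocol([
        StimulusEntry(x_range=(0.0, cell_len), y_range=None,
                      amplitude=amplitude, onset=0.0, duration=duration)
    ])


def s1_s2_protocol(net: Network, s2_delay: float = 240.0, *,
                   amplitude: float = STIM_AMPLITUDE,
                   duration: float = STIM_DURATION) -> StimulusProtocol:
    """S1 plus a premature S2 over the lower-left quarter after ``s2_delay`` ms.

    The quarter spans floor(n_x/2) cells in x and floor(n_y/2) cells in y
    (floor rounding for odd grids).  Requires a 2D domain.
    """
    if s2_delay < 0:
        raise ValueError("s2_delay must be nonnegative")
    meta = net.meta
    n_cells_y = int(round(_domain_um(net)[1] / meta["cell_width_um"]))
    if n_cells_y < 2:
        raise ValueError("S1-S2 protocol needs a 2D domain (the S2 quarter is undefined in 1D)")
    dom_x, dom_y, cell_len, cell_wid = _domain_um(net)
    n_cells_x = int(round(dom_x / cell_len))
    quarter_x = (n_cells_x // 2) * cell_len
    quarter_y = (n_cells_y // 2) * cell_wid
    proto = s1_protocol(net, amplitude=amplitude, duration=duration)
    proto.entries.append(
        StimulusEntry(x_range=(0.0, quarter_x), y_range=(0.0, quarter_y),
                      amplitude=amplitude, onset=s2_delay, duration=duration)
    )
    return proto


def nearest_nodes(net: Network, points_um) -> list[int]:
    """Indices of the nodes whose centers are nearest the given x positions (1D)
    or (x, y) points (um)."""
    out = []
    for p in points_um:
        p = np.atleast_1d(np.asarray(p, dtype=float))
        if p.size == 1:
            d = np.abs(net.positions[:, 0] - p[0])
        else:
            d = np.hypot(net.positions[:, 0] - p[0], net.positions[:, 1] - p[1])
        out.append(int(np.argmin(d)))
    return out


def conduction_velocity(
    trace: Trace,
    cell_a: int = 3,
    cell_b: int = 13,
    threshold: float | None = None,
    *,
    nodes: tuple[int, int] | None = None,
    interpolate: bool = False,
) -> float:
    """Conduction velocity in cm/s between two measurement cells.

    ``cell_a``/``cell_b`` are 1-based cell numbers along the strand (defaults
    3 and 13); ``nodes`` overrides them with explicit 0-based node indices
    (used for finite-difference grids).  The first upward crossing of the
    threshold at each node defines the activation time; ``interpolate``
    selects linear sub-step interpolation of the crossing instant.
    """
    if threshold is not None and threshold != trace.threshold:
        raise ValueError(
            f"trace was recorded with threshold {trace.threshold} mV; "
            f"re-run the simulation to measure at {threshold} mV"
        )
    ia, ib = nodes if nodes is not None else (cell_a - 1, cell_b - 1)
    t_a = trace.first_activation(ia, interpolate=interpolate)
    t_b = trace.first_activation(ib, interpolate=interpolate)
    if t_a is None or t_b is None:
        missing = [n for n, t in ((ia, t_a), (ib, t_b)) if t is None]
        raise NoPropagationError(
            f"no threshold crossing at node(s) {missing}: wavefront did not reach "
            "the measurement point (propagation failure or block)"
        )
    dist_cm = float(np.linalg.norm(trace.positions[ib] - trace.positions[ia])) * 1e-4
    dt_ms = t_b - t_a
    if dt_ms <= 0:
        raise NoPropagationError(
            f"non-positive activation-time difference ({dt_ms} ms) between nodes {ia} and {ib}"
        )
    return dist_cm / (dt_ms * 1e-3)


def detect_reentry(
    trace: Trace,
    t_s2: float,
    *,
    guard: float = 50.0,
    window: float = 300.0,
    ignore_nodes: np.ndarray | None = None,
) -> tuple[bool, dict]:
    """Reentry flag plus evidence from re-activation counts and persistence.

    Reentrant iff (a) at least one node activates at least twice after
    t_s2 + guard (re-excitation beyond the S2 capture itself) and (b)
    suprathreshold activity persists beyond t_s2 + window.  Both windows
    are configurable; the trace must extend past t_s2 + window.
    """
    if trace.duration < t_s2 + window:
        raise ValueError(
            f"trace ends at {trace.duration} ms, before the persistence window "
            f"{t_s2 + window} ms"
        )
    counts = np.array([
        trace.activation_count(node, after=t_s2 + guard) for node in range(trace.n_nodes)
    ])
    if ignore_nodes is not None:
        counts[np.asarray(ignore_nodes, dtype=int)] = 0
    last_activity = float(trace.last_above.max())
    reactivated = counts >= 2
    reentrant = bool(reactivated.any() and last_activity > t_s2 + window)
    evidence = {
        "n_reactivated_nodes": int(reactivated.sum()),
        "max_reactivations": int(counts.max(initial=0)),
        "last_activity_ms": last_activity,
        "persists_past_ms": t_s2 + window,
    }
    return reentrant, evidence


# ---------------------------------------------------------------------------
# experiment drivers


def _strand_trace(
    n_cells: int,
    dt: float,
    rg_multiplier: float,
    *,
    model_kind: str = "knm",
    geom=None,
    params=None,
    membrane=None,
    dx: float | None = None,
    duration: float = 400.0,
    solver: str = "direct",
) -> Trace:
    from .bidomain import build_fd_network
    from .geometry import CellGeometry, TissueParams, build_grid_network
    from .membrane import get_model

    geom = geom or CellGeometry()
    params = params or TissueParams()
    membrane = membrane or get_model("mitchell-schaeffer")
    if model_kind == "knm":
        net = build_grid_network(n_cells, 1, geom, params, rg_multiplier=rg_multiplier)
    elif model_kind == "bd":
        net = build_fd_network(n_cells, 1, geom, params, dx=dx, rg_multiplier=rg_multiplier)
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")
    proto = s1_protocol(net)
    return simulate(
        net, membrane, proto, dt=dt, duration=duration,
        stop_after_all_activated=1.0, snapshot_every=5.0, solver=solver,
        config={"model": model_kind, "n_cells": n_cells, "dt": dt,
                "rg_multiplier": rg_multiplier, "dx_um": dx},
    )


def strand_cv(
    dt: float,
    rg_multiplier: float = 1.0,
    *,
    n_cells: int = 15,
    cell_a: int = 3,
    cell_b: int = 13,
    model_kind: str = "knm",
    dx: float | None = None,
    duration: float = 400.0,
    interpolate: bool = True,
    geom=None,
    params=None,
    membrane=None,
) -> float:
    """CV (cm/s) on a 1D strand between the centers of two measurement cells.

    Defaults to the reference protocol: 15 cells, measurement between cells
    3 and 13 (1-based).  For the finite-difference continuum the measurement
    points are the grid nodes nearest those cell centers.
    """
    from .geometry import CellGeometry

    geom = geom or CellGeometry()
    trace = _strand_trace(
        n_cells, dt, rg_multiplier, model_kind=model_kind, geom=geom,
        params=params, membrane=membrane, dx=dx, duration=duration,
    )
    if model_kind == "bd":
        net_positions = trace.positions
        xa, xb = (cell_a - 0.5) * geom.length, (cell_b - 0.5) * geom.length
        ia = int(np.argmin(np.abs(net_positions[:, 0] - xa)))
        ib = int(np.argmin(np.abs(net_positions[:, 0] - xb)))
        return conduction_velocity(trace, nodes=(ia, ib), interpolate=interpolate)
    return conduction_velocity(trace, cell_a, cell_b, interpolate=interpolate)


def convergence_study(
    dts,
    rg_multipliers=(1.0, 50.0, 500.0),
    *,
    n_cells: int = 15,
    cell_a: int = 3,
    cell_b: int = 13,
    model_kind: str = "knm",
    dx: float | None = None,
    duration: float = 400.0,
    geom=None,
    params=None,
    membrane=None,
) -> pd.DataFrame:
    """Temporal-convergence table: CV and percent difference to the finest dt.

    For each gap-junction multiplier, the CV at every dt is compared with the
    CV at the smallest dt in ``dts``; propagation failure is recorded as
    status "block" rather than raised.
    """
    dts = sorted(set(float(d) for d in dts), reverse=True)
    finest = dts[-1]
    rows = []
    for mult in rg_multipliers:
        cvs = {}
        for dt in dts:
            try:
                cvs[dt] = strand_cv(
                    dt, mult, n_cells=n_cells, cell_a=cell_a, cell_b=cell_b,
                    model_kind=model_kind, dx=dx, duration=duration, geom=geom,
                    params=params, membrane=membrane,
                )
                status = "ok"
            except NoPropagationError:
                cvs[dt] = np.nan
                status = "block"
            rows.append({"rg_multiplier": mult, "dt_ms": dt, "cv_cm_s": cvs[dt],
                         "status": status})
        cv_ref = cvs[finest]
        for row in rows:
            if row["rg_multiplier"] == mult:
                cv = row["cv_cm_s"]
                row["pct_diff_to_finest"] = (
                    abs(cv - cv_ref) / cv_ref * 100.0
                    if np.isfinite(cv) and np.isfinite(cv_ref) and cv_ref > 0
                    else np.nan
                )
    return pd.DataFrame(rows)


def cv_rg_sweep(
    multipliers=(1.0, 10.0, 50.0, 100.0, 500.0),
    *,
    dt: float = 0.01,
    n_cells: int = 15,
    cell_a: int = 3,
    cell_b: int = 13,
    model_kinds=("knm", "bd"),
    dx: float | None = None,
    duration: float = 400.0,
    geom=None,
    params=None,
    membrane=None,
) -> pd.DataFrame:
    """CV versus gap-junction resistance multiplier for one or both models."""
    rows = []
    for kind in model_kinds:
        for mult in multipliers:
            try:
                cv = strand_cv(dt, mult, n_cells=n_cells, cell_a=cell_a,
                               cell_b=cell_b, model_kind=kind, dx=dx,
                               duration=duration, geom=geom, params=params,
                               membrane=membrane)
                status = "ok"
            except NoPropagationError:
                cv, status = np.nan, "block"
            rows.append({"model": kind, "rg_multiplier": mult, "cv_cm_s": cv,
                         "status": status})
    return pd.DataFrame(rows)


def reentry_experiment(
    model_kind: str = "knm",
    *,
    n_x: int = 20,
    n_y: int = 20,
    rg_multiplier: float = 500.0,
    s2_delay: float = 240.0,
    dt: float = 0.01,
    duration: float = 600.0,
    dx: float | None = None,
    dy: float | None = None,
    guard: float = 50.0,
    window: float = 300.0,
    geom=None,
    params=None,
    membrane=None,
) -> tuple[bool, dict, Trace]:
    """Run the S1-S2 protocol on the 2D domain and test for reentry."""
    from .bidomain import build_fd_network
    from .geometry import CellGeometry, TissueParams, build_grid_network
    from .membrane import get_model

    geom = geom or CellGeometry()
    params = params or TissueParams()
    membrane = membrane or get_model("mitchell-schaeffer")
    if model_kind == "knm":
        net = build_grid_network(n_x, n_y, geom, params, rg_multiplier=rg_multiplier)
    elif model_kind == "bd":
        net = build_fd_network(n_x, n_y, geom, params, dx=dx, dy=dy,
                               rg_multiplier=rg_multiplier)
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")
    proto = s1_s2_protocol(net, s2_delay)
    trace = simulate(
        net, membrane, proto, dt=dt, duration=duration, snapshot_every=5.0,
        config={"model": model_kind, "n_x": n_x, "n_y": n_y,
                "rg_multiplier": rg_multiplier, "s2_delay": s2_delay, "dt": dt},
    )
    reentrant, evidence = detect_reentry(trace, proto.entries[-1].onset,
                                         guard=guard, window=window)
    return reentrant, evidence, trace
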
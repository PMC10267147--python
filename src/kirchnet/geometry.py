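"""Cell geometry and network construction for the Kirchhoff network model.

A cardiac myocyte is idealized as a solid of revolution: two conical frusta
joined at the cell center, with radius varying linearly from ``end_radius``
at the intercalated discs to ``center_radius`` at mid-cell.  Each cell sits
in a rectangular tissue compartment of size ``length x l_y x l_z`` that also
contains its share of extracellular space.  Cells are coupled to their
lattice neighbors by an intracellular conductance that puts the bulk
cytoplasmic resistance in series with the gap-junction resistance of the
intercalated disc, and extracellular compartments are coupled by a bulk
extracellular conductance.

Units follow cardiac-electrophysiology convention: lengths are entered in
micrometres, conductivities in mS/cm, the gap-junction resistance density in
kOhm*cm^2, capacitance in uF/cm^2.  All derived areas/volumes/conductances
are returned in cm^2 / cm^3 / mS so that currents come out in uA when
potentials are in mV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp

__all__ = [
    "CellGeometry",
    "TissueParams",
    "Network",
    "volume_fractions",
    "membrane_area",
    "disc_area",
    "extracellular_conductance",
    "intracellular_conductance",
    "build_grid_network",
]

UM_TO_CM = 1e-4
UM2_TO_CM2 = 1e-8
UM3_TO_CM3 = 1e-12


@dataclass(frozen=True)
class CellGeometry:
    """Physical dimensions of one myocyte and its tissue compartment (um).

    ``l_y``/``l_z`` default to the tightest compartment consistent with the
    cell radius and the extracellular margin, ``2 * (center_radius + margin)``.
    """

    length: float = 120.0
    end_radius: float = 6.0
    center_radius: float = 7.0
    margin: float = 2.0
    l_y: float = None  # type: ignore[assignment]
    l_z: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        default_side = 2.0 * (self.center_radius + self.margin)
        if self.l_y is None:
            object.__setattr__(self, "l_y", default_side)
        if self.l_z is None:
            object.__setattr__(self, "l_z", default_side)
        for name in ("length", "end_radius", "center_radius", "margin", "l_y", "l_z"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise ValueError(f"CellGeometry.{name} must be strictly positive, got {value!r}")
        if self.end_radius > self.center_radius:
            raise ValueError(
                f"end_radius ({self.end_radius}) must not exceed center_radius ({self.center_radius})"
            )
        min_side = 2.0 * (self.center_radius + self.margin)
        if self.l_y < min_side or self.l_z < min_side:
            raise ValueError(
                "compartment cross-section too small: need l_y, l_z >= "
                f"2*(center_radius + margin) = {min_side} um"
            )

    @property
    def compartment_volume_um3(self) -> float:
        return self.length * self.l_y * self.l_z

    @property
    def cross_section_x_um2(self) -> float:
        """Compartment cross-section normal to the fiber axis."""
        return self.l_y * self.l_z

    @property
    def cross_section_y_um2(self) -> float:
        """Compartment cross-section normal to the transverse (y) axis."""
        return self.length * self.l_z


@dataclass(frozen=True)
class TissueParams:
    """Electrical tissue parameters.

    sigma_i/sigma_e: intracellular/extracellular conductivity (mS/cm);
    c_m: specific membrane capacitance (uF/cm^2);
    r_g: gap-junction resistance density (kOhm*cm^2) of the intercalated
    disc, with ``rg_multiplier`` as a global scale used to model impaired
    cell-to-cell coupling (e.g. fibrosis).
    """

    sigma_i: float = 4.0
    sigma_e: float = 20.0
    c_m: float = 1.0
    r_g: float = 0.0015
    rg_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma_i", "sigma_e", "c_m", "r_g", "rg_multiplier"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise ValueError(f"TissueParams.{name} must be strictly positive, got {value!r}")


def volume_fractions(geom: CellGeometry) -> tuple[float, float]:
    """Intracellular and extracellular volume fractions (delta_i, delta_e).

    The cell volume is that of two conical frusta of half-length each, radius
    running linearly from ``end_radius`` to ``center_radius``; the compartment
    volume is the full box.  For a frustum of height h and radii r1, r2 the
    volume is pi*h*(r1^2 + r1*r2 + r2^2)/3.
    """
    h = geom.length / 2.0
    r1, r2 = geom.end_radius, geom.center_radius
    v_cell = 2.0 * np.pi * h * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0
    delta_i = v_cell / geom.compartment_volume_um3
    if not 0.0 < delta_i < 1.0:
        raise ValueError(f"cell does not fit in compartment (delta_i = {delta_i:.4f})")
    return float(delta_i), float(1.0 - delta_i)


def membrane_area(geom: CellGeometry) -> float:
    """Lateral membrane area of the double-frustum cell, in cm^2.

    End caps are excluded: the cell ends are intercalated discs, which carry
    gap-junction current rather than ionic membrane current.  Lateral area of
    one frustum is pi*(r1+r2)*slant with slant = sqrt(h^2 + (r2-r1)^2).
    """
    h = geom.length / 2.0
    r1, r2 = geom.end_radius, geom.center_radius
    slant = np.hypot(h, r2 - r1)
    area_um2 = 2.0 * np.pi * (r1 + r2) * slant
    return float(area_um2 * UM2_TO_CM2)


def disc_area(geom: CellGeometry) -> float:
    """Intercalated-disc area pi*end_radius^2 for longitudinal contacts, cm^2."""
    return float(np.pi * geom.end_radius**2 * UM2_TO_CM2)


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0.0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


def extracellular_conductance(delta_e: float, area_cm2: float, sigma_e: float, l_cm: float) -> float:
    """Bulk extracellular conductance G_e = delta_e * A * sigma_e / l (mS).

    ``area_cm2`` is the full compartment cross-section between the two
    nodes and ``l_cm`` the distance between their centers.
    """
    _check_positive(delta_e=delta_e, area_cm2=area_cm2, sigma_e=sigma_e, l_cm=l_cm)
    return delta_e * area_cm2 * sigma_e / l_cm


def intracellular_conductance(
    delta_i: float,
    area_cm2: float,
    sigma_i: float,
    l_cm: float,
    r_g: float,
    a_g_cm2: float,
) -> float:
    """Intracellular conductance between two coupled cells (mS).

    Bulk cytoplasmic resistance over one cell spacing in series with the
    gap-junction resistance of the disc:

        G_i = 1 / ( l / (delta_i * A * sigma_i)  +  R_g / A_g )

    With R_g in kOhm*cm^2 and A_g in cm^2, R_g/A_g is in kOhm = 1/mS, the
    same unit as the bulk term, so the sum may be inverted directly.
    """
    _check_positive(
        delta_i=delta_i, area_cm2=area_cm2, sigma_i=sigma_i, l_cm=l_cm, r_g=r_g, a_g_cm2=a_g_cm2
    )
    r_bulk = l_cm / (delta_i * area_cm2 * sigma_i)  # kOhm
    r_gap = r_g / a_g_cm2  # kOhm
    return 1.0 / (r_bulk + r_gap)


@dataclass
class Network:
    """Graph of cell/compartment nodes with per-edge conductances.

    positions: (N, 2) node centers in um; edges: (E, 2) int node pairs
    (each undirected edge stored once, j < k); g_i/g_e: per-edge
    conductances in mS; a_m: per-node membrane area in cm^2; dirichlet:
    per-node flags marking grounded extracellular compartments (u_e = 0).
    """

    positions: np.ndarray
    edges: np.ndarray
    g_i: np.ndarray
    g_e: np.ndarray
    a_m: np.ndarray
    dirichlet: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.g_i = np.asarray(self.g_i, dtype=float)
        self.g_e = np.asarray(self.g_e, dtype=float)
        self.a_m = np.asarray(self.a_m, dtype=float)
        self.dirichlet = np.asarray(self.dirichlet, dtype=bool)
        n, e = self.n_nodes, self.n_edges
        if self.positions.shape != (n, 2):
            raise ValueError("positions must be (N, 2)")
        if self.g_i.shape != (e,) or self.g_e.shape != (e,):
            raise ValueError("per-edge conductance arrays must match edge count")
        if self.dirichlet.shape != (n,):
            raise ValueError("dirichlet flags must match node count")
        if e:
            if self.edges.min() < 0 or self.edges.max() >= n:
                raise ValueError("edge endpoint out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-loop edge")
        if np.any(self.g_i <= 0) or np.any(self.g_e <= 0):
            raise ValueError("all conductances must be strictly positive")
        if np.any(self.a_m <= 0):
            raise ValueError("membrane areas must be strictly positive")

    @property
    def n_nodes(self) -> int:
        return int(self.a_m.shape[0])

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def laplacian(self, weights: np.ndarray) -> sp.csr_matrix:
        """Weighted graph Laplacian L with (L x)_k = sum_j w_jk (x_k - x_j)."""
        n, e = self.n_nodes, self.n_edges
        if e == 0:
            return sp.csr_matrix((n, n))
        j, k = self.edges[:, 0], self.edges[:, 1]
        rows = np.concatenate([j, k, j, k])
        cols = np.concatenate([j, k, k, j])
        data = np.concatenate([weights, weights, -weights, -weights])
        return sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()

    def neighbors(self, node: int) -> np.ndarray:
        mask0 = self.edges[:, 0] == node
        mask1 = self.edges[:, 1] == node
        return np.concatenate([self.edges[mask1, 0], self.edges[mask0, 1]])

    def to_json(self) -> str:
        payload = {
            "positions_um": self.positions.tolist(),
            "edges": self.edges.tolist(),
            "g_i_mS": self.g_i.tolist(),
            "g_e_mS": self.g_e.tolist(),
            "a_m_cm2": self.a_m.tolist(),
            "dirichlet": self.dirichlet.astype(int).tolist(),
            "meta": {k: v for k, v in self.meta.items() if _json_safe(v)},
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Network":
        d = json.loads(text)
        return cls(
            positions=np.array(d["positions_um"], dtype=float),
            edges=np.array(d["edges"], dtype=np.int64).reshape(-1, 2),
            g_i=np.array(d["g_i_mS"], dtype=float),
            g_e=np.array(d["g_e_mS"], dtype=float),
            a_m=np.array(d["a_m_cm2"], dtype=float),
            dirichlet=np.array(d["dirichlet"], dtype=bool),
            meta=d.get("meta", {}),
        )


def _json_safe(value) -> bool:
    try:
        json.dumps(value)
        return True
    except TypeError:
        return False


def build_grid_network(
    n_x: int,
    n_y: int = 1,
    geom: CellGeometry | None = None,
    params: TissueParams | None = None,
    *,
    rg_multiplier: float | None = None,
    transverse_disc_area: float | None = None,
    rg_edge_multipliers: Mapping[tuple[int, int], float] | None = None,
) -> Network:
    """Build a rectangular n_x x n_y lattice of coupled cell compartments.

    Longitudinal (x) edges use the compartment cross-section l_y*l_z and
    spacing l_x; transverse (y) edges use l_x*l_z and spacing l_y.  The disc
    area for transverse contacts defaults to the longitudinal disc area
    (``transverse_disc_area`` overrides it).  ``rg_edge_multipliers`` maps an
    (ordered-low, high) 0-based node pair to an extra per-edge R_g factor for
    heterogeneous coupling.  Extracellular Dirichlet (grounded) compartments
    are the two strand ends in 1D and the whole perimeter in 2D.
    """
    if n_x < 1 or n_y < 1:
        raise ValueError("grid must contain at least one cell in each direction")
    geom = geom or CellGeometry()
    params = params or TissueParams()
    mult = params.rg_multiplier if rg_multiplier is None else float(rg_multiplier)
    if mult <= 0:
        raise ValueError("rg_multiplier must be strictly positive")

    delta_i, delta_e = volume_fractions(geom)
    a_m = membrane_area(geom)
    a_g_x = disc_area(geom)
    a_g_y = a_g_x if transverse_disc_area is None else float(transverse_disc_area)
    if a_g_y <= 0:
        raise ValueError("transverse disc area must be strictly positive")

    n = n_x * n_y
    ix, iy = np.meshgrid(np.arange(n_x), np.arange(n_y), indexing="xy")
    ix, iy = ix.ravel(), iy.ravel()  # node index = iy * n_x + ix
    positions = np.column_stack([(ix + 0.5) * geom.length, (iy + 0.5) * geom.l_y])

    edges, g_i, g_e = [], [], []
    overrides = dict(rg_edge_multipliers or {})

    def add_edge(j: int, k: int, area_um2: float, l_um: float, a_g: float) -> None:
        key = (min(j, k), max(j, k))
        edge_mult = mult * overrides.get(key, 1.0)
        area = area_um2 * UM2_TO_CM2
        l_cm = l_um * UM_TO_CM
        edges.append(key)
        g_i.append(
            intracellular_conductance(delta_i, area, params.sigma_i, l_cm, params.r_g * edge_mult, a_g)
        )
        g_e.append(extracellular_conductance(delta_e, area, params.sigma_e, l_cm))

    for node in range(n):
        cx, cy = node % n_x, node // n_x
        if cx + 1 < n_x:
            add_edge(node, node + 1, geom.cross_section_x_um2, geom.length, a_g_x)
        if cy + 1 < n_y:
            add_edge(node, node + n_x, geom.cross_section_y_um2, geom.l_y, a_g_y)

    if n_y == 1:
        dirichlet = (ix == 0) | (ix == n_x - 1)
    else:
        dirichlet = (ix == 0) | (ix == n_x - 1) | (iy == 0) | (iy == n_y - 1)

    return Network(
        positions=positions,
        edges=np.array(edges, dtype=np.int64).reshape(-1, 2),
        g_i=np.array(g_i),
        g_e=np.array(g_e),
        a_m=np.full(n, a_m),
        dirichlet=dirichlet,
        meta={
            "kind": "knm",
            "n_x": n_x,
            "n_y": n_y,
            "cell_length_um": geom.length,
            "cell_width_um": geom.l_y,
            "delta_i": delta_i,
            "delta_e": delta_e,
            "rg_multiplier": mult,
        },
    )
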
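"""Homogenized bidomain reference solver on 1D/2D finite-difference grids.

The bidomain equations

    C_m dv/dt = chi^-1 ( div(M_i grad v) + div(M_i grad u_e) ) - I_ion(s, v)
    0         = div(M_i grad v) + div((M_i + M_e) grad u_e)

are discretized in flux form on a cell-centered lattice with spacing
(dx, dy): every control volume becomes a node with membrane area
chi * volume, and every face becomes an edge with conductance
M * face_area / spacing.  The result is a :class:`~kirchnet.geometry.Network`
integrated by the same splitting/backward-Euler core as the cell network,
so with dx equal to the cell length the two assembled operators coincide —
the discrete-bidomain reading of the cell network.

Homogenized parameters are fixed by consistency with the cell network: the
resistance of one cell length of homogenized intracellular medium must equal
the cell-network edge resistance 1/G_i.  That yields

    chi  = A_m / (l_x l_y l_z)
    M_e  = delta_e * sigma_e                          (each direction)
    M_i  = delta_i / (1/sigma_i + R_g delta_i A / (A_g l))

with A the compartment cross-section and l the spacing in the relevant
direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    UM_TO_CM,
    UM2_TO_CM2,
    UM3_TO_CM3,
    CellGeometry,
    Network,
    TissueParams,
    disc_area,
    membrane_area,
    volume_fractions,
)

__all__ = ["BidomainParams", "homogenize", "build_fd_network", "bd_simulate"]


@dataclass(frozen=True)
class BidomainParams:
    """Homogenized tissue parameters: chi (cm^-1), diagonal M_i/M_e (mS/cm)."""

    chi: float
    m_i_x: float
    m_i_y: float
    m_e_x: float
    m_e_y: float
    c_m: float

    def __post_init__(self) -> None:
        for name in ("chi", "m_i_x", "m_i_y", "m_e_x", "m_e_y", "c_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"BidomainParams.{name} must be strictly positive")


def _m_i(delta_i: float, sigma_i: float, r_g: float, area_cm2: float, a_g: float, l_cm: float) -> float:
    return delta_i / (1.0 / sigma_i + r_g * delta_i * area_cm2 / (a_g * l_cm))


def homogenize(
    geom: CellGeometry,
    params: TissueParams,
    *,
    rg_multiplier: float | None = None,
    transverse_disc_area: float | None = None,
) -> BidomainParams:
    """Derive bidomain parameters from cell geometry and tissue parameters."""
    delta_i, delta_e = volume_fractions(geom)
    a_m = membrane_area(geom)
    a_g = disc_area(geom)
    a_g_y = a_g if transverse_disc_area is None else float(transverse_disc_area)
    mult = params.rg_multiplier if rg_multiplier is None else float(rg_multiplier)
    r_g = params.r_g * mult
    chi = a_m / (geom.compartment_volume_um3 * UM3_TO_CM3)
    m_i_x = _m_i(delta_i, params.sigma_i, r_g, geom.cross_section_x_um2 * UM2_TO_CM2,
                 a_g, geom.length * UM_TO_CM)
    m_i_y = _m_i(delta_i, params.sigma_i, r_g, geom.cross_section_y_um2 * UM2_TO_CM2,
                 a_g_y, geom.l_y * UM_TO_CM)
    m_e = delta_e * params.sigma_e
    return BidomainParams(chi=chi, m_i_x=m_i_x, m_i_y=m_i_y, m_e_x=m_e, m_e_y=m_e,
                          c_m=params.c_m)


def build_fd_network(
    n_x: int,
    n_y: int = 1,
    geom: CellGeometry | None = None,
    params: TissueParams | None = None,
    *,
    dx: float | None = None,
    dy: float | None = None,
    rg_multiplier: float | None = None,
    transverse_disc_area: float | None = None,
) -> Network:
    """Cell-centered finite-difference bidomain grid as a Network.

    The domain spans ``n_x`` cell lengths by ``n_y`` cell widths; ``dx`` and
    ``dy`` (um, defaults: the cell length / width, i.e. the coarsest mesh)
    must divide the domain evenly.  Grounded (Dirichlet u_e) control volumes
    are the two strand ends in 1D and the whole perimeter in 2D, matching
    the cell-network boundary treatment; zero-flux (Neumann) conditions on
    the intracellular potential are natural in flux form.
    """
    if n_x < 1 or n_y < 1:
        raise ValueError("domain must span at least one cell in each direction")
    geom = geom or CellGeometry()
    params = params or TissueParams()
    dx = geom.length if dx is None else float(dx)
    dy = geom.l_y if dy is None else float(dy)
    lx_dom, ly_dom = n_x * geom.length, n_y * geom.l_y
    mx, my = lx_dom / dx, ly_dom / dy
    if abs(mx - round(mx)) > 1e-9 or abs(my - round(my)) > 1e-9:
        raise ValueError("dx/dy must divide the domain size evenly")
    mx, my = int(round(mx)), int(round(my))
    if n_y == 1:
        my = 1  # 1D strand: no transverse discretization
        dy = geom.l_y

    bd = homogenize(geom, params, rg_multiplier=rg_multiplier,
                    transverse_disc_area=transverse_disc_area)
    dz_cm = geom.l_z * UM_TO_CM
    dx_cm, dy_cm = dx * UM_TO_CM, dy * UM_TO_CM
    vol_cm3 = dx_cm * dy_cm * dz_cm
    a_m_node = bd.chi * vol_cm3
    g_i_x = bd.m_i_x * (dy_cm * dz_cm) / dx_cm
    g_e_x = bd.m_e_x * (dy_cm * dz_cm) / dx_cm
    g_i_y = bd.m_i_y * (dx_cm * dz_cm) / dy_cm
    g_e_y = bd.m_e_y * (dx_cm * dz_cm) / dy_cm

    n = mx * my
    ix, iy = np.meshgrid(np.arange(mx), np.arange(my), indexing="xy")
    ix, iy = ix.ravel(), iy.ravel()
    positions = np.column_stack([(ix + 0.5) * dx, (iy + 0.5) * dy])

    edges, g_i, g_e = [], [], []
    for node in range(n):
        cx, cy = node % mx, node // mx
        if cx + 1 < mx:
            edges.append((node, node + 1))
            g_i.append(g_i_x)
            g_e.append(g_e_x)
        if cy + 1 < my:
            edges.append((node, node + mx))
            g_i.append(g_i_y)
            g_e.append(g_e_y)

    if my == 1:
        dirichlet = (ix == 0) | (ix == mx - 1)
    else:
        dirichlet = (ix == 0) | (ix == mx - 1) | (iy == 0) | (iy == my - 1)

    return Network(
        positions=positions,
        edges=np.array(edges, dtype=np.int64).reshape(-1, 2),
        g_i=np.array(g_i),
        g_e=np.array(g_e),
        a_m=np.full(n, a_m_node),
        dirichlet=dirichlet,
        meta={
            "kind": "bd",
            "n_x": mx,
            "n_y": my,
            "dx_um": dx,
            "dy_um": dy,
            "cell_length_um": geom.length,
            "cell_width_um": geom.l_y,
            "domain_um": (lx_dom, ly_dom),
            "chi_cm^-1": bd.chi,
            "m_i_x": bd.m_i_x,
            "m_i_y": bd.m_i_y,
            "m_e": bd.m_e_x,
            "rg_multiplier": params.rg_multiplier if rg_multiplier is None else rg_multiplier,
        },
    )


def bd_simulate(net: Network, model, protocol=None, **kwargs):
    """Run the bidomain finite-difference scheme (thin wrapper over the core)."""
    from .core import simulate

    return simulate(net, model, protocol, **kwargs)
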
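"""Geometry, areas, volume fractions and conductance construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from kirchnet import (
    CellGeometry,
    Network,
    TissueParams,
    build_grid_network,
    disc_area,
    extracellular_conductance,
    intracellular_conductance,
    membrane_area,
    volume_fractions,
)

UM2_TO_CM2 = 1e-8


def radius_profile(geom):
    """Linear radius along the cell axis: end -> center -> end."""
    h = geom.length / 2.0

    def r(x):
        d = abs(x - h)
        return geom.center_radius + (geom.end_radius - geom.center_radius) * d / h

    return r


class TestVolumeFractions:
    def test_default_geometry_matches_quadrature_oracle(self, geom):
        r = radius_profile(geom)
        v_cell, _ = quad(lambda x: np.pi * r(x) ** 2, 0, geom.length, points=[geom.length / 2])
        expected = v_cell / (geom.length * geom.l_y * geom.l_z)
        di, de = volume_fractions(geom)
        assert di == pytest.approx(expected, rel=1e-10)
        # frozen value from the quadrature oracle for the default cell
        assert di == pytest.approx(0.4104755833394071, rel=1e-12)
        assert de == pytest.approx(1.0 - di, abs=1e-15)

    def test_cylinder_degenerate_case(self):
        g = CellGeometry(length=100.0, end_radius=5.0, center_radius=5.0, margin=2.0)
        di, _ = volume_fractions(g)
        assert di == pytest.approx(np.pi * 25.0 / (g.l_y * g.l_z), rel=1e-12)

    @given(
        end_r=st.floats(1.0, 7.0),
        extra=st.floats(0.0, 3.0),
        length=st.floats(50.0, 200.0),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_complementarity_and_bounds(self, end_r, extra, length):
        g = CellGeometry(length=length, end_radius=end_r, center_radius=end_r + extra)
        di, de = volume_fractions(g)
        assert 0 < di < 1
        assert di + de == pytest.approx(1.0, abs=1e-14)


class TestMembraneArea:
    def test_cylinder_lateral_surface(self):
        g = CellGeometry(length=100.0, end_radius=5.0, center_radius=5.0)
        assert membrane_area(g) == pytest.approx(2 * np.pi * 5.0 * 100.0 * UM2_TO_CM2, rel=1e-12)

    def test_default_matches_surface_of_revolution_quadrature(self, geom):
        r = radius_profile(geom)
        slope = (geom.center_radius - geom.end_radius) / (geom.length / 2.0)
        area_um2, _ = quad(
            lambda x: 2 * np.pi * r(x) * np.hypot(1.0, slope),
            0,
            geom.length,
            points=[geom.length / 2],
        )
        assert membrane_area(geom) == pytest.approx(area_um2 * UM2_TO_CM2, rel=1e-9)
        # closed form: 2 * pi * (6+7) * sqrt(60^2 + 1)
        assert membrane_area(geom) == pytest.approx(
            2 * np.pi * 13.0 * np.hypot(60.0, 1.0) * UM2_TO_CM2, rel=1e-12
        )

    def test_doubling_dimensions_quadruples_area(self, geom):
        doubled = CellGeometry(
            length=2 * geom.length,
            end_radius=2 * geom.end_radius,
            center_radius=2 * geom.center_radius,
            margin=2 * geom.margin,
        )
        assert membrane_area(doubled) == pytest.approx(4 * membrane_area(geom), rel=1e-12)


class TestDiscArea:
    def test_default_value(self, geom):
        assert disc_area(geom) == pytest.approx(np.pi * 36.0 * UM2_TO_CM2, rel=1e-12)

    def test_independent_of_center_radius(self, geom):
        fatter = CellGeometry(end_radius=6.0, center_radius=8.5)
        assert disc_area(fatter) == disc_area(geom)

    def test_degenerate_disc_rejected(self):
        with pytest.raises(ValueError):
            CellGeometry(end_radius=0.0)


class TestGeometryValidation:
    @pytest.mark.parametrize("kwargs", [
        {"length": -1.0},
        {"end_radius": 8.0, "center_radius": 7.0},
        {"l_y": 10.0},  # cell of radius 7 + margin 2 does not fit
        {"margin": 0.0},
    ])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CellGeometry(**kwargs)

    def test_tissue_params_positive(self):
        with pytest.raises(ValueError):
            TissueParams(sigma_i=0.0)


class TestConductances:
    def test_extracellular_hand_value(self):
        # delta_e=0.5, A = 18x18 um^2, sigma_e=20 mS/cm, l = 120 um
        g_e = extracellular_conductance(0.5, 3.24e-6, 20.0, 0.012)
        assert g_e == pytest.approx(2.7e-3, rel=1e-12)

    def test_unit_identity(self):
        assert extracellular_conductance(1.0, 2.0, 1.0, 2.0) == pytest.approx(1.0)

    def test_linear_in_sigma(self):
        a = extracellular_conductance(0.6, 3.24e-6, 10.0, 0.012)
        b = extracellular_conductance(0.6, 3.24e-6, 20.0, 0.012)
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_series_resistance_oracle(self):
        """The intracellular formula equals 1/(R1+R2) for the two resistances."""
        delta_i, area, sigma, l_cm = 0.41, 3.24e-6, 4.0, 0.012
        r_g, a_g = 0.0015, 1.131e-6
        r1 = l_cm / (delta_i * area * sigma)
        r2 = r_g / a_g
        assert intracellular_conductance(delta_i, area, sigma, l_cm, r_g, a_g) == pytest.approx(
            1.0 / (r1 + r2), rel=1e-14
        )

    def test_default_parameter_value(self, geom, params):
        """Frozen hand evaluation of the series formula at default parameters."""
        di, _ = volume_fractions(geom)
        g_i = intracellular_conductance(
            di, 3.24e-6, params.sigma_i, 0.012, params.r_g, disc_area(geom)
        )
        assert g_i == pytest.approx(2.7917126554e-4, rel=1e-9)

    def test_rg_limits(self):
        base = dict(delta_i=0.4, area_cm2=3.24e-6, sigma_i=4.0, l_cm=0.012, a_g_cm2=1.13e-6)
        bulk = base["delta_i"] * base["area_cm2"] * base["sigma_i"] / base["l_cm"]
        nearly_zero = intracellular_conductance(r_g=1e-12, **base)
        assert nearly_zero == pytest.approx(bulk, rel=1e-6)
        assert intracellular_conductance(r_g=1e9, **base) < 1e-12

    @given(
        rg=st.floats(1e-4, 1.0),
        factor=st.floats(1.01, 10.0),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_decreasing_in_rg(self, rg, factor):
        args = dict(delta_i=0.4, area_cm2=3.24e-6, sigma_i=4.0, l_cm=0.012, a_g_cm2=1.13e-6)
        assert intracellular_conductance(r_g=rg * factor, **args) < intracellular_conductance(
            r_g=rg, **args
        )

    @pytest.mark.parametrize("name", ["delta_i", "area_cm2", "sigma_i"])
    def test_monotone_increasing_in_transport_terms(self, name):
        args = dict(delta_i=0.4, area_cm2=3.24e-6, sigma_i=4.0, l_cm=0.012,
                    r_g=0.0015, a_g_cm2=1.13e-6)
        lo = intracellular_conductance(**args)
        args[name] *= 1.5
        assert intracellular_conductance(**args) > lo

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(ValueError):
            extracellular_conductance(-0.5, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            intracellular_conductance(0.4, 1.0, 1.0, 1.0, 0.0, 1.0)


class TestGridNetwork:
    def test_strand_counts(self, strand15):
        assert strand15.n_nodes == 15
        assert strand15.n_edges == 14
        assert strand15.dirichlet.sum() == 2
        assert strand15.dirichlet[0] and strand15.dirichlet[14]

    def test_2d_counts_and_perimeter(self, geom, params):
        net = build_grid_network(20, 20, geom, params)
        assert net.n_nodes == 400
        assert net.n_edges == 2 * 20 * 19
        assert net.dirichlet.sum() == 4 * 20 - 4

    def test_single_cell(self, geom, params):
        net = build_grid_network(1, 1, geom, params)
        assert net.n_nodes == 1
        assert net.n_edges == 0

    def test_interior_degree(self, geom, params):
        net = build_grid_network(5, 5, geom, params)
        center = 2 * 5 + 2
        assert len(net.neighbors(center)) == 4
        net1d = build_grid_network(5, 1, geom, params)
        assert len(net1d.neighbors(2)) == 2

    def test_conductance_symmetry_via_laplacian(self, strand15):
        l_i = strand15.laplacian(strand15.g_i)
        assert (l_i - l_i.T).nnz == 0

    def test_rg_multiplier_reduces_gi(self, geom, params):
        base = build_grid_network(5, 1, geom, params)
        weak = build_grid_network(5, 1, geom, params, rg_multiplier=500.0)
        assert np.all(weak.g_i < base.g_i)
        assert np.allclose(weak.g_e, base.g_e)  # extracellular path unaffected

    def test_per_edge_override(self, geom, params):
        net = build_grid_network(4, 1, geom, params, rg_edge_multipliers={(1, 2): 100.0})
        idx = [tuple(e) for e in net.edges].index((1, 2))
        others = [i for i in range(net.n_edges) if i != idx]
        assert net.g_i[idx] < net.g_i[others].min()

    def test_zero_cells_rejected(self, geom, params):
        with pytest.raises(ValueError):
            build_grid_network(0, 1, geom, params)

    def test_json_round_trip(self, strand15):
        restored = Network.from_json(strand15.to_json())
        assert np.allclose(restored.g_i, strand15.g_i)
        assert np.allclose(restored.positions, strand15.positions)
        assert np.array_equal(restored.dirichlet, strand15.dirichlet)
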
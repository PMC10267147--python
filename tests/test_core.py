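"""Core solver: currents, conservation, assembly, splitting, oracles."""

import numpy as np
import pytest

from kirchnet import (
    CellGeometry,
    Network,
    NoDirichletError,
    PassiveMembrane,
    SimState,
    TissueParams,
    assemble,
    build_grid_network,
    edge_currents,
    kirchhoff_residual,
    s1_protocol,
    simulate,
    step,
)
from kirchnet.fixtures import dense_reference_solution, two_node_network


def make_state(net, v, u_e):
    return SimState(0.0, np.asarray(v, float), np.asarray(u_e, float), np.empty((0, net.n_nodes)))


def tiny_network(g_i=2.0, g_e=2.0):
    """Two nodes, one edge, unit-ish conductances, left node grounded."""
    return Network(
        positions=np.array([[0.0, 0.0], [120.0, 0.0]]),
        edges=np.array([[0, 1]]),
        g_i=np.array([g_i]),
        g_e=np.array([g_e]),
        a_m=np.array([5e-5, 5e-5]),
        dirichlet=np.array([True, False]),
    )


class TestEdgeCurrents:
    def test_uniform_potentials_carry_no_current(self):
        net = tiny_network()
        i_i, i_e = edge_currents(make_state(net, [3.0, 3.0], [1.0, 1.0]), net)
        assert i_i[0] == 0.0 and i_e[0] == 0.0

    def test_hand_example(self):
        """v=(0,0), u_e=(1,0) mV with G=2 mS gives 2 uA on both paths."""
        net = tiny_network(g_i=2.0, g_e=2.0)
        i_i, i_e = edge_currents(make_state(net, [0.0, 0.0], [1.0, 0.0]), net)
        assert i_i[0] == pytest.approx(2.0)
        assert i_e[0] == pytest.approx(2.0)

    def test_antisymmetry(self):
        net = tiny_network()
        state = make_state(net, [5.0, -3.0], [0.5, -0.2])
        i_i, i_e = edge_currents(state, net)
        flipped = Network(
            positions=net.positions, edges=net.edges[:, ::-1], g_i=net.g_i,
            g_e=net.g_e, a_m=net.a_m, dirichlet=net.dirichlet,
        )
        i_i_f, i_e_f = edge_currents(state, flipped)
        assert i_i_f[0] == -i_i[0]
        assert i_e_f[0] == -i_e[0]


class TestKirchhoffResidual:
    def test_uniform_is_exactly_zero(self, strand15):
        state = make_state(strand15, np.full(15, -80.0), np.zeros(15))
        assert np.all(kirchhoff_residual(state, strand15) == 0.0)

    def test_matches_dense_laplacian_oracle(self, rng):
        """Residual equals the dense graph-Laplacian product on 5 nodes."""
        net = build_grid_network(5, 1)
        v = rng.normal(size=5)
        u_e = rng.normal(size=5)
        state = make_state(net, v, u_e)
        l_i = net.laplacian(net.g_i).toarray()
        l_e = net.laplacian(net.g_e).toarray()
        expected = -(l_i @ (v + u_e) + l_e @ u_e)
        expected[net.dirichlet] = 0.0
        assert np.allclose(kirchhoff_residual(state, net), expected, atol=1e-15)


class TestAssembly:
    def test_requires_grounded_node(self):
        net = tiny_network()
        net.dirichlet[:] = False
        with pytest.raises(NoDirichletError):
            assemble(net, 1.0, 0.01)

    def test_isolated_node_keeps_voltage(self):
        net = build_grid_network(1, 1)
        system = assemble(net, 1.0, 0.05)
        state = SimState(0.0, np.array([-37.0]), np.zeros(1), np.empty((0, 1)))
        out = step(state, system, PassiveMembrane(e_leak=-37.0), 0.0, 0.05)
        assert out.v[0] == pytest.approx(-37.0, abs=1e-12)

    def test_small_dt_is_near_identity(self, strand15, rng):
        v0 = -80.0 + rng.normal(scale=2.0, size=15)
        sys_small = assemble(strand15, 1.0, 1e-7)
        state = SimState(0.0, v0.copy(), np.zeros(15), np.empty((0, 15)))
        out = step(state, sys_small, PassiveMembrane(), 0.0, 1e-7)
        assert np.allclose(out.v, v0, atol=1e-6)

    def test_invalid_dt(self, strand15):
        with pytest.raises(ValueError):
            assemble(strand15, 1.0, 0.0)


class TestStepping:
    def test_rest_is_preserved(self, strand15, excitable):
        trace = simulate(strand15, excitable, None, dt=0.05, duration=20.0)
        assert np.max(np.abs(trace.v - excitable.v_rest)) < 1e-6

    def test_strand_propagation_is_ordered(self, strand15, excitable):
        proto = s1_protocol(strand15)
        trace = simulate(strand15, excitable, proto, dt=0.02, duration=300.0,
                         stop_after_all_activated=1.0)
        firsts = [trace.first_activation(k) for k in range(15)]
        assert all(t is not None for t in firsts)
        assert np.all(np.diff(firsts) > 0)  # strictly rightward wavefront
        assert all(len(trace.activations_step[k]) == 1 for k in range(15))

    def test_duration_zero_gives_initial_snapshot_only(self, strand15, excitable):
        trace = simulate(strand15, excitable, None, dt=0.01, duration=0.0)
        assert trace.times.tolist() == [0.0]
        assert trace.v.shape == (1, 15)

    def test_bitwise_determinism(self, strand15, excitable):
        proto = s1_protocol(strand15)
        kwargs = dict(dt=0.05, duration=10.0, snapshot_every=1.0)
        a = simulate(strand15, excitable, proto, **kwargs)
        b = simulate(strand15, excitable, proto, **kwargs)
        assert np.array_equal(a.v, b.v)
        assert a.activations_interp == b.activations_interp

    def test_gmres_matches_direct(self, strand15, excitable):
        proto = s1_protocol(strand15)
        a = simulate(strand15, excitable, proto, dt=0.05, duration=5.0, solver="direct")
        b = simulate(strand15, excitable, proto, dt=0.05, duration=5.0, solver="gmres")
        assert np.allclose(a.v, b.v, atol=1e-6)
        assert b.meta["max_residual_norm"] < 10 * b.meta["tol"]


class TestChargePathConsistency:
    def test_two_node_loop_current_balance(self):
        """With one grounded compartment, the intracellular current on the
        edge returns through the extracellular path at every step (current
        conservation at the ungrounded node)."""
        net = two_node_network()
        net.dirichlet[:] = [True, False]  # ground only the left compartment
        model = PassiveMembrane()
        system = assemble(net, 1.0, 0.01)
        state = SimState(0.0, np.array([-60.0, -80.0]), np.zeros(2), np.empty((0, 2)))
        for _ in range(200):
            state = step(state, system, model, 0.0, 0.01)
            i_i, i_e = edge_currents(state, net)
            assert abs(i_i[0] + i_e[0]) < 1e-10 * max(1.0, abs(i_i[0]))


class TestSymmetry:
    def test_reflection_symmetry_on_3x3(self, excitable):
        """Center-cell stimulus on a 3x3 grid keeps v mirror-symmetric."""
        net = build_grid_network(3, 3)
        geom = CellGeometry()
        from kirchnet import StimulusEntry, StimulusProtocol

        proto = StimulusProtocol([
            StimulusEntry((geom.length, 2 * geom.length), (geom.l_y, 2 * geom.l_y),
                          40.0, 0.0, 2.0)
        ])
        trace = simulate(net, excitable, proto, dt=0.05, duration=20.0, snapshot_every=1.0)
        for v in trace.v:
            grid = v.reshape(3, 3)
            assert np.allclose(grid, grid[::-1, :], atol=1e-8)
            assert np.allclose(grid, grid[:, ::-1], atol=1e-8)


class TestDenseOracle:
    def test_passive_trajectory_matches_dae_reference(self):
        """Split scheme vs brute-force implicit ODE/constraint solve, 3 nodes."""
        net = build_grid_network(3, 1)
        model = PassiveMembrane()
        v0 = np.array([-50.0, -80.0, -80.0])
        t_end = 2.0
        t_eval = np.array([0.0, t_end])
        v_ref, _ = dense_reference_solution(net, model, v0, t_eval)

        def run(dt):
            trace = simulate(net, model, None, dt=dt, duration=t_end, v0=v0,
                             snapshot_every=t_end)
            return trace.v[-1]

        err = {dt: np.max(np.abs(run(dt) - v_ref[-1])) for dt in (0.02, 0.01, 0.005)}
        assert err[0.005] < err[0.01] < err[0.02]
        order = np.log2(err[0.02] / err[0.01])
        assert 0.8 <= order <= 1.2

    def test_kirchhoff_residual_small_after_each_step(self):
        net = build_grid_network(4, 1)
        model = PassiveMembrane()
        trace = simulate(net, model, None, dt=0.01, duration=1.0,
                         v0=np.array([-40.0, -80.0, -80.0, -80.0]))
        assert trace.meta["max_residual_norm"] < 10 * trace.meta["tol"]
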
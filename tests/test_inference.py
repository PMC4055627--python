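"""Tension/pressure system assembly, constrained solvers, General Solution."""

import numpy as np
import pytest

from arcforce import geometry as geom
from arcforce import inference as inf
from arcforce import mesh as mm
from arcforce.model import ForceInferenceModel
from arcforce.synthetic import double_bubble, error_metrics

from conftest import single_junction_mesh


def star_tangents(mesh, angles_deg):
    (j,) = mesh.junctions.values()
    out = {}
    for eid, a in zip(sorted(mesh.edges), angles_deg):
        d = np.array([np.cos(np.deg2rad(a)), np.sin(np.deg2rad(a))])
        e = mesh.edges[eid]
        end = "first" if e.endpoint_junctions[0] == j.id else "second"
        out[(eid, end)] = d
        other = "second" if end == "first" else "first"
        out[(eid, other)] = -d
    return out


class TestAssembleTensions:
    def test_symmetric_tj_rows(self, tj_star):
        tangents = star_tangents(tj_star, [0, 120, 240])
        sys = inf.assemble_tension_system(tj_star, tangents)
        assert sys.matrix_G.shape == (2, 3)
        np.testing.assert_allclose(
            sys.matrix_G[0], [1.0, -0.5, -0.5], atol=1e-12)
        np.testing.assert_allclose(
            sys.matrix_G[1], [0.0, np.sqrt(3) / 2, -np.sqrt(3) / 2],
            atol=1e-12)

    def test_excluding_shared_edge_removes_both_junctions(self):
        # two junctions joined by one edge, each with two extra stubs
        from arcforce.mesh import Cell, Edge, Node, build_mesh

        nodes = [Node(0, np.array([0.0, 0.0])), Node(1, np.array([1.0, 0.0]))]
        nid = 2
        edges = [Edge(0, [0, 1], (1, 2))]
        eid = 1
        for base, sgn in ((0, -1), (1, 1)):
            for dy in (1.0, -1.0):
                nodes.append(Node(nid, np.array([base + sgn * 1.0, dy])))
                edges.append(Edge(eid, [base, nid], (eid + 1, eid + 10)))
                nid += 1
                eid += 1
        cells = {}
        for e in edges:
            for s in e.side_cells:
                cells.setdefault(s, []).append(e.id)
        mesh = build_mesh(nodes, edges,
                          [Cell(c, ids, is_partial=True)
                           for c, ids in cells.items()])
        geometry = geom.mesh_geometry(mesh)
        tangents = inf.tangent_map(geometry)
        sys = inf.assemble_tension_system(mesh, tangents, excluded_edge_ids={0})
        assert sys.matrix_G.shape[0] == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_row_column_counts_match_tally(self, seed):
        from arcforce.synthetic import generate_patch

        mesh = generate_patch(15, seed)
        geometry = geom.mesh_geometry(mesh)
        tangents = inf.tangent_map(geometry)
        counts = mm.tally_counts(mesh)
        sys = inf.assemble_tension_system(mesh, tangents)
        assert sys.matrix_G.shape[0] == counts.n_tension_eqns
        # each row has exactly (junction order) nonzeros, all in [-1, 1]
        for k, (jid, _) in enumerate(sys.row_index):
            row = sys.matrix_G[k]
            assert np.count_nonzero(row) <= mesh.junctions[jid].order
            assert np.all(np.abs(row) <= 1 + 1e-12)


class TestSolveTensions:
    def test_symmetric_tj_unit_tensions(self, tj_star):
        tangents = star_tangents(tj_star, [0, 120, 240])
        sys = inf.assemble_tension_system(tj_star, tangents)
        gamma, lam = inf.solve_tensions(sys)
        np.testing.assert_allclose(list(gamma.values()), [1, 1, 1],
                                   atol=1e-10)

    def test_lami_theorem_closed_form(self, tj_star):
        """Tangents at 0/90/225 degrees give ratios 1 : 1 : sqrt(2)."""
        tangents = star_tangents(tj_star, [0, 90, 225])
        sys = inf.assemble_tension_system(tj_star, tangents)
        gamma, _ = inf.solve_tensions(sys)
        expected = np.array([1.0, 1.0, np.sqrt(2.0)])
        expected /= expected.mean()
        np.testing.assert_allclose(
            [gamma[e] for e in sorted(gamma)], expected, atol=1e-10)
        np.testing.assert_allclose(expected,
                                   [0.87867966, 0.87867966, 1.24264069])

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_substitution_oracle(self, seed):
        """KKT solve equals eliminating the constraint by substitution."""
        rng = np.random.default_rng(seed)
        m, n = 14, 8
        G = rng.normal(size=(m, n))
        sys = inf.TensionSystem(
            matrix_G=G,
            constraint_vector=np.full(n, 1.0 / n),
            row_index=[(i // 2, "xy"[i % 2]) for i in range(m)],
            col_index=list(range(n)),
        )
        gamma, _ = inf.solve_tensions(sys)
        got = np.array([gamma[i] for i in range(n)])
        # oracle: gamma = 1 + Z u, minimise ||G(1 + Z u)||
        ones = np.ones(n) / np.sqrt(n)
        Z = np.linalg.svd(np.eye(n) - np.outer(ones, ones))[0][:, : n - 1]
        u, *_ = np.linalg.lstsq(G @ Z, -G @ np.ones(n), rcond=None)
        expected = np.ones(n) + Z @ u
        np.testing.assert_allclose(got, expected, atol=1e-8)
        assert np.mean(got) == pytest.approx(1.0, abs=1e-10)

    def test_homogeneity_under_coordinate_scaling(self, annealed_small):
        mesh, _ = annealed_small
        g1 = ForceInferenceModel(mesh).fit(tensions_only=True).tensions
        for node in mesh.nodes.values():
            node.position = node.position * 3.7
        try:
            g2 = ForceInferenceModel(mesh).fit(tensions_only=True).tensions
        finally:
            for node in mesh.nodes.values():
                node.position = node.position / 3.7
        np.testing.assert_allclose(g1.values, g2.values, atol=1e-8)


class TestPressures:
    def test_two_cell_worked_example(self, two_cell_mesh):
        """gamma=1, rho=2, convex into cell 2: row (+1,-1), rhs 0.5,
        pressures split symmetrically to (+0.25, -0.25)."""
        geometry = geom.mesh_geometry(two_cell_mesh)
        assert geometry[0].curvature_signed == pytest.approx(0.5, abs=1e-9)
        usable = [0]
        sys = inf.assemble_pressure_system(
            two_cell_mesh, {0: 1.0}, inf.curvature_map(geometry), usable)
        assert sys.matrix_G.shape == (1, 2)
        i = sys.col_index.index(1)
        j = sys.col_index.index(2)
        assert sys.matrix_G[0, i] == 1.0 and sys.matrix_G[0, j] == -1.0
        assert sys.rhs_q[0] == pytest.approx(0.5, abs=1e-9)
        p, _ = inf.solve_pressures(sys)
        assert p[1] == pytest.approx(0.25, abs=1e-10)
        assert p[2] == pytest.approx(-0.25, abs=1e-10)

    def test_all_straight_mesh_zero_pressures(self):
        rows = [(0, 1, 2), (1, 2, 3), (2, 3, 1)]
        G = np.array([[1.0, -1, 0], [0, 1, -1], [-1, 0, 1]])
        sys = inf.PressureSystem(
            matrix_G=G, rhs_q=np.zeros(3),
            constraint_vector=np.full(3, 1 / 3),
            row_index=[0, 1, 2], col_index=[1, 2, 3])
        p, _ = inf.solve_pressures(sys)
        np.testing.assert_allclose(list(p.values()), 0.0, atol=1e-12)

    def test_chain_of_cells_cumulative_oracle(self):
        """Consistent dp chain: cumulative sum then de-mean."""
        G = np.array([[1.0, -1, 0], [0, 1, -1]])
        q = np.array([0.5, 0.3])
        sys = inf.PressureSystem(
            matrix_G=G, rhs_q=q, constraint_vector=np.full(3, 1 / 3),
            row_index=[0, 1], col_index=[1, 2, 3])
        p, _ = inf.solve_pressures(sys)
        raw = np.array([0.8, 0.3, 0.0])  # p1-p3=0.8, p2-p3=0.3
        expected = raw - raw.mean()
        np.testing.assert_allclose([p[1], p[2], p[3]], expected, atol=1e-10)


class TestGeneralSolution:
    def test_identity(self):
        g, p = inf.general_solution({0: 0.8, 1: 1.2}, {1: 0.25, 2: -0.25},
                                    1.0, 0.0)
        assert g == {0: 0.8, 1: 1.2}
        assert p == {1: 0.25, 2: -0.25}

    def test_scaling_arithmetic(self):
        g, p = inf.general_solution({0: 0.8, 1: 1.2}, {1: 0.25, 2: -0.25},
                                    3.0, 10.0)
        assert g[0] == pytest.approx(2.4) and g[1] == pytest.approx(3.6)
        assert p[1] == pytest.approx(10.75) and p[2] == pytest.approx(9.25)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            inf.general_solution({0: 1.0}, {}, 0.0, 0.0)

    def test_standardize_roundtrip(self):
        gs = {0: 0.6, 1: 1.4}
        ps = {1: 0.5, 2: -0.5}
        g, p = inf.general_solution(gs, ps, alpha=2.5, beta=-3.0)
        gs2, ps2, alpha, beta = inf.standardize(g, p)
        assert alpha == pytest.approx(2.5, abs=1e-12)
        assert beta == pytest.approx(-3.0, abs=1e-12)
        for k in gs:
            assert gs2[k] == pytest.approx(gs[k], abs=1e-12)
        for k in ps:
            assert ps2[k] == pytest.approx(ps[k], abs=1e-12)

    def test_standardize_tension_classes(self):
        gamma = np.array([5.0, 6, 7, 10, 11, 12])
        gs, ps, alpha, beta = inf.standardize(gamma, np.zeros(1))
        assert alpha == pytest.approx(8.5)
        np.testing.assert_allclose(
            gs, [0.588, 0.706, 0.824, 1.176, 1.294, 1.412], atol=5e-4)

    def test_constant_pressure_standardizes_to_zero(self):
        gs, ps, alpha, beta = inf.standardize(np.ones(4), np.full(3, 7.0))
        assert beta == pytest.approx(7.0)
        np.testing.assert_allclose(ps, 0.0, atol=1e-12)


class TestExactRecovery:
    @pytest.mark.parametrize("gammas,tilt", [
        ((1.0, 1.0, 1.0), 0.0),
        ((1.0, 1.2, 0.9), 10.0),
        ((0.8, 1.1, 1.0), -7.0),
    ])
    def test_double_bubble_machine_precision(self, gammas, tilt):
        """An analytically equilibrated configuration is recovered exactly."""
        mesh, truth = double_bubble(gammas, tilt_deg=tilt)
        res = ForceInferenceModel(mesh).fit()
        m = error_metrics(res.tensions.to_dict(), res.pressures.to_dict(),
                          truth)
        assert m.tension_error_pct < 1e-6
        assert m.pressure_error_pct < 1e-6
        # residuals vanish for a consistent system
        g = np.array([res.tensions[e] for e in res.tension_systems[0].col_index])
        assert np.abs(res.tension_systems[0].matrix_G @ g).max() < 1e-9

    def test_mean_constraints_hold(self, annealed_small):
        mesh, _ = annealed_small
        res = ForceInferenceModel(mesh).fit()
        for tsys in res.tension_systems:
            vals = np.array([res.tensions[e] for e in tsys.col_index])
            assert abs(vals.mean() - 1.0) < 1e-10
        for psys in res.pressure_systems:
            vals = np.array([res.pressures[c] for c in psys.col_index])
            assert abs(vals.mean()) < 1e-10

    def test_overdetermined_on_annealed_regions(self, annealed_region):
        mesh, _ = annealed_region
        res = ForceInferenceModel(mesh).fit()
        for tsys in res.tension_systems:
            assert tsys.matrix_G.shape[0] > tsys.matrix_G.shape[1]
        for psys in res.pressure_systems:
            assert psys.matrix_G.shape[0] > psys.matrix_G.shape[1]
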
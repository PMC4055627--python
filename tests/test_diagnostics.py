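"""Condition numbers, residuals and covariance standard errors."""

import numpy as np
import pytest

from arcforce import diagnostics as diag
from arcforce import geometry as geom
from arcforce import inference as inf
from arcforce.model import ForceInferenceModel

from conftest import single_junction_mesh
from test_inference import star_tangents


class TestConditionNumber:
    def test_identity_is_one(self):
        assert diag.condition_number(np.eye(2)) == pytest.approx(1.0)

    def test_diagonal_ratio(self):
        assert diag.condition_number(np.diag([4.0, 2.0])) == pytest.approx(2.0)

    def test_rank_deficient_is_infinite(self):
        A = np.array([[1.0, 1.0], [2.0, 2.0]])
        assert diag.condition_number(A) == np.inf

    def test_augmented_y_junction_matches_svd_oracle(self, tj_star):
        tangents = star_tangents(tj_star, [0, 120, 240])
        sys = inf.assemble_tension_system(tj_star, tangents)
        got = diag.system_condition_number(sys)
        A = np.vstack([sys.matrix_G, sys.constraint_vector[None, :]])
        s = np.linalg.svd(A, compute_uv=False)
        assert got == pytest.approx(s[0] / s[-1], abs=1e-10)

    def test_annealed_systems_well_conditioned(self, annealed_region):
        """Curved-edge systems stay far from singular (condition < 1e3)."""
        mesh, _ = annealed_region
        res = ForceInferenceModel(mesh).fit()
        assert 1.0 <= res.diagnostics.cond_tension < 1e3
        assert 1.0 <= res.diagnostics.cond_pressure < 1e3


class TestTensionResiduals:
    def test_consistent_system_zero_residuals(self, tj_star):
        tangents = star_tangents(tj_star, [0, 120, 240])
        sys = inf.assemble_tension_system(tj_star, tangents)
        gamma, _ = inf.solve_tensions(sys)
        _, norm = diag.tension_residuals(sys, gamma)
        assert max(norm.values()) < 1e-12

    def test_perturbed_junction_is_localised(self):
        """A 5-degree tangent error at one junction dominates the residual
        increase there, not elsewhere (clean unfrayed patch)."""
        from arcforce.synthetic import (anneal, assign_types_and_tensions,
                                        generate_patch, resample_chains)

        mesh = generate_patch(24, seed=2)
        truth = assign_types_and_tensions(mesh, seed=3)
        mesh, _ = anneal(mesh, truth)
        resample_chains(mesh)
        geometry = geom.mesh_geometry(mesh)
        tangents = dict(inf.tangent_map(geometry))
        target = next(
            j for j in mesh.junctions.values()
            if j.order == 3
            and all(s is not None
                    for e in j.incident_edge_ids
                    for s in mesh.edges[e].side_cells))
        eid = next(e for e in target.incident_edge_ids
                   if not mesh.edges[e].is_stub)
        end = ("first" if mesh.edges[eid].endpoint_junctions[0] == target.id
               else "second")
        import arcforce.mesh as mm

        comp = max(mm.tension_components(mesh), key=len)
        sys0 = inf.assemble_tension_system(mesh, tangents, junction_ids=comp)
        gamma0, _ = inf.solve_tensions(sys0)
        _, base = diag.tension_residuals(sys0, gamma0)

        a = np.deg2rad(5.0)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        tangents[(eid, end)] = R @ tangents[(eid, end)]
        sys1 = inf.assemble_tension_system(mesh, tangents, junction_ids=comp)
        gamma, _ = inf.solve_tensions(sys1)
        _, norm = diag.tension_residuals(sys1, gamma)

        delta = {j: abs(norm[j] - base.get(j, 0.0)) for j in norm}
        med = np.median(list(delta.values()))
        # the residual increase concentrates at the perturbed edge's
        # junctions, not elsewhere
        other = [j for j in mesh.edges[eid].endpoint_junctions if j is not None]
        top = max(delta, key=delta.get)
        assert top in other
        assert delta[top] > 10 * med

    def test_ls_residual_orthogonal_to_feasible_directions(self):
        rng = np.random.default_rng(0)
        G = rng.normal(size=(12, 6))
        sys = inf.TensionSystem(G, np.full(6, 1 / 6),
                                [(i // 2, "xy"[i % 2]) for i in range(12)],
                                list(range(6)))
        gamma, _ = inf.solve_tensions(sys)
        g = np.array([gamma[i] for i in range(6)])
        r = G @ g
        # gradient of ||G gamma||^2 must be normal to the constraint plane
        ones = np.ones(6) / np.sqrt(6)
        Z = np.linalg.svd(np.eye(6) - np.outer(ones, ones))[0][:, :5]
        assert np.abs(Z.T @ (G.T @ r)).max() < 1e-9


class TestPressureResiduals:
    def test_consistent_two_cell_case_zero(self, two_cell_mesh):
        geometry = geom.mesh_geometry(two_cell_mesh)
        sys = inf.assemble_pressure_system(
            two_cell_mesh, {0: 1.0}, inf.curvature_map(geometry), [0])
        p, _ = inf.solve_pressures(sys)
        raw, norm = diag.pressure_residuals(sys, p, {0: 2.0}, 1.0)
        assert abs(raw[0]) < 1e-12 and norm[0] < 1e-12

    def test_zero_pressures_residual_is_q_times_chord(self, two_cell_mesh):
        geometry = geom.mesh_geometry(two_cell_mesh)
        sys = inf.assemble_pressure_system(
            two_cell_mesh, {0: 1.0}, inf.curvature_map(geometry), [0])
        chord = geometry[0].chord_length
        _, norm = diag.pressure_residuals(sys, {1: 0.0, 2: 0.0},
                                          {0: chord}, 1.0)
        assert norm[0] == pytest.approx(abs(sys.rhs_q[0]) * chord)

    def test_doubling_chords_doubles_normalised_residuals(self, two_cell_mesh):
        geometry = geom.mesh_geometry(two_cell_mesh)
        sys = inf.assemble_pressure_system(
            two_cell_mesh, {0: 1.0}, inf.curvature_map(geometry), [0])
        _, n1 = diag.pressure_residuals(sys, {1: 0.0, 2: 0.0}, {0: 1.0}, 1.0)
        _, n2 = diag.pressure_residuals(sys, {1: 0.0, 2: 0.0}, {0: 2.0}, 1.0)
        assert n2[0] == pytest.approx(2 * n1[0])


class TestStandardErrors:
    def test_exactly_consistent_system_tiny_ses(self):
        from arcforce.synthetic import double_bubble

        mesh, _ = double_bubble((1.0, 1.2, 0.9), tilt_deg=10)
        res = ForceInferenceModel(mesh).fit(tensions_only=True)
        se = res.tension_se.dropna()
        assert (se < 1e-6).all()

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_kkt_pseudoinverse_oracle(self, seed):
        """Reduced-parametrisation covariance equals the KKT pseudo-inverse
        covariance on random overdetermined systems."""
        rng = np.random.default_rng(seed)
        m, n = 10, 6
        G = rng.normal(size=(m, n))
        q = rng.normal(size=m)
        c = np.full(n, 1.0 / n)
        sys = inf.PressureSystem(G, q, c, list(range(m)), list(range(n)))
        p, _ = inf.solve_pressures(sys)
        pv = np.array([p[i] for i in range(n)])
        got = diag.standard_errors(G, q, pv)

        # oracle: covariance propagated through the KKT pseudo-inverse
        K = np.zeros((n + 1, n + 1))
        K[:n, :n] = 2 * G.T @ G
        K[:n, n] = c
        K[n, :n] = c
        Kinv = np.linalg.pinv(K)
        B = Kinv[:n, :n] @ (2 * G.T)  # d p / d q
        resid = G @ pv - q
        sigma2 = resid @ resid / (m - (n - 1))
        cov = sigma2 * B @ B.T
        expected = np.sqrt(np.diag(cov))
        np.testing.assert_allclose(got, expected, rtol=1e-6)

    def test_underdetermined_returns_none(self):
        G = np.eye(3)[:2]  # 2 equations, 3 unknowns
        assert diag.standard_errors(G, np.zeros(2), np.zeros(3)) is None

    def test_invariant_under_row_permutation(self):
        rng = np.random.default_rng(1)
        G = rng.normal(size=(9, 5))
        q = rng.normal(size=9)
        c = np.full(5, 0.2)
        sys = inf.PressureSystem(G, q, c, list(range(9)), list(range(5)))
        p, _ = inf.solve_pressures(sys)
        pv = np.array([p[i] for i in range(5)])
        se1 = diag.standard_errors(G, q, pv)
        perm = rng.permutation(9)
        se2 = diag.standard_errors(G[perm], q[perm], pv)
        np.testing.assert_allclose(se1, se2, rtol=1e-10)


class TestNoiseMonotonicity:
    def test_median_se_increases_with_noise(self, annealed_small):
        """Measurement noise inflates the covariance standard errors."""
        from arcforce.synthetic import (NoiseSpec, angles_to_tangents,
                                        inject_noise, tangents_to_angles)

        mesh, _ = annealed_small
        geometry = geom.mesh_geometry(mesh)
        tangents0 = inf.tangent_map(geometry)
        curv0 = inf.curvature_map(geometry)
        medians = []
        for level in (0.0, 1.0, 2.0, 5.0):
            vals = []
            for rep in range(3):
                if level == 0:
                    tangents = tangents0
                else:
                    ang, _ = inject_noise(tangents_to_angles(tangents0),
                                          curv0,
                                          NoiseSpec(level, seed=7 * rep + 1))
                    tangents = angles_to_tangents(ang)
                gamma, systems, _, _ = inf.solve_tension_field(mesh, tangents)
                tsys = systems[0]
                g = np.array([gamma[e] for e in tsys.col_index])
                se = diag.standard_errors(
                    tsys.matrix_G, np.zeros(tsys.matrix_G.shape[0]), g)
                vals.append(np.median(se))
            medians.append(np.mean(vals))
        assert all(a < b for a, b in zip(medians, medians[1:]))
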
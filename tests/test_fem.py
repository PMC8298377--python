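"""Mixed H1-P0 finite elements: patch test, tangent consistency, surface
pressure resultant, prestretch release, and equivalence with the
material-point driver on homogeneous histories."""

import numpy as np
import pytest

from tissueheal.driver import PhaseSchedule
from tissueheal.experiments import (
    make_plate_mesh,
    material_point_biaxial,
    prestretch_and_release,
    run_biaxial,
    _homogeneous_thickness_stretch,
)
from tissueheal.fem import FemModel, LoadCase, cone_pressure_profile
from tissueheal.params import DAY, YEAR, biaxial_params, indentation_params


@pytest.fixture
def schedule():
    return PhaseSchedule(t0=0.0, t_star=60.0, t_end=YEAR)


class TestMesh:
    def test_single_element_counts(self):
        m = make_plate_mesh(1.0, 1.0, 1.0, 1, 1, 1)
        assert m.n_nodes == 8 and m.n_elems == 1

    def test_indentation_mesh_counts(self):
        m = make_plate_mesh(0.06, 0.06, 0.012, 22, 22, 8)
        assert m.n_nodes == 23 * 23 * 9
        assert m.n_elems == 22 * 22 * 8 == 3872

    def test_grading_preserves_dimensions(self):
        m = make_plate_mesh(0.06, 0.05, 0.012, 9, 7, 4, grading=0.7)
        assert m.nodes[:, 0].max() == pytest.approx(0.06, abs=1e-14)
        assert m.nodes[:, 1].max() == pytest.approx(0.05, abs=1e-14)
        # element sizes shrink toward the loaded corner at x = 0
        xs = np.unique(m.nodes[:, 0])
        sizes = np.diff(xs)
        assert all(b > a for a, b in zip(sizes, sizes[1:]))

    def test_boundary_sets_complete(self):
        m = make_plate_mesh(1.0, 1.0, 0.5, 3, 3, 2)
        assert len(m.node_sets["x0"]) == 4 * 3
        assert len(m.node_sets["top"]) == 16
        assert len(m.top_facets) == 9

    def test_positive_jacobians_checked(self, params, schedule):
        m = make_plate_mesh(1.0, 1.0, 1.0, 2, 2, 2)
        FemModel(m, params, schedule)  # does not raise


class TestElementResidualTangent:
    def test_zero_residual_at_reference(self, params, schedule):
        m = make_plate_mesh(1e-3, 1e-3, 1e-3, 1, 1, 1)
        model = FemModel(m, params, schedule)
        f, _, _, theta, p = model.assemble(model.u, -1.0, 1.0,
                                           want_tangent=False)
        assert np.abs(f).max() < 1e-9
        assert theta[0] == pytest.approx(1.0)

    def test_homogeneous_deformation_theta_equals_J(self, params, schedule):
        lx, ly, lz = 6e-3, 3e-3, 0.225e-3
        m = make_plate_mesh(lx, ly, lz, 1, 1, 1)
        model = FemModel(m, params, schedule)
        lam = np.array([1.2, 1.1, 0.8])
        model.u = (m.nodes * (lam - 1.0)).reshape(-1)
        _, _, _, theta, _ = model.assemble(model.u, -1.0, 1.0,
                                           want_tangent=False)
        assert theta[0] == pytest.approx(np.prod(lam), rel=1e-12)

    def test_tangent_matches_fd_of_residual(self, rng, params, schedule):
        m = make_plate_mesh(2e-3, 2e-3, 1e-3, 2, 2, 1, grading=0.8)
        model = FemModel(m, params, schedule)
        u = 2e-5 * rng.normal(size=model.ndof)
        f0, K, _, _, _ = model.assemble(u, -1.0, 1.0)
        K = K.toarray()
        h = 1e-9
        for j in rng.choice(model.ndof, 8, replace=False):
            up, um = u.copy(), u.copy()
            up[j] += h
            um[j] -= h
            fp, _, _, _, _ = model.assemble(up, -1.0, 1.0, want_tangent=False)
            fm, _, _, _, _ = model.assemble(um, -1.0, 1.0, want_tangent=False)
            col = (fp - fm) / (2 * h)
            assert np.abs(K[:, j] - col).max() <= 1e-5 * max(
                1.0, np.abs(col).max())

    def test_patch_test_homogeneous_stress(self, params, schedule):
        """Linear displacement BCs on a distorted 2x2x2 mesh produce a
        homogeneous deformation (and hence stress) field."""
        m = make_plate_mesh(1e-3, 1e-3, 1e-3, 2, 2, 2)
        rng = np.random.default_rng(7)
        interior = 13  # the single interior node of the 3x3x3 grid
        m.nodes[interior] += 1e-4 * rng.normal(size=3)  # distort
        model = FemModel(m, params, schedule, stall_rtol=1e-14,
                         newton_atol=1e-13)
        Fh = np.array([[1.08, 0.02, 0.0], [0.01, 1.03, 0.0], [0.0, 0.0, 0.93]])
        disp = m.nodes @ (Fh - np.eye(3)).T
        boundary = np.setdiff1d(np.arange(m.n_nodes), [interior])
        model.loadcase = LoadCase(dirichlet=[
            (boundary, c, 0.0) for c in range(3)])
        # prescribe the exact linear values dof-by-dof
        model.loadcase.dirichlet = [
            (np.array([nid]), c, float(disp[nid, c]))
            for nid in boundary for c in range(3)
        ]
        model.t = -2.0
        model.solve_step(-1.0, 1.0)
        u = model.u.reshape(-1, 3)
        assert np.abs(u - disp).max() < 1e-9 * max(1.0, np.abs(disp).max())
        Fs = [model.deformation_gradient(e, g)
              for e in range(m.n_elems) for g in range(8)]
        assert np.abs(np.array(Fs) - Fh).max() < 1e-9


class TestSurfacePressure:
    def test_zero_and_edge_profile(self):
        assert cone_pressure_profile(0.0, 0.01) == 1.0
        assert cone_pressure_profile(0.01, 0.01) == 0.0
        assert cone_pressure_profile(0.02, 0.01) == 0.0

    def test_quarter_disk_resultant(self, schedule):
        """Total force of the cone pressure on the quarter plate equals the
        analytic integral pi pbar r_p^2 / 12."""
        params = indentation_params()
        m = make_plate_mesh(0.06, 0.06, 0.012, 24, 24, 1)
        model = FemModel(m, params, schedule)
        pbar, r_p = 36e3, 0.01
        model.loadcase = LoadCase(pressure=(pbar, r_p))
        f = model.surface_pressure_forces(0.0)
        total_z = f[2::3].sum()
        exact = -np.pi * pbar * r_p**2 / 12.0
        assert total_z == pytest.approx(exact, rel=5e-3)
        assert f[0::3].sum() == pytest.approx(0.0, abs=1e-12)

    def test_zero_pressure_zero_forces(self, params, schedule):
        m = make_plate_mesh(0.06, 0.06, 0.012, 4, 4, 2)
        model = FemModel(m, params, schedule)
        model.loadcase = LoadCase(pressure=(0.0, 0.01))
        assert np.abs(model.surface_pressure_forces(0.0)).max() == 0.0


class TestSolveStep:
    def test_zero_increment_converges_immediately(self, params, schedule):
        m = make_plate_mesh(6e-3, 3e-3, 0.225e-3, 1, 1, 1)
        model = FemModel(m, params, schedule)
        ns = m.node_sets
        model.loadcase = LoadCase(dirichlet=[
            (ns["x0"], 0, 0.0), (ns["y0"], 1, 0.0), (ns["z0"], 2, 0.0)])
        model.t = -2.0
        model.solve_step(-1.5, 0.5)
        iters_first = model.log[-1]["iters"]
        model.solve_step(-1.0, 0.5)
        assert model.log[-1]["iters"] == 1
        assert np.abs(model.u).max() < 1e-12
        assert iters_first >= 1

    def test_single_element_biaxial_matches_material_point(self):
        """Cross-module oracle: the mixed single-element solution under the
        full biaxial protocol agrees with the homogeneous material-point
        solve (plane-stress thickness iteration) to high accuracy."""
        fem_rep = run_biaxial(dt_damage=1.0, dt_heal=20 * DAY,
                              t_end=60.0 + 80 * DAY, n_heal_records=4)
        mp_rep = material_point_biaxial(dt_damage=1.0, dt_heal=20 * DAY,
                                        t_end=60.0 + 80 * DAY)
        assert fem_rep["d_star"] == pytest.approx(mp_rep["d_star"], rel=1e-7)
        assert fem_rep["lambda_z_end"] == pytest.approx(
            mp_rep["lambda_z_end"], rel=1e-6)
        assert fem_rep["J_end"] == pytest.approx(mp_rep["J_end"], rel=1e-6)


class TestPrestretchRelease:
    def test_release_preserves_equilibrium(self, schedule):
        params = indentation_params()
        lx = ly = 0.06
        lz = 0.012
        m = make_plate_mesh(lx, ly, lz, 3, 3, 2, grading=0.7)
        model = FemModel(m, params, schedule)
        ns = m.node_sets
        model.loadcase = LoadCase(dirichlet=[
            (ns["x0"], 0, 0.0), (ns["y0"], 1, 0.0), (ns["z0"], 2, 0.0),
            (ns["xl"], 0, 0.34 * lx), (ns["yl"], 1, 0.25 * ly)])
        lam_z0 = _homogeneous_thickness_stretch(params, 1.34, 1.25)
        model.u = (m.nodes * (np.array([1.34, 1.25, lam_z0]) - 1.0)).reshape(-1)
        model.t = -2.0
        model.solve_step(-1.0, 1.0)
        model.equilibrate_prestretch()
        model.solve_step(-0.5, 0.5)
        rel = prestretch_and_release(model)
        assert rel["displacement_drift"] < 1e-8
        assert rel["residual_norm"] < 1e-5

    def test_zero_prestretch_zero_release_tractions(self, params, schedule):
        m = make_plate_mesh(6e-3, 3e-3, 0.225e-3, 1, 1, 1)
        model = FemModel(m, params, schedule)
        ns = m.node_sets
        model.loadcase = LoadCase(dirichlet=[
            (ns["x0"], 0, 0.0), (ns["y0"], 1, 0.0), (ns["z0"], 2, 0.0),
            (ns["xl"], 0, 0.0), (ns["yl"], 1, 0.0)])
        model.t = -2.0
        model.solve_step(-1.0, 1.0)
        rel = prestretch_and_release(model)
        assert np.abs(rel["forces"]).max() < 1e-9
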
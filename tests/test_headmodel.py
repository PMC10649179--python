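"""Mesh geometry, solid angles and the BEM forward solution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mieeg.headmodel import (
    BemSolver,
    Dipole,
    MeshError,
    assemble_bem_system,
    homogeneous_sphere_potential,
    infinite_medium_potential,
    lead_field,
    make_concentric_sphere_model,
    make_icosphere,
    solid_angle,
    solid_angles,
    standard_electrode_positions,
)
from mieeg.io import DEFAULT_CHANNELS


class TestIcosphere:
    def test_level2_combinatorics(self):
        m = make_icosphere(1.0, 2)
        assert m.n_triangles == 320
        assert len(m.vertices) == 162
        m.validate()

    def test_volume_converges_to_sphere(self):
        m = make_icosphere(0.08, 3)
        assert m.signed_volume() == pytest.approx(
            4 / 3 * np.pi * 0.08**3, rel=0.02)

    def test_nesting_and_bad_radii(self):
        model = make_concentric_sphere_model((0.08, 0.085, 0.092))
        r = [np.linalg.norm(s.vertices, axis=1).max() for s in model.shells]
        assert r[0] < r[1] < r[2]
        with pytest.raises(ValueError):
            make_concentric_sphere_model((0.09, 0.085, 0.092))


class TestInfiniteMediumPotential:
    def test_closed_form_value(self):
        dip = Dipole([0, 0, 0], [0, 0, 1e-8])
        u = infinite_medium_potential(dip, np.array([0, 0, 0.05]), 0.33)
        assert u == pytest.approx(1e-8 / (4 * np.pi * 0.33 * 0.05**2),
                                  rel=1e-12)

    def test_perpendicular_plane_is_zero(self):
        dip = Dipole([0, 0, 0], [0, 0, 1e-8])
        assert infinite_medium_potential(dip, np.array([0.03, -0.02, 0.0]),
                                         0.33) == pytest.approx(0.0, abs=1e-30)

    def test_antisymmetry_through_the_dipole(self):
        dip = Dipole([0.01, 0.0, 0.02], [1e-8, 2e-8, -1e-8])
        p = np.array([0.04, -0.01, 0.05])
        mirror = 2 * dip.position - p
        assert infinite_medium_potential(dip, p, 0.33) == pytest.approx(
            -infinite_medium_potential(dip, mirror, 0.33), rel=1e-12)

    def test_coincident_point_rejected(self):
        dip = Dipole([0, 0, 0], [0, 0, 1e-8])
        with pytest.raises(ZeroDivisionError):
            infinite_medium_potential(dip, np.zeros(3), 0.33)


class TestSolidAngle:
    @settings(max_examples=20, deadline=None)
    @given(st.tuples(*[st.floats(-0.5, 0.5) for _ in range(3)]))
    def test_closure_interior_and_exterior(self, p):
        mesh = make_icosphere(1.0, 2)
        p = np.asarray(p)
        if np.linalg.norm(p) > 0.9:
            p = p * 0.5
        inside = solid_angles(mesh.vertices, mesh.triangles, p).sum()
        outside = solid_angles(mesh.vertices, mesh.triangles,
                               p + [0.0, 0.0, 3.0]).sum()
        assert inside == pytest.approx(4 * np.pi, abs=1e-9)
        assert outside == pytest.approx(0.0, abs=1e-9)

    def test_small_distant_triangle_vs_numeric_integration(self):
        tri = np.array([[1.0, 0.0, 5.0], [1.01, 0.0, 5.0],
                        [1.0, 0.012, 5.0]])
        obs = np.array([0.3, -0.2, 0.1])
        # numerical surface-integration oracle: centroid rule over a
        # uniform barycentric subdivision of the triangle
        n = 60
        normal = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        area = np.linalg.norm(normal) / 2
        nhat = normal / (2 * area)
        total, count = 0.0, 0
        for i in range(n):
            for j in range(n - i):
                for a, b, keep in ((i + 1 / 3, j + 1 / 3, True),
                                   (i + 2 / 3, j + 2 / 3, j < n - i - 1)):
                    if not keep:
                        continue
                    pt = (tri[0] + (tri[1] - tri[0]) * a / n
                          + (tri[2] - tri[0]) * b / n)
                    r = pt - obs
                    total += (r @ nhat) / np.linalg.norm(r) ** 3
                    count += 1
        total *= area / count
        assert solid_angle(tri, obs) == pytest.approx(total, rel=0.01)

    def test_sign_follows_orientation(self):
        tri = np.array([[1.0, 0, 2.0], [0, 1.0, 2.0], [-1.0, -1.0, 2.0]])
        obs = np.zeros(3)
        assert solid_angle(tri, obs) == pytest.approx(
            -solid_angle(tri[::-1], obs), rel=1e-12)


class TestBemAssembly:
    def test_equal_conductivity_blocks_vanish(self):
        model = make_concentric_sphere_model(
            (0.08, 0.085, 0.092), (0.3, 0.3, 0.3), 1)
        B, _ = assemble_bem_system(model)
        n = model.shells[0].n_triangles
        # interfaces 0 and 1 have sigma- == sigma+ -> those column blocks
        # are exactly zero
        assert np.all(B[:, : 2 * n] == 0)
        assert np.any(B[:, 2 * n :] != 0)

    def test_constant_vector_is_null_direction(self):
        model = make_concentric_sphere_model(subdivision=1)
        B, _ = assemble_bem_system(model)
        ones = np.ones(len(B))
        np.testing.assert_allclose(B @ ones, ones, atol=1e-10)

    def test_open_surface_rejected(self):
        from mieeg.headmodel import ShellModel, TriMesh

        m = make_icosphere(0.08, 1)
        holed = TriMesh(m.vertices, m.triangles[:-1])
        with pytest.raises(MeshError):
            assemble_bem_system(ShellModel([holed], (0.33,)))


class TestForwardSolution:
    def test_linearity_superposition(self, level3_solver):
        el = standard_electrode_positions(list(DEFAULT_CHANNELS), 0.092)
        d1 = Dipole([0, 0, 0.05], [0, 0, 1e-8])
        d2 = Dipole([0, 0, 0.05], [5e-9, 0, 0])
        d12 = Dipole([0, 0, 0.05], [5e-9, 0, 1e-8])
        u1 = level3_solver.solve_forward(d1, el)
        u2 = level3_solver.solve_forward(d2, el)
        u12 = level3_solver.solve_forward(d12, el)
        np.testing.assert_allclose(u1 + u2, u12,
                                   atol=1e-10 * np.abs(u12).max())

    def test_conductivity_scaling(self):
        el = standard_electrode_positions(list(DEFAULT_CHANNELS), 0.092)
        dip = Dipole([0, 0, 0.05], [0, 0, 1e-8])
        c = 3.0
        u1 = BemSolver(make_concentric_sphere_model(
            (0.08, 0.085, 0.092), (0.33, 0.0042, 0.33), 1)
        ).solve_forward(dip, el)
        u2 = BemSolver(make_concentric_sphere_model(
            (0.08, 0.085, 0.092), (0.33 * c, 0.0042 * c, 0.33 * c), 1)
        ).solve_forward(dip, el)
        np.testing.assert_allclose(u2, u1 / c, rtol=1e-10)

    def test_dipole_outside_inner_shell_rejected(self, level3_solver):
        el = standard_electrode_positions(list(DEFAULT_CHANNELS), 0.092)
        with pytest.raises(ValueError):
            level3_solver.solve_forward(
                Dipole([0, 0, 0.083], [0, 0, 1e-8]), el)

    def test_accuracy_improves_with_subdivision(self):
        el = standard_electrode_positions(list(DEFAULT_CHANNELS), 0.092)
        dip = Dipole([0, 0, 0.056], [1e-8, 0, 0])
        u_ana = homogeneous_sphere_potential(dip, el, 0.092, 0.33)
        u_ana = u_ana - u_ana.mean()
        errs = []
        for level in (1, 2):
            solver = BemSolver(make_concentric_sphere_model(
                (0.08, 0.085, 0.092), (0.33, 0.33, 0.33), level))
            u = solver.solve_forward(dip, el)
            errs.append(np.linalg.norm(u - u_ana) / np.linalg.norm(u_ana))
        assert errs[1] < errs[0]


class TestLeadField:
    def test_column_equals_single_forward(self, bundle):
        lf = bundle.lead_field
        m = 17
        dip = Dipole(lf.source_space.vertices[m],
                     lf.source_space.normals[m])
        u = bundle.solver.solve_forward(dip, bundle.electrodes)
        np.testing.assert_allclose(lf.K[:, m], u,
                                   atol=1e-10 * np.abs(u).max())

    def test_columns_average_referenced(self, bundle):
        K = bundle.lead_field.K
        assert np.abs(K.mean(axis=0)).max() <= 1e-12 * np.abs(K).max()

    def test_superposition_u_equals_KJ(self, bundle):
        lf = bundle.lead_field
        J = np.zeros(lf.K.shape[1])
        J[3], J[100] = 2e-8, -1e-8
        u = lf.K @ J
        d3 = Dipole(lf.source_space.vertices[3],
                    2e-8 * lf.source_space.normals[3])
        d100 = Dipole(lf.source_space.vertices[100],
                      -1e-8 * lf.source_space.normals[100])
        u_direct = bundle.solver.solve_forward(d3, bundle.electrodes) \
            + bundle.solver.solve_forward(d100, bundle.electrodes)
        np.testing.assert_allclose(u, u_direct, atol=1e-10 * np.abs(u).max())

    def test_assembly_deterministic(self, bundle):
        lf2 = lead_field(bundle.solver, bundle.source_space,
                         bundle.electrodes, bundle.electrode_names)
        np.testing.assert_array_equal(lf2.K, bundle.lead_field.K)
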
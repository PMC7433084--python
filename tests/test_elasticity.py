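"""Element stiffness, assembly, boundary conditions and the solve path,
checked against closed forms and a dense brute-force oracle."""

import numpy as np
import pytest

from conftest import make_label_grid
from microfx.benchmarks import homogeneous_config, patch_test, two_layer_column
from microfx.elasticity import (
    SolverError,
    SparseSystem,
    apply_boundary_conditions,
    assemble,
    element_stiffness,
    solve,
)
from microfx.geometry import BaseConstraint, MaterialSpec, Region
from microfx.voxelmesh import build_hex_mesh, extract_node_sets, voxelize
from oracles import dense_assemble, dense_element_stiffness, dense_solve

UNIT_CUBE = np.array(
    [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]],
    dtype=float,
)


class TestElementStiffness:
    def test_six_rigid_body_modes(self):
        """A free element has exactly six zero-energy modes (rank 18)."""
        ke = element_stiffness(UNIT_CUBE, MaterialSpec("m", 123.0, 0.3))
        w = np.linalg.eigvalsh(ke)
        assert np.all(np.abs(w[:6]) < 1e-8 * w[-1])
        assert w[6] > 1e-8 * w[-1]

    def test_linearity_in_youngs_modulus(self):
        m1 = MaterialSpec("m", 100.0, 0.25)
        m2 = MaterialSpec("m", 200.0, 0.25)
        np.testing.assert_allclose(
            element_stiffness(UNIT_CUBE, m2), 2 * element_stiffness(UNIT_CUBE, m1), rtol=1e-14
        )

    @pytest.mark.parametrize("E, nu", [(1.0, 0.0), (17e3, 0.3), (700.0, 0.25)])
    def test_matches_dense_quadrature_oracle(self, E, nu):
        """Entry-wise agreement with an independent 3x3x3-point dense
        quadrature implementation (exact for trilinear elements)."""
        ke = element_stiffness(UNIT_CUBE, MaterialSpec("m", E, nu))
        ko = dense_element_stiffness(UNIT_CUBE, E, nu)
        np.testing.assert_allclose(ke, ko, atol=1e-10 * E)

    def test_stretched_box_matches_oracle(self):
        box = UNIT_CUBE * np.array([0.4, 0.4, 0.15])
        ke = element_stiffness(box, MaterialSpec("m", 17e3, 0.3))
        ko = dense_element_stiffness(box, 17e3, 0.3)
        np.testing.assert_allclose(ke, ko, rtol=1e-10)

    def test_inverted_element_rejected(self):
        bad = UNIT_CUBE.copy()
        bad[:, 2] *= -1  # left-handed
        with pytest.raises(SolverError):
            element_stiffness(bad, MaterialSpec("m", 1.0, 0.0))

    def test_symmetry(self):
        ke = element_stiffness(UNIT_CUBE * 0.31, MaterialSpec("m", 5.0, 0.4))
        np.testing.assert_allclose(ke, ke.T, rtol=0, atol=1e-12 * np.abs(ke).max())


class TestAssemble:
    def test_single_element_equals_element_matrix(self, unit_cube_mesh, soft_material):
        system = assemble(unit_cube_mesh, {Region.TRABECULAR: soft_material})
        conn = unit_cube_mesh.element_connectivity[0]
        dofs = (3 * conn[:, None] + np.arange(3)).ravel()  # element-local dof order
        K_local = system.stiffness.toarray()[np.ix_(dofs, dofs)]
        ke = element_stiffness(unit_cube_mesh.node_coordinates[conn], soft_material)
        np.testing.assert_allclose(K_local, ke, rtol=1e-12, atol=1e-12)

    def test_two_elements_match_dense_oracle(self, soft_material):
        solid = np.zeros((2, 1, 1), dtype=bool)
        solid[:, 0, 0] = True
        mesh = build_hex_mesh(make_label_grid(solid))
        system = assemble(mesh, {Region.TRABECULAR: soft_material})
        Ko = dense_assemble(
            mesh.node_coordinates,
            mesh.element_connectivity,
            soft_material.young_modulus,
            soft_material.poisson_ratio,
        )
        np.testing.assert_allclose(system.stiffness.toarray(), Ko, atol=1e-9)

    def test_eight_element_two_layer_matches_dense_oracle(self, two_by_two_mesh):
        mesh = build_hex_mesh(make_label_grid(np.ones((2, 2, 2)), plate_layers=1))
        plate = MaterialSpec("p", 17e3, 0.3)
        trab = MaterialSpec("t", 700.0, 0.3)
        system = assemble(mesh, {Region.PLATE: plate, Region.TRABECULAR: trab})
        E = np.where(mesh.element_layer == 2, 17e3, 700.0)
        Ko = dense_assemble(mesh.node_coordinates, mesh.element_connectivity, E, np.full(8, 0.3))
        np.testing.assert_allclose(system.stiffness.toarray(), Ko, rtol=1e-10, atol=1e-8)

    def test_rigid_modes_in_global_nullspace(self, two_by_two_mesh, soft_material):
        """Rigid translations and rotations produce no forces."""
        system = assemble(two_by_two_mesh, {Region.TRABECULAR: soft_material})
        K = system.stiffness
        X = two_by_two_mesh.node_coordinates
        n = X.shape[0]
        scale = np.abs(K.data).max()
        modes = []
        for d in range(3):  # translations
            u = np.zeros((n, 3))
            u[:, d] = 1.0
            modes.append(u)
        for axis in range(3):  # infinitesimal rotations about centroid
            c = X - X.mean(axis=0)
            u = np.cross(np.eye(3)[axis], c)
            modes.append(u)
        for u in modes:
            r = K @ u.ravel()
            assert np.abs(r).max() < 1e-8 * scale

    def test_missing_material_rejected(self, two_by_two_mesh, soft_material):
        with pytest.raises(ValueError):
            assemble(two_by_two_mesh, {Region.PLATE: soft_material})


class TestBoundaryConditions:
    def _system(self, config):
        mesh = build_hex_mesh(voxelize(config))
        sets = extract_node_sets(mesh, config)
        mats = {
            Region.PLATE: config.layer_stack.plate_material,
            Region.TRABECULAR: config.layer_stack.trabecular_material,
        }
        return mesh, sets, assemble(mesh, mats)

    def test_load_vector_statics(self, coarse_block_config):
        mesh, sets, system = self._system(coarse_block_config)
        bc = apply_boundary_conditions(system, sets)
        f = bc.load_vector.reshape(-1, 3)
        np.testing.assert_allclose(f[:, 2].sum(), 147.0, rtol=1e-12)
        assert f[:, 0].sum() == 0.0 and f[:, 1].sum() == 0.0

    def test_doubling_force_doubles_load_vector(self, coarse_block_config):
        from dataclasses import replace
        from microfx.geometry import LoadCase

        mesh, sets, system = self._system(coarse_block_config)
        bc1 = apply_boundary_conditions(system, sets)
        cfg2 = replace(coarse_block_config, load_case=LoadCase(total_force=294.0))
        sets2 = extract_node_sets(mesh, cfg2)
        bc2 = apply_boundary_conditions(system, sets2)
        np.testing.assert_allclose(bc2.load_vector, 2 * bc1.load_vector, rtol=1e-12)

    def test_empty_bottom_set_rejected(self, coarse_block_config):
        import dataclasses

        mesh, sets, system = self._system(coarse_block_config)
        bad = dataclasses.replace(sets, bottom_surface=np.empty(0, dtype=int))
        with pytest.raises(SolverError):
            apply_boundary_conditions(system, bad)

    def test_unconstrained_solve_rejected(self, coarse_block_config):
        _, _, system = self._system(coarse_block_config)
        with pytest.raises(SolverError):
            solve(system)


class TestSolve:
    def test_patch_test_machine_precision(self):
        """Homogeneous nu=0 block under uniform pressure on rollers:
        sigma_zz = -p to machine precision at any resolution."""
        for voxel in (1.0, 0.5):
            out = patch_test(homogeneous_config(voxel_lateral=voxel, voxel_vertical=voxel / 2))
            assert out["max_szz_error_MPa"] < 1e-10 * out["pressure_MPa"]
            assert out["max_other_component_MPa"] < 1e-10 * out["pressure_MPa"]

    def test_two_layer_series_spring_closed_form(self):
        """Mean top settlement of the nu=0 two-layer column matches
        (F/A)(t_p/E_p + t_t/E_t) within 0.1% (coarse voxels: the state is
        piecewise uniform, so even a coarse mesh is nearly exact)."""
        out = two_layer_column(voxel_lateral=2.0)
        assert out["relative_error"] < 1e-3
        assert out["closed_form_mm"] == pytest.approx(6.33e-3, rel=0.02)

    def test_zero_load_zero_displacement(self, coarse_block_config):
        mesh = build_hex_mesh(voxelize(coarse_block_config))
        sets = extract_node_sets(mesh, coarse_block_config)
        mats = {
            Region.PLATE: coarse_block_config.layer_stack.plate_material,
            Region.TRABECULAR: coarse_block_config.layer_stack.trabecular_material,
        }
        system = assemble(mesh, mats)
        bc = apply_boundary_conditions(system, sets)
        bc = SparseSystem(bc.stiffness, np.zeros_like(bc.load_vector), bc.constrained_dofs)
        disp = solve(bc)
        assert np.all(disp.values == 0.0)

    def test_linearity_in_load(self, coarse_block_config):
        from dataclasses import replace
        from microfx.geometry import LoadCase
        from microfx.pipeline import solve_config

        _, d1, _, _ = solve_config(coarse_block_config)
        cfg2 = replace(coarse_block_config, load_case=LoadCase(total_force=294.0))
        _, d2, _, _ = solve_config(cfg2)
        np.testing.assert_allclose(d2.values, 2 * d1.values, rtol=1e-8, atol=1e-16)

    def test_reactions_balance_load(self, coarse_block_config):
        from microfx.pipeline import solve_config

        _, disp, _, _ = solve_config(coarse_block_config)
        np.testing.assert_allclose(disp.reaction_sum[2], -147.0, rtol=1e-6)
        assert abs(disp.reaction_sum[0]) < 1e-6 * 147
        assert abs(disp.reaction_sum[1]) < 1e-6 * 147

    def test_displacements_match_dense_oracle_on_tiny_meshes(self):
        """<= 8 element meshes: sparse path vs dense brute force, 1e-8."""
        mesh = build_hex_mesh(make_label_grid(np.ones((2, 2, 2)), plate_layers=1))
        plate = MaterialSpec("p", 17e3, 0.3)
        trab = MaterialSpec("t", 700.0, 0.3)
        system = assemble(mesh, {Region.PLATE: plate, Region.TRABECULAR: trab})
        coords = mesh.node_coordinates
        bottom = np.flatnonzero(coords[:, 2] == 2.0)
        top = np.flatnonzero(coords[:, 2] == 0.0)
        f = np.zeros(3 * mesh.n_nodes)
        f[3 * top + 2] = 1.0
        constrained = np.concatenate([3 * bottom, 3 * bottom + 1, 3 * bottom + 2])
        disp = solve(SparseSystem(system.stiffness, f, constrained))
        E = np.where(mesh.element_layer == 2, 17e3, 700.0)
        Ko = dense_assemble(coords, mesh.element_connectivity, E, np.full(8, 0.3))
        uo = dense_solve(Ko, f, constrained)
        np.testing.assert_allclose(disp.values.ravel(), uo, rtol=1e-8, atol=1e-12 * np.abs(uo).max())

    def test_roller_base_requires_coordinates(self, coarse_block_config):
        mesh, sets, system = (None, None, None)
        mesh = build_hex_mesh(voxelize(coarse_block_config))
        sets = extract_node_sets(mesh, coarse_block_config)
        mats = {
            Region.PLATE: coarse_block_config.layer_stack.plate_material,
            Region.TRABECULAR: coarse_block_config.layer_stack.trabecular_material,
        }
        system = assemble(mesh, mats)
        with pytest.raises(ValueError):
            apply_boundary_conditions(system, sets, base_constraint=BaseConstraint.ROLLER_Z)
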
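"""Voxelization, hexahedral mesh construction and boundary node sets."""

import math

import numpy as np
import pytest

from conftest import make_label_grid
from microfx.geometry import (
    HolePattern,
    LayerStack,
    LoadApplication,
    LoadCase,
    MaterialSpec,
    ModelConfig,
    Region,
    default_config,
)
from microfx.voxelmesh import (
    DiscontinuityError,
    VoxelGrid,
    build_hex_mesh,
    extract_node_sets,
    voxelize,
)


class TestVoxelize:
    def test_intact_fast_grid_dimensions(self):
        """16x16x8 mm at 0.4/0.15 mm voxels: 40x40x54 grid (vertical count
        rounds up so the grid covers the block exactly), no voids, and the
        top two voxel layers are plate."""
        grid = voxelize(default_config())
        assert grid.dims == (40, 40, 54)
        assert grid.count(Region.HOLE_VOID) == 0
        assert grid.count(Region.OUTSIDE) == 0
        labels = grid.data
        assert np.all(labels[:, :, :2] == 2)
        assert np.all(labels[:, :, 2:] == 1)

    def test_void_volume_close_to_analytic_cylinder(self):
        """One 1 mm hole, 4 mm deep, at 0.1 mm voxels: voxelized void volume
        within 5% of pi r^2 h."""
        cfg = ModelConfig(
            hole_pattern=HolePattern(spacing=10.0, hole_diameter=1.0, hole_depth=4.0),
            voxel_size_lateral=0.1,
            voxel_size_vertical=0.1,
            label="one_hole",
        )
        grid = voxelize(cfg)
        void = grid.count(Region.HOLE_VOID) * grid.voxel_volume
        analytic = math.pi * 0.5**2 * 4.0
        assert void == pytest.approx(analytic, rel=0.05)

    def test_degenerate_two_cube_grid(self):
        cfg = ModelConfig(
            layer_stack=LayerStack(plate_thickness=1.0, trabecular_thickness=1.0,
                                   lateral_extent_x=2.0, lateral_extent_y=2.0),
            voxel_size_lateral=1.0,
            voxel_size_vertical=0.5,
            label="tiny",
        )
        grid = voxelize(cfg)
        assert grid.dims == (2, 2, 4)
        assert int(grid.solid_mask.sum()) == 16

    def test_refuses_fewer_than_two_plate_elements(self):
        with pytest.raises(ValueError):
            ModelConfig(voxel_size_vertical=0.16)  # ceil gives dz > 0.15


class TestBuildHexMesh:
    @pytest.mark.parametrize("shape, n_elem, n_nodes", [((1, 1, 1), 1, 8), ((2, 2, 2), 8, 27)])
    def test_structured_counts(self, shape, n_elem, n_nodes):
        mesh = build_hex_mesh(make_label_grid(np.ones(shape)))
        assert mesh.n_elements == n_elem
        assert mesh.n_nodes == n_nodes

    def test_edge_sharing_voxels_raise_discontinuity(self):
        solid = np.zeros((2, 2, 2), dtype=bool)
        solid[0, 0, 0] = solid[1, 1, 0] = True  # share only an edge
        with pytest.raises(DiscontinuityError):
            build_hex_mesh(make_label_grid(solid))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            build_hex_mesh(make_label_grid(np.zeros((2, 2, 2), dtype=bool)))

    def test_largest_component_cleanup_enables_meshing(self):
        from microfx.voxelmesh import largest_connected_component

        solid = np.zeros((5, 5, 5), dtype=bool)
        solid[:3, :3, :3] = True  # 27-voxel main block
        solid[4, 4, 4] = True  # floating island
        grid = make_label_grid(solid)
        with pytest.raises(DiscontinuityError):
            build_hex_mesh(grid)
        cleaned = largest_connected_component(grid)
        mesh = build_hex_mesh(cleaned)
        assert mesh.n_elements == 27
        # already-connected grids pass through unchanged
        ok = make_label_grid(np.ones((2, 2, 2)))
        assert largest_connected_component(ok) is ok

    def test_node_dedup_bound(self):
        """Total nodes <= (nx+1)(ny+1)(nz+1), equality iff fully solid."""
        full = build_hex_mesh(make_label_grid(np.ones((3, 3, 3))))
        assert full.n_nodes == 4**3
        solid = np.ones((3, 3, 3), dtype=bool)
        solid[0, 0, 0] = False  # corner voxel owns one lattice node exclusively
        partial = build_hex_mesh(make_label_grid(solid))
        assert partial.n_nodes < 4**3

    def test_volume_conservation(self):
        cfg = default_config(hole_pattern=HolePattern(spacing=3.0))
        grid = voxelize(cfg)
        mesh = build_hex_mesh(grid)
        total = mesh.element_volumes().sum()
        expected = int(grid.solid_mask.sum()) * grid.voxel_volume
        assert total == pytest.approx(expected, rel=1e-12)

    def test_positive_jacobian_ordering(self, unit_cube_mesh):
        """Connectivity must give a positive Jacobian (right-handed)."""
        from microfx.elasticity import element_stiffness

        mat = MaterialSpec("m", 1.0, 0.0)
        corners = unit_cube_mesh.node_coordinates[unit_cube_mesh.element_connectivity[0]]
        element_stiffness(corners, mat)  # raises on inverted elements

    def test_layer_labels_copied(self):
        mesh = build_hex_mesh(make_label_grid(np.ones((2, 2, 4)), plate_layers=2))
        assert int(mesh.layer_mask(Region.PLATE).sum()) == 8
        assert int(mesh.layer_mask(Region.TRABECULAR).sum()) == 8

    def test_study_configs_are_connected_at_default_resolution(self):
        """All eight study configurations must mesh into one face-connected
        component (checked cheaply via the hole-free base grid plus each
        spacing's voxelization succeeding)."""
        from microfx.geometry import make_study_configs

        for cfg in make_study_configs():
            build_hex_mesh(voxelize(cfg))  # DiscontinuityError would fail


class TestNodeSets:
    def test_full_face_load_covers_all_top_nodes(self, coarse_block_config):
        mesh = build_hex_mesh(voxelize(coarse_block_config))
        sets = extract_node_sets(mesh, coarse_block_config)
        assert sets.loaded_nodes.size == 9 * 9  # (8+1)^2 top nodes
        assert sets.loaded_forces.sum() == pytest.approx(147.0, rel=1e-12)
        assert sets.bottom_surface.size == 9 * 9

    def test_interior_nodes_carry_four_times_corner_share(self, coarse_block_config):
        mesh = build_hex_mesh(voxelize(coarse_block_config))
        sets = extract_node_sets(mesh, coarse_block_config)
        shares = sets.loaded_forces
        assert shares.max() == pytest.approx(4 * shares.min(), rel=1e-12)

    def test_hole_rim_top_carries_no_traction(self):
        cfg = default_config(hole_pattern=HolePattern(spacing=10.0))
        mesh = build_hex_mesh(voxelize(cfg))
        sets = extract_node_sets(mesh, cfg)
        coords = mesh.node_coordinates
        center = np.array([8.0, 8.0])
        # nodes strictly inside the hole opening are absent from the mesh;
        # total load is still carried, renormalised over the annular face
        assert sets.loaded_forces.sum() == pytest.approx(147.0, rel=1e-12)
        loaded_xy = coords[sets.loaded_nodes][:, :2]
        r = np.linalg.norm(loaded_xy - center, axis=1)
        interior = r < 0.5 - max(mesh.uniform_element_size[:2])
        assert not interior.any()

    def test_patch_footprints(self, coarse_block_config):
        from dataclasses import replace

        mesh = build_hex_mesh(voxelize(coarse_block_config))
        for app in (LoadApplication.UNIFORM_PATCH, LoadApplication.HERTZIAN_PATCH):
            cfg = replace(
                coarse_block_config,
                load_case=LoadCase(total_force=147.0, application=app, patch_radius=2.0),
            )
            sets = extract_node_sets(mesh, cfg)
            assert sets.loaded_forces.sum() == pytest.approx(147.0, rel=1e-12)
            loaded_xy = mesh.node_coordinates[sets.loaded_nodes][:, :2]
            assert np.linalg.norm(loaded_xy - 4.0, axis=1).max() <= 2.0 + 1.5

    def test_footprint_outside_block_errors(self, coarse_block_config):
        from dataclasses import replace

        mesh = build_hex_mesh(voxelize(coarse_block_config))
        cfg = replace(
            coarse_block_config,
            load_case=LoadCase(
                total_force=1.0, application=LoadApplication.UNIFORM_PATCH, patch_radius=0.01
            ),
        )
        with pytest.raises(ValueError):
            extract_node_sets(mesh, cfg)

    def test_top_bottom_disjoint(self, coarse_block_config):
        mesh = build_hex_mesh(voxelize(coarse_block_config))
        sets = extract_node_sets(mesh, coarse_block_config)
        assert np.intersect1d(sets.top_surface, sets.bottom_surface).size == 0
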
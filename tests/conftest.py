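"""Shared fixtures: tiny meshes and coarse configurations.

Everything here is generated programmatically; the expensive fast-preset
experiment is session-scoped so the acceptance tests share one run.
"""

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from microfx.geometry import (
    HolePattern,
    LayerStack,
    LoadCase,
    MaterialSpec,
    ModelConfig,
)
from microfx.voxelmesh import VoxelGrid, build_hex_mesh


def make_label_grid(solid: np.ndarray, voxel_size=(1.0, 1.0, 1.0), plate_layers: int = 0) -> VoxelGrid:
    """Label grid from a boolean solid mask; top `plate_layers` slices of
    solid voxels get the plate label."""
    solid = np.asarray(solid, dtype=bool)
    labels = np.where(solid, 1, 0).astype(np.uint8)
    if plate_layers:
        plate = solid.copy()
        plate[:, :, plate_layers:] = False
        labels[plate] = 2
    return VoxelGrid(dims=solid.shape, voxel_size=voxel_size, data=labels, kind="labels")


@pytest.fixture
def unit_cube_mesh():
    """One 1 mm element."""
    return build_hex_mesh(make_label_grid(np.ones((1, 1, 1))))


@pytest.fixture
def two_by_two_mesh():
    """2x2x2 fully solid grid: 8 elements, 27 nodes."""
    return build_hex_mesh(make_label_grid(np.ones((2, 2, 2))))


@pytest.fixture
def soft_material():
    return MaterialSpec("soft", 1000.0, 0.3, yield_stress=10.0)


@pytest.fixture
def coarse_block_config():
    """A small two-layer block solvable in well under a second.

    8 x 8 mm block, 2 mm thick plate so coarse voxels still give two
    elements through the plate; geometry differs from the study defaults
    but exercises the identical code path.
    """
    plate = MaterialSpec("plate", 17_000.0, 0.3, yield_stress=135.0)
    trab = MaterialSpec("trab", 700.0, 0.3)
    stack = LayerStack(
        plate_thickness=2.0,
        trabecular_thickness=4.0,
        lateral_extent_x=8.0,
        lateral_extent_y=8.0,
        plate_material=plate,
        trabecular_material=trab,
    )
    return ModelConfig(
        layer_stack=stack,
        load_case=LoadCase(total_force=147.0),
        voxel_size_lateral=1.0,
        voxel_size_vertical=1.0,
        label="coarse_block",
    )


@pytest.fixture
def small_template(coarse_block_config):
    """Experiment template whose eight derived configurations solve fast:
    2 mm holes in a 4x4 mm defect on the small coarse block."""
    from dataclasses import replace

    return replace(
        coarse_block_config,
        voxel_size_lateral=0.5,
        voxel_size_vertical=1.0,
        hole_pattern=HolePattern(spacing=1.0, hole_diameter=2.0, hole_depth=3.0,
                                 defect_extent_x=4.0, defect_extent_y=4.0),
    )


@pytest.fixture(scope="session")
def fast_experiment():
    """The eight-configuration experiment at the fast preset (shared)."""
    from microfx.pipeline import run_spacing_experiment

    return run_spacing_experiment(preset="fast", seed=0)
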
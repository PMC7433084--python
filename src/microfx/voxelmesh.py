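"""Voxelization of the block model and labelled hexahedral mesh construction.

Each solid voxel (plate or trabecular) becomes one 8-node hexahedral
element; hole voids and outside voxels carry no elements.  Meshing is
deterministic: voxels are labelled by the region of their centroid, nodes
are numbered lexicographically, and elements follow the voxel raster
order.  The jagged, stair-stepped hole walls this produces are a known
property of image-based meshes; their effect on peak stresses is
quantified by the mesh-convergence study in the pipeline module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .geometry import (
    CODE_REGIONS,
    REGION_CODES,
    LoadApplication,
    ModelConfig,
    Region,
    membership_grid,
)

__all__ = [
    "VoxelGrid",
    "HexMesh",
    "NodeSets",
    "DiscontinuityError",
    "voxelize",
    "largest_connected_component",
    "build_hex_mesh",
    "extract_node_sets",
]

SOLID_CODES = (REGION_CODES[Region.TRABECULAR], REGION_CODES[Region.PLATE])

# 6-connectivity structuring element (faces only, no edges/corners)
_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


class DiscontinuityError(RuntimeError):
    """Solid region is not a single face-connected component.

    This is the failure mode that plagues image-derived bone models: a
    disconnected piece of the plate or trabecular network makes the
    stiffness matrix singular and the structural analysis unsolvable.
    """


@dataclass
class VoxelGrid:
    """A regular voxel volume, either labelled regions or grayscale.

    ``data[ix, iy, iz]`` with ``iz`` increasing downward from the top
    surface.  For label grids the codes are
    ``{0: outside/background, 1: trabecular, 2: plate, 3: hole_void}``.
    """

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    data: np.ndarray
    kind: str = "labels"  # "labels" | "intensity"

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.dims):
            raise ValueError(f"dims must all be >= 1, got {self.dims}")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size}")
        if tuple(self.data.shape) != tuple(self.dims):
            raise ValueError(f"data shape {self.data.shape} does not match dims {self.dims}")

    @property
    def solid_mask(self) -> np.ndarray:
        if self.kind != "labels":
            raise ValueError("solid_mask requires a label grid; segment the volume first")
        return np.isin(self.data, SOLID_CODES)

    def count(self, region: Region) -> int:
        return int(np.count_nonzero(self.data == REGION_CODES[region]))

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz


def voxelize(config: ModelConfig) -> VoxelGrid:
    """Rasterise a model configuration onto a voxel grid.

    Voxel counts are chosen so the grid covers the block exactly: the
    actual voxel size is the extent divided by ``ceil(extent / requested)``
    and is therefore never coarser than requested.  Each voxel is labelled
    by the region of its centroid.
    """
    stack = config.layer_stack
    lat = config.voxel_size_lateral
    nx = int(np.ceil(stack.lateral_extent_x / lat - 1e-9))
    ny = int(np.ceil(stack.lateral_extent_y / lat - 1e-9))
    nz = int(np.ceil(stack.total_height / config.voxel_size_vertical - 1e-9))
    dx = stack.lateral_extent_x / nx
    dy = stack.lateral_extent_y / ny
    dz = stack.total_height / nz
    if stack.plate_thickness / dz < 2.0 - 1e-12:
        raise ValueError(
            f"vertical voxel size {dz:.4g} mm leaves fewer than two elements "
            f"through the {stack.plate_thickness} mm plate"
        )
    xc = (np.arange(nx) + 0.5) * dx
    yc = (np.arange(ny) + 0.5) * dy
    zc = (np.arange(nz) + 0.5) * dz
    labels = membership_grid(xc, yc, zc, config)
    return VoxelGrid(dims=(nx, ny, nz), voxel_size=(dx, dy, dz), data=labels, kind="labels")


def largest_connected_component(grid: VoxelGrid) -> VoxelGrid:
    """Keep only the largest face-connected solid component of a label grid.

    Segmented trabecular bone routinely contains small disconnected
    islands (noise voxels, severed struts); image-based FE practice
    removes everything but the main load-bearing network before meshing.
    Removed voxels become background; the cleanup is logged.
    """
    import logging

    solid = grid.solid_mask
    labels, n_comp = ndimage.label(solid, structure=_FACE_STRUCTURE)
    if n_comp <= 1:
        return grid
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = int(np.argmax(sizes))
    cleaned = np.where(labels == keep, grid.data, 0).astype(grid.data.dtype)
    removed = int(solid.sum() - sizes[keep])
    logging.getLogger(__name__).info(
        "largest_connected_component: kept %d voxels, removed %d across %d islands",
        int(sizes[keep]), removed, n_comp - 1,
    )
    return VoxelGrid(dims=grid.dims, voxel_size=grid.voxel_size, data=cleaned, kind="labels")


@dataclass
class HexMesh:
    """Voxel-derived hexahedral mesh.

    ``element_connectivity`` rows list the 8 node indices of one element in
    the standard right-handed hexahedron ordering (four nodes of the
    shallower face counter-clockwise, then the four below them); the
    resulting Jacobian is positive everywhere for axis-aligned boxes.
    ``element_layer`` holds the region code (1 trabecular, 2 plate).
    """

    node_coordinates: np.ndarray  # (n_nodes, 3) mm
    element_connectivity: np.ndarray  # (n_elements, 8) int
    element_layer: np.ndarray  # (n_elements,) uint8 region codes
    uniform_element_size: Optional[tuple[float, float, float]] = None
    # provenance of voxel-derived meshes, used for fast stencil assembly:
    # per-element (ix, iy, iz) voxel indices and the source grid dims
    voxel_indices: Optional[np.ndarray] = None
    lattice_dims: Optional[tuple[int, int, int]] = None

    @property
    def n_nodes(self) -> int:
        return self.node_coordinates.shape[0]

    @property
    def n_elements(self) -> int:
        return self.element_connectivity.shape[0]

    def layer_mask(self, layer: Region) -> np.ndarray:
        return self.element_layer == REGION_CODES[layer]

    def element_centroids(self) -> np.ndarray:
        return self.node_coordinates[self.element_connectivity].mean(axis=1)

    def element_volumes(self) -> np.ndarray:
        if self.uniform_element_size is not None:
            dx, dy, dz = self.uniform_element_size
            return np.full(self.n_elements, dx * dy * dz)
        corners = self.node_coordinates[self.element_connectivity]
        # axis-aligned boxes: |(x1-x0)(y3-y0)(z4-z0)| per local ordering
        return np.abs(
            (corners[:, 1, 0] - corners[:, 0, 0])
            * (corners[:, 3, 1] - corners[:, 0, 1])
            * (corners[:, 4, 2] - corners[:, 0, 2])
        )


def build_hex_mesh(grid: VoxelGrid) -> HexMesh:
    """Turn every solid voxel of a label grid into a hexahedral element.

    Shared nodes are deduplicated; node numbering is lexicographic in
    (ix, iy, iz) so repeated runs are bit-identical.

    Raises
    ------
    DiscontinuityError
        If the solid voxels do not form one face-connected component.
    ValueError
        If the grid contains no solid voxel.
    """
    solid = grid.solid_mask
    n_solid = int(solid.sum())
    if n_solid == 0:
        raise ValueError("grid has no solid voxel")
    _, n_comp = ndimage.label(solid, structure=_FACE_STRUCTURE)
    if n_comp != 1:
        raise DiscontinuityError(
            f"solid region splits into {n_comp} face-connected components; "
            "a disconnected mesh makes the structural analysis singular"
        )

    nx, ny, nz = grid.dims
    dx, dy, dz = grid.voxel_size

    # mark used corner nodes on the (nx+1, ny+1, nz+1) node lattice
    used = np.zeros((nx + 1, ny + 1, nz + 1), dtype=bool)
    ix, iy, iz = np.nonzero(solid)
    for ox in (0, 1):
        for oy in (0, 1):
            for oz in (0, 1):
                used[ix + ox, iy + oy, iz + oz] = True
    node_id = np.full(used.shape, -1, dtype=np.int64)
    node_id.ravel()[np.flatnonzero(used.ravel())] = np.arange(used.sum())

    gx, gy, gz = np.nonzero(used)
    node_coordinates = np.column_stack([gx * dx, gy * dy, gz * dz]).astype(float)

    # standard hex ordering: shallow face CCW (z = iz), then deep face (z = iz+1)
    offsets = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)]
    conn = np.empty((n_solid, 8), dtype=np.int64)
    for k, (ox, oy, oz) in enumerate(offsets):
        conn[:, k] = node_id[ix + ox, iy + oy, iz + oz]

    element_layer = grid.data[ix, iy, iz].astype(np.uint8)
    return HexMesh(
        node_coordinates=node_coordinates,
        element_connectivity=conn,
        element_layer=element_layer,
        uniform_element_size=(dx, dy, dz),
        voxel_indices=np.column_stack([ix, iy, iz]).astype(np.int32),
        lattice_dims=(nx, ny, nz),
    )


@dataclass
class NodeSets:
    """Boundary node sets and consistent nodal load shares.

    ``loaded_forces[i]`` is the downward (+z, toward the fixed base) force
    share in N carried by ``loaded_nodes[i]``; the shares sum to the total
    applied force exactly (they are renormalised after footprint masking).
    """

    top_surface: np.ndarray
    bottom_surface: np.ndarray
    loaded_nodes: np.ndarray
    loaded_forces: np.ndarray

    def __post_init__(self) -> None:
        if np.intersect1d(self.top_surface, self.bottom_surface).size:
            raise ValueError("top and bottom node sets overlap")


def extract_node_sets(mesh: HexMesh, config: ModelConfig) -> NodeSets:
    """Locate the fixed base, the articular top surface, and the load.

    The base is the set of nodes at maximal depth (all fixed).  Traction
    acts on the top faces of surface voxels at depth zero — hole openings
    carry none — using the footprint of the configured load case, with
    one quarter of each face's share accumulated to each face node
    (tributary areas of a constant pressure on bilinear faces).
    """
    coords = mesh.node_coordinates
    z = coords[:, 2]
    z_max = z.max()
    dz = mesh.uniform_element_size[2] if mesh.uniform_element_size else np.diff(np.unique(z)).min()
    tol = 1e-6 * max(z_max, dz)
    bottom = np.flatnonzero(z >= z_max - tol)
    top = np.flatnonzero(z <= tol)
    if top.size == 0 or bottom.size == 0:
        raise ValueError("mesh has no top or bottom surface nodes")

    # top faces: elements whose shallow face lies at z = 0
    conn = mesh.element_connectivity
    shallow_z = coords[conn[:, 0], 2]
    top_elems = np.flatnonzero(shallow_z <= tol)
    if top_elems.size == 0:
        raise ValueError("no element face on the articular surface")
    face_nodes = conn[np.ix_(top_elems, [0, 1, 2, 3])]
    face_centroids = coords[face_nodes].mean(axis=1)[:, :2]

    stack = config.layer_stack
    center = np.array([stack.lateral_extent_x / 2.0, stack.lateral_extent_y / 2.0])
    rho = np.linalg.norm(face_centroids - center, axis=1)

    lc = config.load_case
    if lc.application is LoadApplication.UNIFORM_FULL_FACE:
        weights = np.ones(top_elems.size)
    elif lc.application is LoadApplication.UNIFORM_PATCH:
        weights = (rho <= lc.patch_radius).astype(float)
    else:  # hertzian pressure profile p(rho) ~ sqrt(1 - rho^2/R^2)
        weights = np.sqrt(np.clip(1.0 - (rho / lc.patch_radius) ** 2, 0.0, None))
    total_w = weights.sum()
    if total_w <= 0:
        raise ValueError(f"load footprint of {lc.application.value} covers no surface face")

    # uniform face areas on a voxel grid: weights alone set the shares
    face_force = lc.total_force * weights / total_w
    shares = np.zeros(mesh.n_nodes)
    np.add.at(shares, face_nodes.ravel(), np.repeat(face_force / 4.0, 4))
    loaded = np.flatnonzero(shares > 0)
    forces = shares[loaded]
    forces *= lc.total_force / forces.sum()  # exact renormalisation
    return NodeSets(top_surface=top, bottom_surface=bottom, loaded_nodes=loaded, loaded_forces=forces)
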
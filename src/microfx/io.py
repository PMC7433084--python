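"""Readers and writers: legacy-VTK meshes, TIFF stacks, raw volumes.

Volumes travel either as TIFF stacks (page order = depth slices, top
first) or as raw little-endian binary with a JSON sidecar recording
dtype, dimensions, voxel size and the label map.  Meshes and cell fields
are written as legacy ASCII VTK unstructured grids (cell type 12,
hexahedron), which ParaView and VTK-based tools read directly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import tifffile

from .voxelmesh import HexMesh, VoxelGrid

__all__ = [
    "write_vtk_mesh",
    "write_tiff_stack",
    "read_tiff_stack",
    "write_raw_volume",
    "read_raw_volume",
    "LABEL_MAP",
]

#: Voxel label semantics shared across the package.
LABEL_MAP = {"0": "background", "1": "trabecular", "2": "plate", "3": "hole_void"}


def write_vtk_mesh(
    mesh: HexMesh,
    path: str | Path,
    cell_data: Optional[Mapping[str, np.ndarray]] = None,
    point_data: Optional[Mapping[str, np.ndarray]] = None,
) -> None:
    """Write a hexahedral mesh with optional fields as legacy ASCII VTK."""
    path = Path(path)
    lines: list[str] = [
        "# vtk DataFile Version 3.0",
        "microfx hexahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines.extend(" ".join(f"{c:.9g}" for c in row) for row in mesh.node_coordinates)
    ne = mesh.n_elements
    lines.append(f"CELLS {ne} {9 * ne}")
    lines.extend("8 " + " ".join(str(i) for i in row) for row in mesh.element_connectivity)
    lines.append(f"CELL_TYPES {ne}")
    lines.extend("12" for _ in range(ne))

    def _field_block(name: str, arr: np.ndarray) -> list[str]:
        arr = np.asarray(arr)
        if arr.ndim == 1:
            block = [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
            block.extend(f"{v:.9g}" for v in arr)
        else:
            block = [f"SCALARS {name} double {arr.shape[1]}", "LOOKUP_TABLE default"]
            block.extend(" ".join(f"{v:.9g}" for v in row) for row in arr)
        return block

    all_cell = {"element_layer": mesh.element_layer.astype(float)}
    if cell_data:
        all_cell.update(cell_data)
    lines.append(f"CELL_DATA {ne}")
    for name, arr in all_cell.items():
        lines.extend(_field_block(name, arr))
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in point_data.items():
            lines.extend(_field_block(name, arr))
    path.write_text("\n".join(lines) + "\n")


def _sidecar(grid: VoxelGrid, dtype: str) -> dict:
    return {
        "dims": list(grid.dims),
        "voxel_size_mm": list(grid.voxel_size),
        "kind": grid.kind,
        "dtype": dtype,
        "axis_order": "zyx pages = depth slices, top first",
        "label_map": LABEL_MAP if grid.kind == "labels" else None,
    }


def write_tiff_stack(grid: VoxelGrid, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF (+ JSON sidecar next to it)."""
    path = Path(path)
    pages = np.ascontiguousarray(np.transpose(grid.data, (2, 1, 0)))  # (z, y, x)
    tifffile.imwrite(path, pages)
    Path(str(path) + ".json").write_text(json.dumps(_sidecar(grid, str(grid.data.dtype)), indent=2))


def read_tiff_stack(path: str | Path) -> VoxelGrid:
    path = Path(path)
    pages = tifffile.imread(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    data = np.transpose(pages, (2, 1, 0))
    return VoxelGrid(
        dims=tuple(meta["dims"]),
        voxel_size=tuple(meta["voxel_size_mm"]),
        data=np.ascontiguousarray(data),
        kind=meta["kind"],
    )


def write_raw_volume(grid: VoxelGrid, path: str | Path) -> None:
    """Write a volume as raw little-endian binary with a JSON sidecar."""
    path = Path(path)
    data = np.ascontiguousarray(grid.data)
    data.tofile(path)
    Path(str(path) + ".json").write_text(json.dumps(_sidecar(grid, str(data.dtype)), indent=2))


def read_raw_volume(path: str | Path) -> VoxelGrid:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    dims = tuple(meta["dims"])
    data = np.fromfile(path, dtype=np.dtype(meta["dtype"])).reshape(dims)
    return VoxelGrid(dims=dims, voxel_size=tuple(meta["voxel_size_mm"]), data=data, kind=meta["kind"])
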
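"""Stress recovery, von Mises fields, layer peaks and safety factors.

Stresses are evaluated once per element at its centroid from the shape
function gradients — no nodal averaging or extrapolation — which is
deterministic and keeps voxel-edge artefacts local.  Safety factors
follow the convention of the study this pipeline reproduces: peak von
Mises stress in the subchondral plate divided by its yield stress
(135 MPa), with values below 1 read as structurally safe.  Alongside the
raw layer maximum a 99.9th-percentile "robust" peak is reported, because
stair-stepped hole rims on voxel meshes can carry isolated artificial
spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Optional

import numpy as np

from .elasticity import DisplacementField, centroid_b_matrix, isotropic_elasticity_matrix, _material_table
from .geometry import REGION_CODES, Region
from .voxelmesh import HexMesh

__all__ = [
    "StressField",
    "LayerPeak",
    "SafetyReport",
    "recover_stress",
    "von_mises",
    "peak_in_layer",
    "safety_factor",
]

#: Voigt component order used throughout.
VOIGT = ("xx", "yy", "zz", "xy", "yz", "zx")


@dataclass
class StressField:
    """Per-element centroid stress tensors, Voigt order (6,), MPa."""

    components: np.ndarray  # (n_elements, 6)
    von_mises: np.ndarray  # (n_elements,)


@dataclass
class LayerPeak:
    value: float  # MPa
    element_index: int
    coordinates: np.ndarray  # centroid, mm
    robust_value: float  # 99.9th percentile, MPa


@dataclass
class SafetyReport:
    """Headline numbers for one configuration."""

    label: str
    spacing: Optional[float]  # mm; None for the intact group
    hole_count: int
    peak_vm_plate: float  # MPa
    robust_peak_vm_plate: float  # MPa
    peak_vm_element: int
    peak_vm_location: tuple[float, float, float]  # mm
    peak_displacement: float  # mm
    safety_factor: float
    yield_stress_used: float  # MPa

    def to_dict(self) -> dict:
        d = asdict(self)
        d["peak_vm_location"] = list(self.peak_vm_location)
        return d


def recover_stress(displacements: DisplacementField, mesh: HexMesh, materials: Mapping) -> StressField:
    """Centroid stresses from a solved displacement field.

    Strain is evaluated from the trilinear shape-function gradients at
    each element centroid; stress follows from the isotropic Hooke law of
    that element's layer material.  With displacements in mm, coordinates
    in mm and moduli in MPa the stresses come out in MPa.
    """
    table = _material_table(materials, mesh.element_layer)
    conn = mesh.element_connectivity
    u_e = displacements.values[conn].reshape(mesh.n_elements, 24)

    if mesh.uniform_element_size is not None:
        dx, dy, dz = mesh.uniform_element_size
        box = np.array(
            [[ox * dx, oy * dy, oz * dz] for ox, oy, oz in
             [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
              (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)]]
        )
        B = centroid_b_matrix(box)
        strain = u_e @ B.T  # (ne, 6)
    else:
        corners = mesh.node_coordinates[conn]
        strain = np.empty((mesh.n_elements, 6))
        for e in range(mesh.n_elements):
            strain[e] = centroid_b_matrix(corners[e]) @ u_e[e]

    stress = np.empty_like(strain)
    for code, mat in table.items():
        mask = mesh.element_layer == code
        if not mask.any():
            continue
        D = isotropic_elasticity_matrix(mat.young_modulus, mat.poisson_ratio)
        stress[mask] = strain[mask] @ D.T
    if not np.all(np.isfinite(stress)):
        raise ValueError("non-finite recovered stresses")
    return StressField(components=stress, von_mises=von_mises(stress))


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress of Voigt tensors (..., 6).

    sigma_vm = sqrt( 1/2 [(sxx-syy)^2 + (syy-szz)^2 + (szz-sxx)^2]
                     + 3 (sxy^2 + syz^2 + szx^2) )
    """
    s = np.asarray(stress, dtype=float)
    sxx, syy, szz, sxy, syz, szx = (s[..., i] for i in range(6))
    return np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
        + 3.0 * (sxy**2 + syz**2 + szx**2)
    )


def peak_in_layer(field: StressField, mesh: HexMesh, layer: Region) -> LayerPeak:
    """Maximum von Mises stress over one layer's elements.

    Ties resolve to the lowest element index (``argmax`` semantics).  The
    99.9th percentile over the same elements accompanies the raw maximum.
    """
    mask = mesh.layer_mask(layer)
    if not mask.any():
        raise ValueError(f"mesh has no {layer.value} elements")
    idx = np.flatnonzero(mask)
    vm = field.von_mises[idx]
    local = int(np.argmax(vm))
    element = int(idx[local])
    centroid = mesh.node_coordinates[mesh.element_connectivity[element]].mean(axis=0)
    return LayerPeak(
        value=float(vm[local]),
        element_index=element,
        coordinates=centroid,
        robust_value=float(np.percentile(vm, 99.9)),
    )


def safety_factor(peak_stress: float, yield_stress: float) -> float:
    """Peak von Mises stress over yield stress (dimensionless).

    This is the printed-value convention of the source study (values < 1
    are "safe"); note it is the inverse of the usual engineering safety
    factor.  Reporting rounds to two decimals; the returned value is
    unrounded.
    """
    if not yield_stress > 0:
        raise ValueError(f"yield_stress must be > 0, got {yield_stress}")
    return peak_stress / yield_stress
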
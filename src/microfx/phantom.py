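"""Synthetic micro-CT phantoms of osteochondral tissue.

Real inputs to this kind of study are segmented micro-CT scans of
condylar bone: a thin dense subchondral plate over a porous trabecular
network, imaged here at 18 µm voxels.  This module generates a stand-in
for such scans — a grayscale volume with a solid plate of configurable
thickness on top of a correlated-random trabecular structure thresholded
to a target bone volume fraction (BV/TV), plus additive Gaussian noise —
and the threshold-segmentation and per-column layer-labelling steps
needed to turn the image into a solvable mesh.

The trabecular microstructure (smoothed Gaussian random field) exercises
the image-to-mesh path deterministically; it makes no claim of
histomorphometric realism.  The known failure mode of this pipeline on
real scans — noisy segmentation disconnecting the plate from the
trabecular network, which makes the structural analysis singular — is
reproducible here by raising the noise and the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import REGION_CODES, Region
from .voxelmesh import VoxelGrid

__all__ = ["PhantomParams", "generate_phantom", "segment", "label_layers", "SCANNER_METADATA"]

logger = logging.getLogger(__name__)

#: Acquisition settings of the emulated scanner, recorded as metadata only
#: (no physics of CT acquisition is simulated).
SCANNER_METADATA = {
    "voltage_kVp": 40,
    "current_uA": 200,
    "integration_time_ms": 200,
    "filter": "0.5 mm aluminium",
    "nominal_resolution_um": 18,
}

_BONE_INTENSITY = 1.0
_BACKGROUND_INTENSITY = 0.0


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of one synthetic scan.

    ``voxel_size`` is in µm (18 by default, the emulated scan
    resolution); thicknesses in mm.  ``seed`` fixes all randomness:
    identical parameters give bit-identical volumes.
    """

    voxel_size: float = 18.0  # µm
    plate_thickness: float = 0.3  # mm
    trabecular_bone_volume_fraction: float = 0.3
    trabecular_correlation_length: float = 0.1  # mm, roughly a trabecular half-spacing
    noise_std: float = 0.05  # intensity units; bone-background contrast is 1.0
    seed: int = 0
    shape: tuple[int, int, int] = (64, 64, 64)

    def __post_init__(self) -> None:
        if not 0.0 < self.trabecular_bone_volume_fraction <= 1.0:
            raise ValueError("trabecular_bone_volume_fraction must be in (0, 1]")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be > 0")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if any(n < 1 for n in self.shape):
            raise ValueError(f"degenerate volume shape {self.shape}")

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size * 1e-3

    @property
    def n_plate_layers(self) -> int:
        return int(round(self.plate_thickness / self.voxel_size_mm))


def generate_phantom(params: PhantomParams) -> VoxelGrid:
    """Generate a grayscale volume: dense plate over thresholded GRF bone.

    The trabecular solid mask is a Gaussian random field smoothed to the
    requested correlation length and thresholded at the quantile that
    realises the target BV/TV; the plate occupies the top
    ``round(plate_thickness / voxel_size)`` slices fully.  Additive
    Gaussian noise (``noise_std``) is applied to the whole volume.
    """
    nx, ny, nz = params.shape
    rng = np.random.default_rng(params.seed)
    vol = np.full(params.shape, _BACKGROUND_INTENSITY)

    n_plate = min(params.n_plate_layers, nz)
    vol[:, :, :n_plate] = _BONE_INTENSITY

    if nz > n_plate:
        f = params.trabecular_bone_volume_fraction
        grf = rng.standard_normal((nx, ny, nz - n_plate))
        sigma_vox = params.trabecular_correlation_length / params.voxel_size_mm
        if sigma_vox > 0:
            grf = ndimage.gaussian_filter(grf, sigma=sigma_vox)
        if f >= 1.0:
            solid = np.ones_like(grf, dtype=bool)
        else:
            threshold = np.quantile(grf, 1.0 - f)
            solid = grf >= threshold
        vol[:, :, n_plate:] = np.where(solid, _BONE_INTENSITY, _BACKGROUND_INTENSITY)

    if params.noise_std > 0:
        vol = vol + rng.normal(0.0, params.noise_std, size=params.shape)

    v = params.voxel_size_mm
    return VoxelGrid(dims=params.shape, voxel_size=(v, v, v), data=vol, kind="intensity")


def segment(volume: VoxelGrid, threshold: float) -> VoxelGrid:
    """Threshold segmentation: intensity >= threshold is bone.

    Bone voxels get the trabecular label (layer assignment comes later in
    :func:`label_layers`); everything else is background.
    """
    bone = volume.data >= threshold
    labels = np.where(bone, REGION_CODES[Region.TRABECULAR], 0).astype(np.uint8)
    return VoxelGrid(dims=volume.dims, voxel_size=volume.voxel_size, data=labels, kind="labels")


def label_layers(mask: VoxelGrid, plate_thickness: float) -> VoxelGrid:
    """Split a bone mask into plate and trabecular labels.

    For every lateral column the top bone surface is detected, and bone
    voxels within ``plate_thickness`` (mm) of it become plate.  Columns
    without any bone are left as background and counted in a warning.
    """
    if mask.kind != "labels":
        raise ValueError("label_layers expects a segmented (label) grid")
    bone = mask.data > 0
    if not bone.any():
        raise ValueError("empty mask: nothing to label")
    dz = mask.voxel_size[2]

    has_bone = bone.any(axis=2)
    top_idx = np.argmax(bone, axis=2)  # first bone voxel down each column
    n_empty = int((~has_bone).sum())
    if n_empty:
        logger.warning("%d lateral columns contain no bone; left unlabelled", n_empty)

    iz = np.arange(mask.dims[2])[None, None, :]
    depth_below_surface = (iz - top_idx[:, :, None]) * dz
    plate = bone & has_bone[:, :, None] & (depth_below_surface >= 0) & (
        depth_below_surface < plate_thickness
    )
    labels = np.where(
        plate, REGION_CODES[Region.PLATE], np.where(bone, REGION_CODES[Region.TRABECULAR], 0)
    ).astype(np.uint8)
    return VoxelGrid(dims=mask.dims, voxel_size=mask.voxel_size, data=labels, kind="labels")
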
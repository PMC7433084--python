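"""Parametric two-layer osteochondral block with microfracture hole patterns.

The model is a simplified rectangular block standing in for the femoral
condyle after cartilage removal: a thin dense subchondral bone plate
(default 0.3 mm, E = 17 GPa) on top of a homogenised trabecular layer
(default 7.7 mm, E = 700 MPa).  Microfracture holes are vertical cylinders
drilled from the articular surface to a fixed depth (default 4 mm), laid
out on a regular grid inside a central defect region.  A compressive load
(default 147 N, two-legged stance) acts on the top face and the bottom
face is fully fixed.

Units are millimetres, Newtons and MPa throughout (a self-consistent
system: 1 N/mm^2 = 1 MPa).  The z axis points downward from the articular
surface; the origin sits at a top corner of the block.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "Region",
    "MaterialSpec",
    "LayerStack",
    "HolePattern",
    "LoadCase",
    "ModelConfig",
    "EmptyPatternError",
    "STUDY_SPACINGS_MM",
    "SUBCHONDRAL_PLATE",
    "TRABECULAR_BONE",
    "generate_hole_centers",
    "geometry_membership",
    "membership_grid",
    "hole_void_volume",
    "make_study_configs",
    "default_config",
    "load_config",
    "save_config",
]

#: Hole spacings (mm) of the seven drilled study groups; the eighth group
#: is the intact plate.
STUDY_SPACINGS_MM: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0)


class Region(enum.Enum):
    """Point classification inside the model block."""

    PLATE = "plate"
    TRABECULAR = "trabecular"
    HOLE_VOID = "hole_void"
    OUTSIDE = "outside"


class EmptyPatternError(ValueError):
    """Raised when the defect region cannot accommodate a single hole."""


@dataclass(frozen=True)
class MaterialSpec:
    """Isotropic linear-elastic constants for one bone layer.

    Parameters
    ----------
    young_modulus : float
        Young's modulus in MPa.
    poisson_ratio : float
        Poisson's ratio, in [0, 0.5).
    yield_stress : float, optional
        Yield stress in MPa, used for safety-factor reporting.
    """

    name: str
    young_modulus: float
    poisson_ratio: float
    yield_stress: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.young_modulus > 0:
            raise ValueError(f"young_modulus must be > 0, got {self.young_modulus}")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError(f"poisson_ratio must be in [0, 0.5), got {self.poisson_ratio}")
        if self.yield_stress is not None and not self.yield_stress > 0:
            raise ValueError(f"yield_stress must be > 0 when given, got {self.yield_stress}")


#: Dense subchondral plate: 17 GPa, nu = 0.3, yield 135 MPa.
SUBCHONDRAL_PLATE = MaterialSpec("subchondral_plate", 17_000.0, 0.3, 135.0)
#: Homogenised trabecular bone: 700 MPa.  The Poisson ratio is reported
#: inconsistently in the source literature (0.25 in text, 0.3 in the
#: material table); 0.3 is the default here and is overridable.
TRABECULAR_BONE = MaterialSpec("trabecular_bone", 700.0, 0.3)


@dataclass(frozen=True)
class LayerStack:
    """The two bone layers and the lateral extents of the block."""

    plate_thickness: float = 0.3
    trabecular_thickness: float = 7.7
    lateral_extent_x: float = 16.0
    lateral_extent_y: float = 16.0
    plate_material: MaterialSpec = SUBCHONDRAL_PLATE
    trabecular_material: MaterialSpec = TRABECULAR_BONE

    def __post_init__(self) -> None:
        for name in ("plate_thickness", "trabecular_thickness", "lateral_extent_x", "lateral_extent_y"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def total_height(self) -> float:
        return self.plate_thickness + self.trabecular_thickness


class Arrangement(str, enum.Enum):
    SQUARE_GRID = "square_grid"
    HEX_GRID = "hex_grid"


class SpacingConvention(str, enum.Enum):
    EDGE_TO_EDGE = "edge_to_edge"
    CENTER_TO_CENTER = "center_to_center"


@dataclass(frozen=True)
class HolePattern:
    """Regular grid of microfracture holes inside a central defect region.

    ``spacing`` follows ``spacing_convention``: edge-to-edge is the clear
    wall-to-wall bone bridge between neighbouring holes (so the
    centre-to-centre pitch is ``spacing + hole_diameter``), matching how a
    surgeon spaces awl punctures.  The defect region bounds the hole
    *centres* (holes at the lesion rim may overhang it by one radius);
    every hole must lie fully inside the block's lateral extents.
    """

    spacing: float
    hole_diameter: float = 1.0
    hole_depth: float = 4.0
    defect_extent_x: float = 8.0
    defect_extent_y: float = 8.0
    arrangement: Arrangement = Arrangement.SQUARE_GRID
    spacing_convention: SpacingConvention = SpacingConvention.EDGE_TO_EDGE

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ValueError("spacing must be > 0")
        if not self.hole_diameter > 0:
            raise ValueError("hole_diameter must be > 0")
        if not self.hole_depth > 0:
            raise ValueError("hole_depth must be > 0")
        if (
            self.spacing_convention is SpacingConvention.CENTER_TO_CENTER
            and not self.spacing > self.hole_diameter
        ):
            raise ValueError("center_to_center spacing must exceed the hole diameter")

    @property
    def pitch(self) -> float:
        """Centre-to-centre distance between nearest-neighbour holes (mm)."""
        if self.spacing_convention is SpacingConvention.EDGE_TO_EDGE:
            return self.spacing + self.hole_diameter
        return self.spacing


class LoadApplication(str, enum.Enum):
    UNIFORM_FULL_FACE = "uniform_full_face"
    UNIFORM_PATCH = "uniform_patch"
    HERTZIAN_PATCH = "hertzian_patch"


class BaseConstraint(str, enum.Enum):
    """Bottom-face support.  The study condition fixes all three directions;
    the roller variant (z only, plus minimal rigid-mode pins) exists for
    verification fixtures with closed-form solutions."""

    FIXED = "fixed"
    ROLLER_Z = "roller_z"


@dataclass(frozen=True)
class LoadCase:
    """Compressive load transmitted through the joint onto the top face.

    The rounded-on-flat frictionless contact of the physical joint is
    replaced by a statically equivalent traction on the top face; three
    footprints are offered.  Whatever the footprint, the nodal force
    shares are renormalised so their sum equals ``total_force`` exactly.
    """

    total_force: float = 147.0
    application: LoadApplication = LoadApplication.UNIFORM_FULL_FACE
    patch_radius: Optional[float] = None
    base_constraint: BaseConstraint = BaseConstraint.FIXED

    def __post_init__(self) -> None:
        if not self.total_force > 0:
            raise ValueError("total_force must be > 0")
        if self.application is not LoadApplication.UNIFORM_FULL_FACE:
            if self.patch_radius is None or not self.patch_radius > 0:
                raise ValueError(f"{self.application.value} requires patch_radius > 0")


@dataclass(frozen=True)
class ModelConfig:
    """Full description of one simulated configuration."""

    layer_stack: LayerStack = field(default_factory=LayerStack)
    hole_pattern: Optional[HolePattern] = None
    load_case: LoadCase = field(default_factory=LoadCase)
    voxel_size_lateral: float = 0.4
    voxel_size_vertical: float = 0.15
    solver_tolerance: float = 1e-8
    label: str = "intact"

    def __post_init__(self) -> None:
        if not self.voxel_size_lateral > 0 or not self.voxel_size_vertical > 0:
            raise ValueError("voxel sizes must be > 0")
        if self.layer_stack.plate_thickness / self.voxel_size_vertical < 2.0 - 1e-12:
            raise ValueError(
                "voxel_size_vertical too coarse: need >= 2 elements through the "
                f"{self.layer_stack.plate_thickness} mm plate"
            )
        if self.hole_pattern is not None:
            if self.hole_pattern.hole_depth > self.layer_stack.total_height + 1e-12:
                raise ValueError("hole_depth exceeds the total stack height")
            if self.hole_pattern.hole_diameter / self.voxel_size_lateral < 4.0 - 1e-12:
                # coarse presets trade hole-wall fidelity for runtime; the
                # convergence study quantifies the effect
                warnings.warn(
                    f"hole diameter {self.hole_pattern.hole_diameter} mm spans fewer than "
                    f"4 voxels at {self.voxel_size_lateral} mm lateral resolution; hole "
                    "walls will be coarsely stair-stepped",
                    stacklevel=2,
                )


# -- resolution presets ------------------------------------------------------

#: (lateral, vertical) voxel sizes in mm.
RESOLUTION_PRESETS: dict[str, tuple[float, float]] = {
    "fast": (0.4, 0.15),
    "fine": (0.1, 0.1),
}


def default_config(preset: str = "fast", **overrides) -> ModelConfig:
    """The intact default configuration at a named resolution preset;
    keyword overrides (including voxel sizes) take precedence."""
    lat, vert = RESOLUTION_PRESETS[preset]
    params: dict = {"voxel_size_lateral": lat, "voxel_size_vertical": vert}
    params.update(overrides)
    return ModelConfig(**params)


# -- hole placement ----------------------------------------------------------


def generate_hole_centers(pattern: HolePattern, stack: LayerStack) -> np.ndarray:
    """Lay out hole centres on the chosen grid inside the defect region.

    The grid is centred on the block centre; hole *centres* stay within the
    defect region (centred in the block), and every hole must lie fully
    inside the lateral block extents.  Returns an (n, 2) array of (x, y)
    centres in mm, ordered row-major (y outer, x inner).

    Raises
    ------
    EmptyPatternError
        If not even one hole fits.
    ValueError
        If a hole would protrude past the block's lateral boundary.
    """
    pitch = pattern.pitch
    cx = stack.lateral_extent_x / 2.0
    cy = stack.lateral_extent_y / 2.0

    def _axis_positions(extent: float, center: float, step: float) -> np.ndarray:
        # largest symmetric grid with (n-1)*step <= extent (+ tolerance)
        n = int(math.floor(extent / step + 1e-9)) + 1
        if n < 1:
            return np.empty(0)
        return center + (np.arange(n) - (n - 1) / 2.0) * step

    if pattern.arrangement is Arrangement.SQUARE_GRID:
        xs = _axis_positions(pattern.defect_extent_x, cx, pitch)
        ys = _axis_positions(pattern.defect_extent_y, cy, pitch)
        gx, gy = np.meshgrid(xs, ys)
        centers = np.column_stack([gx.ravel(), gy.ravel()])
    else:  # hex grid: rows pitch*sqrt(3)/2 apart, alternate rows offset pitch/2
        row_step = pitch * math.sqrt(3.0) / 2.0
        ys = _axis_positions(pattern.defect_extent_y, cy, row_step)
        half_x = pattern.defect_extent_x / 2.0
        kmax = int(math.ceil(half_x / pitch)) + 1
        rows = []
        for i, y in enumerate(ys):
            frac = 0.5 if i % 2 else 0.0
            xs = cx + (np.arange(-kmax, kmax + 1) + frac) * pitch
            xs = xs[np.abs(xs - cx) <= half_x + 1e-9]
            for x in xs:
                rows.append((x, y))
        centers = np.array(rows, dtype=float).reshape(-1, 2)

    if centers.size == 0:
        raise EmptyPatternError(
            f"defect region {pattern.defect_extent_x} x {pattern.defect_extent_y} mm "
            f"cannot fit a hole at pitch {pitch} mm"
        )

    r = pattern.hole_diameter / 2.0
    if (
        centers[:, 0].min() - r < -1e-9
        or centers[:, 0].max() + r > stack.lateral_extent_x + 1e-9
        or centers[:, 1].min() - r < -1e-9
        or centers[:, 1].max() + r > stack.lateral_extent_y + 1e-9
    ):
        raise ValueError("hole pattern protrudes past the lateral block extents")
    return centers


def hole_void_volume(pattern: Optional[HolePattern], stack: LayerStack) -> float:
    """Analytic total void volume (mm^3) of the drilled cylinders."""
    if pattern is None:
        return 0.0
    n = len(generate_hole_centers(pattern, stack))
    return n * math.pi * (pattern.hole_diameter / 2.0) ** 2 * pattern.hole_depth


# -- point membership --------------------------------------------------------


def membership_grid(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, config: ModelConfig
) -> np.ndarray:
    """Classify a separable grid of points.

    ``x``, ``y``, ``z`` are 1-D coordinate arrays; the result has shape
    ``(len(x), len(y), len(z))`` with :class:`Region` values encoded as
    uint8 codes ``{0: outside, 1: trabecular, 2: plate, 3: hole_void}``
    (the label map shared with the image modules).
    """
    stack = config.layer_stack
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)

    inside_x = (x >= 0.0) & (x <= stack.lateral_extent_x)
    inside_y = (y >= 0.0) & (y <= stack.lateral_extent_y)
    inside_z = (z >= 0.0) & (z <= stack.total_height)

    out = np.zeros((x.size, y.size, z.size), dtype=np.uint8)
    layer = np.where(z < stack.plate_thickness, REGION_CODES[Region.PLATE], REGION_CODES[Region.TRABECULAR])
    out[:, :, :] = layer[None, None, :]

    if config.hole_pattern is not None:
        pat = config.hole_pattern
        centers = generate_hole_centers(pat, stack)
        r2 = (pat.hole_diameter / 2.0) ** 2
        in_depth = z < pat.hole_depth
        # lateral squared distance to the nearest centre, separable per axis
        dx2 = (x[:, None] - centers[None, :, 0]) ** 2  # (nx, nh)
        dy2 = (y[:, None] - centers[None, :, 1]) ** 2  # (ny, nh)
        # within-hole mask per (x, y): min over holes of dx2+dy2 < r2
        lateral = np.zeros((x.size, y.size), dtype=bool)
        for h in range(centers.shape[0]):
            lateral |= (dx2[:, h][:, None] + dy2[None, :, h]) < r2
        out[lateral[:, :, None] & in_depth[None, None, :]] = REGION_CODES[Region.HOLE_VOID]

    inside = inside_x[:, None, None] & inside_y[None, :, None] & inside_z[None, None, :]
    out[~inside] = REGION_CODES[Region.OUTSIDE]
    return out


REGION_CODES = {
    Region.OUTSIDE: 0,
    Region.TRABECULAR: 1,
    Region.PLATE: 2,
    Region.HOLE_VOID: 3,
}
CODE_REGIONS = {v: k for k, v in REGION_CODES.items()}


def geometry_membership(point: Sequence[float], config: ModelConfig) -> Region:
    """Classify a single point (x, y, z) in mm; z measured down from the top."""
    px, py, pz = (float(c) for c in point)
    code = membership_grid(np.array([px]), np.array([py]), np.array([pz]), config)[0, 0, 0]
    return CODE_REGIONS[int(code)]


# -- the eight study configurations ------------------------------------------


def make_study_configs(defaults: Optional[ModelConfig] = None) -> list[ModelConfig]:
    """The eight study configurations: intact plus seven hole spacings.

    All configurations share the defaults' geometry, materials, load and
    resolution; only the hole spacing differs (the intact one has no
    holes).  Labels are unique.
    """
    if defaults is None:
        defaults = default_config()
    base_pattern = defaults.hole_pattern or HolePattern(spacing=1.0)
    configs = [replace(defaults, hole_pattern=None, label="intact")]
    for s in STUDY_SPACINGS_MM:
        pat = replace(base_pattern, spacing=s)
        label = f"{s:g}mm"
        configs.append(replace(defaults, hole_pattern=pat, label=label))
    return configs


# -- configuration file I/O --------------------------------------------------


def _config_to_dict(config: ModelConfig) -> dict:
    stack = config.layer_stack

    def mat(m: MaterialSpec) -> dict:
        d = {"name": m.name, "young_modulus": m.young_modulus, "poisson_ratio": m.poisson_ratio}
        if m.yield_stress is not None:
            d["yield_stress"] = m.yield_stress
        return d

    out = {
        "label": config.label,
        "layer_stack": {
            "plate_thickness": stack.plate_thickness,
            "trabecular_thickness": stack.trabecular_thickness,
            "lateral_extent_x": stack.lateral_extent_x,
            "lateral_extent_y": stack.lateral_extent_y,
            "plate_material": mat(stack.plate_material),
            "trabecular_material": mat(stack.trabecular_material),
        },
        "load_case": {
            "total_force": config.load_case.total_force,
            "application": config.load_case.application.value,
            "patch_radius": config.load_case.patch_radius,
            "base_constraint": config.load_case.base_constraint.value,
        },
        "voxel_size_lateral": config.voxel_size_lateral,
        "voxel_size_vertical": config.voxel_size_vertical,
        "solver_tolerance": config.solver_tolerance,
    }
    if config.hole_pattern is not None:
        p = config.hole_pattern
        out["hole_pattern"] = {
            "spacing": p.spacing,
            "hole_diameter": p.hole_diameter,
            "hole_depth": p.hole_depth,
            "defect_extent_x": p.defect_extent_x,
            "defect_extent_y": p.defect_extent_y,
            "arrangement": p.arrangement.value,
            "spacing_convention": p.spacing_convention.value,
        }
    return out


def _config_from_dict(data: dict) -> ModelConfig:
    def mat(d: dict) -> MaterialSpec:
        return MaterialSpec(
            name=d["name"],
            young_modulus=float(d["young_modulus"]),
            poisson_ratio=float(d["poisson_ratio"]),
            yield_stress=float(d["yield_stress"]) if d.get("yield_stress") is not None else None,
        )

    sd = data["layer_stack"]
    stack = LayerStack(
        plate_thickness=float(sd["plate_thickness"]),
        trabecular_thickness=float(sd["trabecular_thickness"]),
        lateral_extent_x=float(sd["lateral_extent_x"]),
        lateral_extent_y=float(sd["lateral_extent_y"]),
        plate_material=mat(sd["plate_material"]),
        trabecular_material=mat(sd["trabecular_material"]),
    )
    pattern = None
    if data.get("hole_pattern"):
        pd = data["hole_pattern"]
        pattern = HolePattern(
            spacing=float(pd["spacing"]),
            hole_diameter=float(pd.get("hole_diameter", 1.0)),
            hole_depth=float(pd.get("hole_depth", 4.0)),
            defect_extent_x=float(pd.get("defect_extent_x", 8.0)),
            defect_extent_y=float(pd.get("defect_extent_y", 8.0)),
            arrangement=Arrangement(pd.get("arrangement", "square_grid")),
            spacing_convention=SpacingConvention(pd.get("spacing_convention", "edge_to_edge")),
        )
    ld = data.get("load_case", {})
    load = LoadCase(
        total_force=float(ld.get("total_force", 147.0)),
        application=LoadApplication(ld.get("application", "uniform_full_face")),
        patch_radius=None if ld.get("patch_radius") is None else float(ld["patch_radius"]),
        base_constraint=BaseConstraint(ld.get("base_constraint", "fixed")),
    )
    return ModelConfig(
        layer_stack=stack,
        hole_pattern=pattern,
        load_case=load,
        voxel_size_lateral=float(data.get("voxel_size_lateral", 0.4)),
        voxel_size_vertical=float(data.get("voxel_size_vertical", 0.15)),
        solver_tolerance=float(data.get("solver_tolerance", 1e-8)),
        label=str(data.get("label", "config")),
    )


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration file (YAML or JSON by extension)."""
    path = Path(path)
    data = _config_to_dict(config)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_config(path: str | Path) -> ModelConfig:
    """Read a configuration file (YAML or JSON by extension)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return _config_from_dict(data)
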
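"""Orchestration of the eight-configuration experiment and convergence study.

The experiment solves the intact plate plus seven hole spacings (1, 1.5,
2, 2.5, 3, 4, 5 mm) under the 147 N stance load and reports, per
configuration, the peak and 99.9th-percentile von Mises stress in the
subchondral plate, the peak displacement, and the safety factor against
the 135 MPa plate yield stress.  Every solve is checked for equilibrium
(reactions balance the applied load) before its result is accepted.

Because hole diameter, block extents and the contact footprint are model
assumptions rather than measured quantities, the outputs are read as
bounds and trends — is the plate anywhere near yield, and does spacing
change that — not as point predictions; the assumptions travel embedded
in every report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .elasticity import apply_boundary_conditions, assemble, solve
from .geometry import (
    ModelConfig,
    Region,
    default_config,
    generate_hole_centers,
    load_config,
    make_study_configs,
    RESOLUTION_PRESETS,
)
from .stress import SafetyReport, StressField, peak_in_layer, recover_stress, safety_factor
from .voxelmesh import HexMesh, build_hex_mesh, extract_node_sets, voxelize

__all__ = [
    "ExperimentResult",
    "PipelineError",
    "solve_config",
    "run_spacing_experiment",
    "convergence_study",
]

logger = logging.getLogger(__name__)

CAVEAT = (
    "Peak stresses and safety factors are computed under stated geometric "
    "assumptions (hole diameter, defect and block extents, load footprint) "
    "that are model choices, not measurements; values are meaningful as "
    "bounds and spacing trends, not as point predictions for a specific "
    "joint."
)


class PipelineError(RuntimeError):
    pass


def _assumptions(config: ModelConfig) -> dict:
    stack = config.layer_stack
    pat = config.hole_pattern
    return {
        "block_extent_mm": [stack.lateral_extent_x, stack.lateral_extent_y, stack.total_height],
        "plate_thickness_mm": stack.plate_thickness,
        "plate_modulus_MPa": stack.plate_material.young_modulus,
        "trabecular_modulus_MPa": stack.trabecular_material.young_modulus,
        "plate_poisson": stack.plate_material.poisson_ratio,
        "trabecular_poisson": stack.trabecular_material.poisson_ratio,
        "yield_stress_MPa": stack.plate_material.yield_stress,
        "hole_diameter_mm": pat.hole_diameter if pat else None,
        "hole_depth_mm": pat.hole_depth if pat else None,
        "defect_extent_mm": [pat.defect_extent_x, pat.defect_extent_y] if pat else None,
        "spacing_convention": pat.spacing_convention.value if pat else None,
        "load_N": config.load_case.total_force,
        "load_application": config.load_case.application.value,
        "caveat": CAVEAT,
    }


def solve_config(config: ModelConfig):
    """Voxelize, mesh, solve and post-process one configuration.

    Returns ``(mesh, displacement, stress_field, report)``; raises
    :class:`PipelineError` naming the configuration on any failure,
    including an equilibrium imbalance above 1e-6 relative.
    """
    t0 = time.perf_counter()
    try:
        grid = voxelize(config)
        mesh = build_hex_mesh(grid)
        sets = extract_node_sets(mesh, config)
        materials = {
            Region.PLATE: config.layer_stack.plate_material,
            Region.TRABECULAR: config.layer_stack.trabecular_material,
        }
        system = assemble(mesh, materials)
        system = apply_boundary_conditions(
            system,
            sets,
            base_constraint=config.load_case.base_constraint,
            node_coordinates=mesh.node_coordinates,
        )
        disp = solve(system, tolerance=config.solver_tolerance, node_coordinates=mesh.node_coordinates)
    except Exception as exc:
        raise PipelineError(f"configuration '{config.label}' failed: {exc}") from exc

    F = config.load_case.total_force
    imbalance = np.linalg.norm(disp.reaction_sum + np.array([0.0, 0.0, F])) / F
    if not imbalance < 1e-6:
        raise PipelineError(
            f"configuration '{config.label}': reactions do not balance the load "
            f"(relative imbalance {imbalance:.3g})"
        )

    field = recover_stress(disp, mesh, materials)
    plate_peak = peak_in_layer(field, mesh, Region.PLATE)
    yield_stress = config.layer_stack.plate_material.yield_stress
    if yield_stress is None:
        raise PipelineError(f"configuration '{config.label}': plate material has no yield stress")
    pat = config.hole_pattern
    n_holes = len(generate_hole_centers(pat, config.layer_stack)) if pat else 0
    report = SafetyReport(
        label=config.label,
        spacing=pat.spacing if pat else None,
        hole_count=n_holes,
        peak_vm_plate=plate_peak.value,
        robust_peak_vm_plate=plate_peak.robust_value,
        peak_vm_element=plate_peak.element_index,
        peak_vm_location=tuple(float(c) for c in plate_peak.coordinates),
        peak_displacement=float(np.linalg.norm(disp.values, axis=1).max()),
        safety_factor=safety_factor(plate_peak.value, yield_stress),
        yield_stress_used=yield_stress,
    )
    logger.info(
        "%s: %d elements, %s in %d iters (residual %.2e), peak plate vM %.3f MPa, %.1f s",
        config.label, mesh.n_elements, disp.method, disp.iterations,
        disp.relative_residual, plate_peak.value, time.perf_counter() - t0,
    )
    return mesh, disp, field, report


@dataclass
class ExperimentResult:
    """All reports of one experiment run plus mesh stats and metadata."""

    reports: list[SafetyReport]
    mesh_stats: list[dict]
    metadata: dict

    def __post_init__(self) -> None:
        labels = [r.label for r in self.reports]
        if len(set(labels)) != len(labels):
            raise ValueError("configuration labels are not unique")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            rows.append(
                {
                    "label": r.label,
                    "spacing_mm": r.spacing,
                    "hole_count": r.hole_count,
                    "peak_vm_plate_MPa": r.peak_vm_plate,
                    "robust_peak_vm_plate_MPa": r.robust_peak_vm_plate,
                    "peak_displacement_mm": r.peak_displacement,
                    "safety_factor": r.safety_factor,
                    "safety_factor_2dp": round(r.safety_factor, 2),
                }
            )
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path, stem: str = "experiment") -> tuple[Path, Path]:
        """Write CSV + JSON reports; bytes are reproducible run-to-run."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        csv_path = out_dir / f"{stem}.csv"
        json_path = out_dir / f"{stem}.json"
        self.to_dataframe().to_csv(csv_path, index=False)
        payload = {
            "metadata": self.metadata,
            "mesh_stats": self.mesh_stats,
            "reports": [r.to_dict() for r in self.reports],
        }
        json_path.write_text(json.dumps(payload, indent=2))
        return csv_path, json_path


def run_spacing_experiment(
    config_file: Optional[str | Path | ModelConfig] = None,
    preset: Optional[str] = None,
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
) -> ExperimentResult:
    """Run the eight-configuration hole-spacing experiment.

    ``config_file`` may be a path to a YAML/JSON configuration, a
    :class:`ModelConfig` used as the template for all eight groups, or
    None for the defaults.  ``preset`` ("fast" or "fine"), when given,
    overrides the template's voxel resolution; when None the template's
    own resolution is kept (defaults to the fast preset).  The whole
    pipeline is deterministic; ``seed`` is recorded in the metadata for
    provenance.
    """
    if config_file is None:
        template = default_config(preset=preset or "fast")
    elif isinstance(config_file, ModelConfig):
        template = config_file
    else:
        template = load_config(config_file)
    if preset is not None and config_file is not None:
        lat, vert = RESOLUTION_PRESETS[preset]
        from dataclasses import replace

        template = replace(template, voxel_size_lateral=lat, voxel_size_vertical=vert)
    preset_label = preset or ("fast" if config_file is None else "custom")

    configs = make_study_configs(template)
    reports, mesh_stats = [], []
    for cfg in configs:
        mesh, disp, field_, report = solve_config(cfg)
        reports.append(report)
        mesh_stats.append(
            {
                "label": cfg.label,
                "n_elements": mesh.n_elements,
                "n_nodes": mesh.n_nodes,
                "n_plate_elements": int(mesh.layer_mask(Region.PLATE).sum()),
                "solver": disp.method,
                "iterations": disp.iterations,
                "relative_residual": disp.relative_residual,
            }
        )
    metadata = {
        "preset": preset_label,
        "seed": seed,
        "version": _version,
        "assumptions": _assumptions(configs[-1]),  # last config has the hole pattern
    }
    result = ExperimentResult(reports=reports, mesh_stats=mesh_stats, metadata=metadata)
    if out_dir is not None:
        result.write(out_dir, stem=f"experiment_{preset_label}")
    return result


def convergence_study(
    config_file: Optional[str | Path | ModelConfig],
    resolutions: Sequence[tuple[float, float] | float],
) -> pd.DataFrame:
    """Peak plate stress versus mesh resolution for one configuration.

    ``resolutions`` lists (lateral, vertical) voxel sizes in mm (a bare
    float is used for both).  Resolutions that violate the
    two-elements-through-the-plate rule are skipped with a warning.
    Returns a table with peak and robust-peak stress per resolution and
    the successive relative changes.
    """
    if len(resolutions) < 2:
        raise ValueError("convergence study needs at least two resolutions")
    if config_file is None:
        base = default_config()
    elif isinstance(config_file, ModelConfig):
        base = config_file
    else:
        base = load_config(config_file)

    from dataclasses import replace

    rows = []
    for res in resolutions:
        lat, vert = (res, res) if np.isscalar(res) else res
        try:
            cfg = replace(base, voxel_size_lateral=float(lat), voxel_size_vertical=float(vert))
        except ValueError as exc:
            logger.warning("skipping resolution (%s, %s): %s", lat, vert, exc)
            continue
        mesh, disp, field_, report = solve_config(cfg)
        rows.append(
            {
                "voxel_lateral_mm": float(lat),
                "voxel_vertical_mm": float(vert),
                "n_elements": mesh.n_elements,
                "peak_vm_plate_MPa": report.peak_vm_plate,
                "robust_peak_vm_plate_MPa": report.robust_peak_vm_plate,
                "peak_displacement_mm": report.peak_displacement,
            }
        )
    if len(rows) < 2:
        raise ValueError("fewer than two valid resolutions after skipping invalid ones")
    df = pd.DataFrame(rows)
    for col in ("peak_vm_plate_MPa", "robust_peak_vm_plate_MPa"):
        prev = df[col].shift(1)
        df[f"rel_change_{col}"] = (df[col] - prev).abs() / prev.abs()
    return df
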
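"""End-to-end inverse planning for the sparse-orthogonal-collimator plan.

Seven equally distributed coplanar fields around the cranio-caudal axis,
isocenter at the target centroid; FISTA fluence optimization against the
skeleton + spleen target with organ-at-risk and integral-dose penalties;
greedy rectangular-aperture decomposition of each optimized fluence map;
final dose recomputed from the delivered (rectangle-reconstructed)
fluence so the reported dosimetry is what the collimator can deliver.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from .engine import (AttenuationModel, DoseInfluenceMatrix, assemble_influence,
                     dose_from_fluence, planning_support, seven_field_geometries)
from .fista import FluencePlan, ObjectiveSpec, StructureGoal, optimize_fluence
from .grids import StructureSet, VoxelGrid
from .phantom import integral_dose_region, ptv_mask
from .rectangles import DecompositionResult, RectangleAperture, decompose_rectangles

__all__ = ["SOCPlanConfig", "SOCPlan", "plan_soc_tmi", "default_objective"]


@dataclass
class SOCPlanConfig:
    """Prescription, geometry and optimizer knobs for a SOC plan."""

    prescription_gy: float = 12.0
    ptv_margin_mm: float = 0.0
    sid_mm: float = 305.4
    beamlet_mm: float = 1.0
    max_field_mm: float = 120.0
    field_margin_mm: float = 2.0
    support_margin_mm: float = 2.0
    floor_rel: float = 1e-4
    decomp_tol: float = 0.02
    rectangle_budget: int = 128
    tv_lambda_rel: float = 0.05
    max_iter: int = 2000
    tol: float = 1e-6
    oar_weights: Dict[str, float] = dc_field(default_factory=lambda: {
        "lungs": 10.0, "kidneys": 10.0, "liver": 3.0, "heart": 3.0, "bowel": 3.0,
    })
    ptv_weight: float = 100.0
    integral_weight: float = 1.0
    attenuation: AttenuationModel = dc_field(default_factory=AttenuationModel)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SOCPlanConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "attenuation" in raw:
            raw["attenuation"] = AttenuationModel(**raw["attenuation"])
        return cls(**raw)


@dataclass
class SOCPlan:
    """Deliverable plan: rectangles, delivered fluence, dose, diagnostics."""

    rectangles: List[RectangleAperture]
    delivered_maps: List[np.ndarray]
    optimized: FluencePlan
    dose: np.ndarray
    rectangles_per_field: List[int]
    decomposition_errors: List[float]
    influence: Optional[DoseInfluenceMatrix] = None
    warnings: List[str] = dc_field(default_factory=list)

    @property
    def delivered_weights(self) -> np.ndarray:
        return np.concatenate([m.ravel() for m in self.delivered_maps])

    def to_manifest(self) -> dict:
        return {
            "fields": [g.to_dict() for g in self.influence.geometries] if self.influence else [],
            "rectangles": [[r.field, r.r0, r.r1, r.c0, r.c1, r.weight] for r in self.rectangles],
            "rectangles_per_field": self.rectangles_per_field,
            "decomposition_errors": self.decomposition_errors,
            "converged": bool(self.optimized.converged),
            "iterations": int(self.optimized.n_iter),
            "warnings": self.warnings,
        }

    def save_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_manifest(), indent=1))


def default_objective(config: SOCPlanConfig) -> ObjectiveSpec:
    goals = {"ptv": StructureGoal(config.ptv_weight, config.prescription_gy, "target")}
    for name, w in config.oar_weights.items():
        goals[name] = StructureGoal(w, 0.0, "oar")
    if config.integral_weight > 0:
        goals["integral"] = StructureGoal(config.integral_weight, 0.0, "oar")
    return ObjectiveSpec(goals, tv_lambda_rel=config.tv_lambda_rel,
                         max_iter=config.max_iter, tol=config.tol)


def _field_grid_size(ptv_coords: np.ndarray, iso: np.ndarray,
                     config: SOCPlanConfig) -> tuple[int, int]:
    """Beamlet rows/cols needed to cover the target from every angle."""
    dz = np.abs(ptv_coords[:, 2] - iso[2]).max()
    r_lat = np.linalg.norm(ptv_coords[:, :2] - iso[:2], axis=1).max()
    half_rows = dz + config.field_margin_mm
    half_cols = r_lat + config.field_margin_mm
    n_rows = 2 * int(np.ceil(half_rows / config.beamlet_mm)) + 1
    n_cols = 2 * int(np.ceil(half_cols / config.beamlet_mm)) + 1
    return n_rows, n_cols


def plan_soc_tmi(grid: VoxelGrid, structures: StructureSet,
                 config: SOCPlanConfig | None = None,
                 keep_influence: bool = True) -> SOCPlan:
    """Plan, optimize and decompose a seven-field SOC treatment."""
    config = config or SOCPlanConfig()
    ptv = ptv_mask(structures, config.ptv_margin_mm)
    if not ptv.any():
        raise ValueError("empty planning target")
    ptv_coords = grid.voxel_centers(ptv)
    iso = ptv_coords.mean(axis=0)
    n_rows, n_cols = _field_grid_size(ptv_coords, iso, config)
    geometries = seven_field_geometries(iso, n_rows, n_cols, config.sid_mm,
                                        config.beamlet_mm, config.max_field_mm)
    support = planning_support(structures, ptv, config.support_margin_mm)
    D = assemble_influence(grid, support, geometries, config.attenuation,
                           config.floor_rel)

    masks: Dict[str, np.ndarray] = {"ptv": ptv}
    for name in config.oar_weights:
        structures.require([name])
        masks[name] = structures[name] & ~ptv
    if config.integral_weight > 0:
        masks["integral"] = integral_dose_region(structures) & ~ptv
    objective = default_objective(config)
    # drop OAR terms whose mask vanished under the PTV margin
    for name in list(objective.goals):
        if name in masks and not masks[name].any():
            del objective.goals[name]
            del masks[name]

    plan = optimize_fluence(D, masks, objective)
    warnings: List[str] = []
    if not plan.converged:
        warnings.append(f"optimizer hit the iteration cap ({plan.n_iter})")

    rectangles: List[RectangleAperture] = []
    delivered: List[np.ndarray] = []
    errors: List[float] = []
    counts: List[int] = []
    for k, m in enumerate(plan.maps):
        dec = decompose_rectangles(m, config.decomp_tol, config.rectangle_budget, field=k)
        if dec.budget_exhausted:
            warnings.append(f"field {k}: rectangle budget exhausted "
                            f"(residual {dec.achieved_rel_error:.3g})")
        rectangles.extend(dec.rectangles)
        delivered.append(dec.reconstruct(m.shape))
        errors.append(dec.achieved_rel_error)
        counts.append(len(dec.rectangles))

    weights = np.concatenate([m.ravel() for m in delivered])
    dose = dose_from_fluence(D, weights)
    return SOCPlan(rectangles, delivered, plan, dose, counts, errors,
                   influence=D if keep_influence else None, warnings=warnings)
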
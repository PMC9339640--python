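"""Parallel-opposed fixed-collimator baseline planner.

The second-generation preclinical technique covers the skeleton + spleen
target with seven anatomic regions — head, cervical spine, shoulders,
dorsal spine and spleen, lumbar spine, femurs, tibias — each irradiated
by a parallel-opposed pair of fixed-collimator beams (lateral pairs for
the axial skeleton, dorso-ventral pairs for limbs and the spleen region)
and normalized so its normalization point receives the prescription.
Because the collimators come in five fixed sizes, fields generally
overshoot their anatomic slab and overlap neighbours, and perpendicular
pairs cross lateral ones: the resulting junction hot spots are an
intrinsic feature of the technique and are surfaced by
``junction_report``.

Normalization is dose-to-tissue: the local medium enhancement at the
normalization point is divided out, so a prescription refers to
soft-tissue dose and bone legitimately absorbs well over 100% of it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml
from scipy import ndimage

from .engine import (FIXED_COLLIMATORS, AttenuationModel, BeamGeometry,
                     fixed_field_dose)
from .grids import StructureSet, VoxelGrid
from .phantom import ptv_mask

__all__ = ["RegionBeamSet", "Plan3D", "auto_place_regions", "compute_3d_plan",
           "junction_report"]

REGION_NAMES = ("tibias", "femurs", "lumbar spine", "dorsal spine and spleen",
                "shoulders", "cervical spine", "head")
#: caudal-to-cranial slab boundaries as fractions of the PTV z-extent
_SLAB_FRACTIONS = (0.146, 0.269, 0.464, 0.675, 0.781, 0.881)
#: regions treated with dorso-ventral (perpendicular) pairs instead of lateral
_PERPENDICULAR = {"femurs", "tibias", "dorsal spine and spleen"}
#: fixed collimators ordered by open area (smallest first)
_SHAPES_BY_AREA = ("circle5", "circle10", "10x10", "20x20", "40x40")


@dataclass
class RegionBeamSet:
    """One region's opposed beam pair."""

    name: str
    isocenter: Tuple[float, float, float]
    collimator: str
    axis: str  # 'lateral' (along x) or 'dorsoventral' (along y)
    norm_point: Tuple[float, float, float]
    weight: float = 1.0
    z_range: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.collimator not in FIXED_COLLIMATORS:
            raise ValueError(f"collimator must be one of {sorted(FIXED_COLLIMATORS)}")
        if self.axis not in ("lateral", "dorsoventral"):
            raise ValueError("axis must be 'lateral' or 'dorsoventral'")
        if self.weight <= 0:
            raise ValueError("region weight must be positive")

    def gantry_angles(self) -> Tuple[float, float]:
        return (90.0, 270.0) if self.axis == "lateral" else (0.0, 180.0)

    def to_dict(self) -> dict:
        return {"name": self.name, "isocenter": list(map(float, self.isocenter)),
                "collimator": self.collimator, "axis": self.axis,
                "norm_point": list(map(float, self.norm_point)),
                "weight": float(self.weight), "z_range": list(map(float, self.z_range))}


@dataclass
class Plan3D:
    regions: List[RegionBeamSet]
    dose: np.ndarray
    junctions: List[dict]

    def save_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"regions": [r.to_dict() for r in self.regions],
             "junctions": self.junctions}, indent=1))


def _smallest_cover(half_z: float, half_u: float) -> Optional[str]:
    """Smallest fixed shape whose aperture covers the given half-extents."""
    for name in _SHAPES_BY_AREA:
        kind, size = FIXED_COLLIMATORS[name]
        if kind == "square":
            if size / 2.0 >= half_z and size / 2.0 >= half_u:
                return name
        else:
            if (size / 2.0) ** 2 >= half_z**2 + half_u**2:
                return name
    return None


def auto_place_regions(structures: StructureSet,
                       overrides: Dict[str, dict] | None = None) -> List[RegionBeamSet]:
    """Deterministically place the seven regions from the structures.

    The PTV cranio-caudal extent is partitioned into seven contiguous
    slabs at fixed anatomic fractions (shared boundary planes are exact
    by construction); each region's isocenter and normalization point
    default to its slab's PTV centroid and its collimator to the
    smallest fixed shape covering the slab's PTV cross-section.  Entries
    in ``overrides`` (keyed by region name) replace individual fields of
    the auto placement.
    """
    ptv = ptv_mask(structures, 0.0)
    if not ptv.any():
        raise ValueError("empty planning target")
    grid = structures.grid
    coords = grid.voxel_centers(ptv)
    zmin = coords[:, 2].min() - grid.spacing[2] / 2.0
    zmax = coords[:, 2].max() + grid.spacing[2] / 2.0

    # compact target: a single fixed collimator can cover the whole PTV
    centroid = coords.mean(axis=0)
    half_vox = np.asarray(grid.spacing) / 2.0
    hz = np.abs(coords[:, 2] - centroid[2]).max() + half_vox[2]
    hu = np.abs(coords[:, 1] - centroid[1]).max() + half_vox[1]
    whole = _smallest_cover(hz, hu)
    if whole is not None and not (overrides or {}):
        return [RegionBeamSet("single", tuple(centroid), whole, "lateral",
                              tuple(centroid), z_range=(float(zmin), float(zmax)))]

    bounds = [zmin] + [zmin + f * (zmax - zmin) for f in _SLAB_FRACTIONS] + [zmax]

    regions: List[RegionBeamSet] = []
    overrides = overrides or {}
    for i, name in enumerate(REGION_NAMES):
        lo, hi = bounds[i], bounds[i + 1]
        sel = (coords[:, 2] >= lo) & (coords[:, 2] < hi) if i < 6 else \
              (coords[:, 2] >= lo) & (coords[:, 2] <= hi)
        sub = coords[sel]
        if sub.size == 0:
            raise ValueError(f"region {name!r}: no target voxels in slab [{lo:.1f}, {hi:.1f}] mm")
        centroid = sub.mean(axis=0)
        axis = "dorsoventral" if name in _PERPENDICULAR else "lateral"
        u_idx = 0 if axis == "dorsoventral" else 1  # field axis perpendicular to beam
        half_vox = np.asarray(grid.spacing) / 2.0
        half_z = np.abs(sub[:, 2] - centroid[2]).max() + half_vox[2]
        half_u = np.abs(sub[:, u_idx] - centroid[u_idx]).max() + half_vox[u_idx]
        ov = overrides.get(name, {})
        shape = ov.get("collimator") or _smallest_cover(half_z, half_u)
        if shape is None:
            raise ValueError(
                f"region {name!r}: target cross-section "
                f"({2*half_z:.1f} x {2*half_u:.1f} mm) exceeds the largest collimator")
        region = RegionBeamSet(
            name=name,
            isocenter=tuple(ov.get("isocenter", centroid)),
            collimator=shape,
            axis=ov.get("axis", axis),
            norm_point=tuple(ov.get("norm_point", centroid)),
            z_range=(float(lo), float(hi)),
        )
        regions.append(region)
    return regions


def _region_dose(grid: VoxelGrid, region: RegionBeamSet,
                 attenuation: AttenuationModel, support: np.ndarray,
                 sid_mm: float, beamlet_mm: float) -> np.ndarray:
    kind, size = FIXED_COLLIMATORS[region.collimator]
    n = int(np.ceil(size / beamlet_mm)) + 3
    dose = np.zeros(grid.dims)
    for ang in region.gantry_angles():
        geo = BeamGeometry(ang, region.isocenter, sid_mm, n, n, beamlet_mm,
                           max_field_mm=max(120.0, (n + 1) * beamlet_mm))
        dose += fixed_field_dose(grid, geo, attenuation, (kind, size), support)
    return dose


def compute_3d_plan(grid: VoxelGrid, structures: StructureSet,
                    regions: List[RegionBeamSet], prescription_gy: float,
                    attenuation: AttenuationModel | None = None,
                    sid_mm: float = 305.4, beamlet_mm: float = 1.0,
                    junction_threshold_pct: float = 110.0) -> Plan3D:
    """Sum the normalized opposed pairs of all regions.

    Each region's weight is set so the dose-to-tissue at its
    normalization point equals the prescription; a zero dose there is an
    error.
    """
    attenuation = attenuation or AttenuationModel()
    support = structures["body"] if "body" in structures else np.ones(grid.dims, bool)
    total = np.zeros(grid.dims)
    placed: List[RegionBeamSet] = []
    for region in regions:
        dose = _region_dose(grid, region, attenuation, support, sid_mm, beamlet_mm)
        idx = np.clip(np.rint(grid.world_to_index(region.norm_point)).astype(int)[0],
                      0, np.asarray(grid.dims) - 1)
        local = dose[tuple(idx)] / attenuation.enhancement(grid.density[tuple(idx)])
        if local <= 0:
            raise ValueError(f"region {region.name!r}: normalization point receives no dose")
        w = prescription_gy / float(local)
        total += w * dose
        placed.append(RegionBeamSet(region.name, region.isocenter, region.collimator,
                                    region.axis, region.norm_point, w, region.z_range))
    junctions = junction_report(total, prescription_gy, junction_threshold_pct)
    return Plan3D(placed, total, junctions)


def junction_report(dose: np.ndarray, prescription_gy: float,
                    threshold_pct: float = 110.0) -> List[dict]:
    """Connected clusters (26-connectivity) above ``threshold_pct`` of Rx."""
    if threshold_pct <= 100:
        raise ValueError("junction threshold must exceed 100%")
    hot = dose > threshold_pct / 100.0 * prescription_gy
    labels, n = ndimage.label(hot, structure=np.ones((3, 3, 3), dtype=int))
    out = []
    for lbl in range(1, n + 1):
        m = labels == lbl
        out.append({
            "size_voxels": int(m.sum()),
            "peak_pct": float(dose[m].max() / prescription_gy * 100.0),
        })
    out.sort(key=lambda c: -c["size_voxels"])
    return out
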
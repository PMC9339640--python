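"""Deterministic digital mouse phantom.

Builds a prone-mouse density grid plus binary structure masks from
analytic primitives (spheres, ellipsoids, capsules).  The anatomy is
schematic but preserves the adjacencies that drive marrow-irradiation
dosimetry: the vertebral column is a capsule chain running cranio-caudally,
the lungs flank the thoracic spine, and each kidney sits within 1 mm of
the lumbar spine surface.  The target is the skeleton plus the spleen;
lungs, kidneys, liver, heart and bowel are the organs at risk inside a
soft-tissue body.

Each voxel is assigned to the innermost containing structure by a fixed
priority (bone > spleen > kidneys > lungs > heart > liver > bowel > body),
so the masks are pairwise disjoint and the density field is the material
density of that structure.  Analytic primitives make volumes testable
against closed forms.

A seeded jitter (<= ``jitter_mm`` per organ center, one rigid shift for
the whole skeleton) emulates subject-to-subject contour variability for
cohort studies; seed 0 with ``jitter_mm=0`` gives the reference subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import yaml
from scipy import ndimage

from .grids import StructureSet, VoxelGrid

__all__ = [
    "PhantomConfig",
    "generate_phantom",
    "ptv_mask",
    "integral_dose_region",
    "debug_sphere_phantom",
]

# ---------------------------------------------------------------- primitives


def _sphere(xx, yy, zz, center, radius) -> np.ndarray:
    cx, cy, cz = center
    return (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2 <= radius**2


def _ellipsoid(xx, yy, zz, center, radii) -> np.ndarray:
    cx, cy, cz = center
    rx, ry, rz = radii
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 + ((zz - cz) / rz) ** 2 <= 1.0


def _capsule(xx, yy, zz, p0, p1, radius) -> np.ndarray:
    """Cylinder with hemispherical caps between world points p0 and p1."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    L2 = float(d @ d)
    vx, vy, vz = xx - p0[0], yy - p0[1], zz - p0[2]
    if L2 == 0.0:
        return vx**2 + vy**2 + vz**2 <= radius**2
    t = np.clip((vx * d[0] + vy * d[1] + vz * d[2]) / L2, 0.0, 1.0)
    qx = vx - t * d[0]
    qy = vy - t * d[1]
    qz = vz - t * d[2]
    return qx**2 + qy**2 + qz**2 <= radius**2


# ------------------------------------------------------------------- config


@dataclass
class OrganSpec:
    """One organ as a union of analytic primitives.

    ``primitives`` is a list of ``("sphere", center, radius)``,
    ``("ellipsoid", center, radii)`` or ``("capsule", p0, p1, radius)``
    tuples in world mm.
    """

    name: str
    primitives: List[tuple]


@dataclass
class PhantomConfig:
    """Geometry, materials and grid of the synthetic mouse.

    Spacing defaults to 0.5 mm; the planning pipeline typically coarsens
    to 1.0 mm.  All organ geometry is in world mm so the phantom is
    spacing-agnostic.
    """

    spacing: Tuple[float, float, float] = (0.5, 0.5, 0.5)
    extent_mm: Tuple[float, float, float] = (30.0, 24.0, 92.0)
    density_soft: float = 1.00
    density_lung: float = 0.26
    density_bone: float = 1.85
    density_air: float = 0.0
    jitter_mm: float = 0.5
    seed: int = 0
    # body: elliptic cylinder with ellipsoidal end rolloff
    body_center_xy: Tuple[float, float] = (15.0, 12.0)
    body_radii_xy: Tuple[float, float] = (11.0, 9.5)
    body_z: Tuple[float, float] = (4.0, 88.0)
    body_cap_mm: float = 6.0
    organs: Tuple[str, ...] = (
        "skeleton", "spleen", "kidneys", "lungs", "heart", "liver", "bowel",
    )

    def grid_dims(self) -> Tuple[int, int, int]:
        return tuple(int(round(e / s)) for e, s in zip(self.extent_mm, self.spacing))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("spacing", "extent_mm", "body_center_xy", "body_radii_xy", "body_z", "organs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def __post_init__(self) -> None:
        if not (0 < self.density_lung < self.density_soft < self.density_bone):
            raise ValueError("need lung density < soft-tissue density < bone density")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacings must be positive")


# Priority order: innermost structure wins a voxel.
_PRIORITY = ("skeleton", "spleen", "kidneys", "lungs", "heart", "liver", "bowel")


def _reference_anatomy(cfg: PhantomConfig, rng: np.random.Generator) -> List[OrganSpec]:
    """Organ primitives (world mm) for the reference mouse, with seeded jitter."""

    def shift(scale=1.0):
        if cfg.jitter_mm <= 0:
            return np.zeros(3)
        return rng.uniform(-cfg.jitter_mm * scale, cfg.jitter_mm * scale, size=3)

    # one rigid shift for the whole skeleton, independent shifts per soft organ
    sk = shift()

    def mv(p, d):
        return tuple(np.asarray(p, float) + d)

    cx, cy = cfg.body_center_xy
    organs: List[OrganSpec] = []

    skel: List[tuple] = []
    # skull
    skel.append(("sphere", mv((cx, cy, 78.0), sk), 4.5))
    # vertebral column: chain of short capsules, dorsal of center
    z0, z1, seg = 14.0, 72.0, 4.0
    zs = np.arange(z0, z1, seg)
    for za in zs:
        skel.append(("capsule", mv((cx, 16.5, za), sk), mv((cx, 16.5, min(za + seg, z1)), sk), 1.6))
    # shoulders
    for s in (+1, -1):
        skel.append(("capsule", mv((cx + 3 * s, 16.0, 66.0), sk), mv((cx + 8 * s, 13.0, 60.0), sk), 1.3))
    # pelvis
    for s in (+1, -1):
        skel.append(("capsule", mv((cx + 2 * s, 16.0, 30.0), sk), mv((cx + 6 * s, 14.0, 26.0), sk), 1.4))
    # femurs
    for s in (+1, -1):
        skel.append(("capsule", mv((cx + 6 * s, 13.5, 26.0), sk), mv((cx + 7.5 * s, 11.0, 18.0), sk), 1.3))
    # tibias
    for s in (+1, -1):
        skel.append(("capsule", mv((cx + 7.5 * s, 11.0, 18.0), sk), mv((cx + 8.0 * s, 10.0, 8.0), sk), 1.1))
    organs.append(OrganSpec("skeleton", skel))

    organs.append(OrganSpec("spleen", [("ellipsoid", mv((8.5, 13.0, 47.0), shift()), (2.0, 2.5, 5.0))]))
    ks = shift()
    organs.append(OrganSpec("kidneys", [
        ("ellipsoid", mv((cx + 3.7, 15.5, 38.0), ks), (2.3, 2.3, 3.8)),
        ("ellipsoid", mv((cx - 3.7, 15.5, 38.0), ks), (2.3, 2.3, 3.8)),
    ]))
    ls = shift()
    organs.append(OrganSpec("lungs", [
        ("ellipsoid", mv((cx + 4.3, 14.0, 62.0), ls), (3.8, 4.5, 7.0)),
        ("ellipsoid", mv((cx - 4.3, 14.0, 62.0), ls), (3.8, 4.5, 7.0)),
    ]))
    organs.append(OrganSpec("heart", [("sphere", mv((cx, 9.5, 58.0), shift()), 3.2)]))
    organs.append(OrganSpec("liver", [("ellipsoid", mv((cx, 9.5, 48.0), shift()), (7.5, 4.5, 5.5))]))
    organs.append(OrganSpec("bowel", [("ellipsoid", mv((cx, 9.5, 31.0), shift()), (6.5, 5.0, 7.0))]))
    return [o for o in organs if o.name in cfg.organs]


def _body_mask(cfg: PhantomConfig, xx, yy, zz) -> np.ndarray:
    cx, cy = cfg.body_center_xy
    rx, ry = cfg.body_radii_xy
    zlo, zhi = cfg.body_z
    cap = cfg.body_cap_mm
    s = np.ones_like(zz)
    lo_edge = zz < zlo + cap
    hi_edge = zz > zhi - cap
    with np.errstate(invalid="ignore"):
        s = np.where(lo_edge, np.sqrt(np.clip(1 - ((zlo + cap - zz) / cap) ** 2, 0, 1)), s)
        s = np.where(hi_edge, np.sqrt(np.clip(1 - ((zz - (zhi - cap)) / cap) ** 2, 0, 1)), s)
    inside_z = (zz >= zlo) & (zz <= zhi)
    r2 = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2
    return inside_z & (r2 <= s**2)


def _rasterize(organ: OrganSpec, xx, yy, zz) -> np.ndarray:
    mask = np.zeros(xx.shape, dtype=bool)
    for prim in organ.primitives:
        kind = prim[0]
        if kind == "sphere":
            mask |= _sphere(xx, yy, zz, prim[1], prim[2])
        elif kind == "ellipsoid":
            mask |= _ellipsoid(xx, yy, zz, prim[1], prim[2])
        elif kind == "capsule":
            mask |= _capsule(xx, yy, zz, prim[1], prim[2], prim[3])
        else:
            raise ValueError(f"unknown primitive kind {kind!r}")
    return mask


def generate_phantom(config: PhantomConfig) -> Tuple[VoxelGrid, StructureSet]:
    """Generate the density grid and structure masks.

    Deterministic for a fixed config and seed.  Raises ``ValueError``
    naming the organ if any organ voxel falls outside the body.
    """
    dims = config.grid_dims()
    sp = np.asarray(config.spacing)
    origin = sp / 2.0  # voxel centers at (i + 1/2) * spacing
    idx = np.indices(dims, dtype=np.float64)
    xx = idx[0] * sp[0] + origin[0]
    yy = idx[1] * sp[1] + origin[1]
    zz = idx[2] * sp[2] + origin[2]

    body = _body_mask(config, xx, yy, zz)
    rng = np.random.default_rng(config.seed)
    organs = _reference_anatomy(config, rng)

    raw: Dict[str, np.ndarray] = {}
    for organ in organs:
        m = _rasterize(organ, xx, yy, zz)
        if np.any(m & ~body):
            raise ValueError(f"organ {organ.name!r} extends outside the body")
        raw[organ.name] = m

    # disjoint masks by priority; density = innermost material
    density = np.where(body, config.density_soft, config.density_air)
    claimed = np.zeros(dims, dtype=bool)
    masks: Dict[str, np.ndarray] = {}
    for name in _PRIORITY:
        if name not in raw:
            continue
        m = raw[name] & ~claimed
        claimed |= m
        masks[name] = m
    if "skeleton" in masks:
        density[masks["skeleton"]] = config.density_bone
    if "lungs" in masks:
        density[masks["lungs"]] = config.density_lung
    masks["body"] = body

    grid = VoxelGrid(density, tuple(sp), tuple(origin))
    return grid, StructureSet(grid, masks)


def ptv_mask(structures: StructureSet, margin_mm: float = 0.0) -> np.ndarray:
    """Planning target: (skeleton ∪ spleen) dilated isotropically by ``margin_mm``.

    Margin 0 returns the exact union.  Dilation thresholds the Euclidean
    distance transform (physical spacing) at ``margin + spacing/4``: the
    quarter-voxel term compensates the half-sample bias of measuring
    distance to center-sampled surfaces, so dilated volumes track the
    analytic continuum dilation instead of systematically undershooting.
    """
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    structures.require(["skeleton", "spleen"])
    union = structures["skeleton"] | structures["spleen"]
    if margin_mm == 0 or not union.any():
        return union.copy()
    dist = ndimage.distance_transform_edt(~union, sampling=structures.grid.spacing)
    return dist <= margin_mm + float(np.mean(structures.grid.spacing)) / 4.0 + 1e-9


def integral_dose_region(structures: StructureSet) -> np.ndarray:
    """Region for integral dose: body minus skeleton minus spleen."""
    structures.require(["body", "skeleton", "spleen"])
    return structures["body"] & ~(structures["skeleton"] | structures["spleen"])


def debug_sphere_phantom(radius_mm: float = 4.0,
                         spacing: float = 0.5,
                         density: float = 1.0) -> Tuple[VoxelGrid, StructureSet]:
    """A water body with a single spherical 'skeleton' and empty spleen.

    Handy for analytic-volume checks: the mask voxel count approximates
    (4/3) pi r^3 / voxel volume.
    """
    pad = 4.0
    n = int(np.ceil(2 * (radius_mm + pad) / spacing))
    n = max(n, 8)
    sp = (spacing,) * 3
    origin = (spacing / 2,) * 3
    idx = np.indices((n, n, n), dtype=np.float64)
    center = n * spacing / 2.0
    xx = idx[0] * spacing + origin[0]
    yy = idx[1] * spacing + origin[1]
    zz = idx[2] * spacing + origin[2]
    sphere = _sphere(xx, yy, zz, (center,) * 3, radius_mm)
    body = np.ones((n, n, n), dtype=bool)
    grid = VoxelGrid(np.full((n, n, n), density), sp, origin)
    masks = {"body": body, "skeleton": sphere,
             "spleen": np.zeros((n, n, n), dtype=bool)}
    return grid, StructureSet(grid, masks)
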
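"""Voxel grids, structure sets and volume I/O.

Conventions
-----------
Arrays are indexed ``(x, y, z)`` with ``x`` left-right, ``y``
anterior-posterior (ventral low, dorsal high) and ``z`` cranio-caudal
(caudal low, cranial high).  Indices are 0-based; the world coordinate of
the *center* of voxel ``(0, 0, 0)`` is ``origin`` (mm) and voxel centers
are spaced by ``spacing`` (mm).  Densities are g/cm^3.

MetaImage (``.mha``/``.mhd``) and NRRD (``.nrrd``) files are read and
written through SimpleITK; the ITK ``(z, y, x)`` array layout is
transposed at the boundary so the in-memory convention above holds
everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping

import numpy as np
import SimpleITK as sitk

__all__ = ["VoxelGrid", "StructureSet", "write_volume", "read_volume", "read_mask"]

_SUPPORTED_EXT = {".mha", ".mhd", ".nrrd"}


@dataclass
class VoxelGrid:
    """A density volume on a regular grid.

    Parameters
    ----------
    density:
        ``(nx, ny, nz)`` array of mass densities in g/cm^3.
    spacing:
        voxel spacing in mm per axis.
    origin:
        world coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    """

    density: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.density.ndim != 3:
            raise ValueError("density must be a 3-D array")
        if any(d < 8 for d in self.density.shape):
            raise ValueError("grid must be at least 8 voxels per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacings must be positive")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.density.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates (mm) of voxel centers, ``(n, 3)``.

        With ``mask`` given, only centers of True voxels (C order).
        """
        if mask is None:
            idx = np.indices(self.dims).reshape(3, -1).T
        else:
            idx = np.argwhere(np.asarray(mask, dtype=bool))
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices for world points (mm)."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def extent_mm(self) -> np.ndarray:
        """``(3, 2)`` world bounds of the grid (outer voxel faces)."""
        lo = np.asarray(self.origin) - 0.5 * np.asarray(self.spacing)
        hi = lo + np.asarray(self.dims) * np.asarray(self.spacing)
        return np.stack([lo, hi], axis=1)


@dataclass
class StructureSet:
    """Named binary masks sharing one grid.

    The canonical phantom carries ``skeleton, spleen, lungs, kidneys,
    liver, heart, bowel, body``; reduced sets (e.g. body only) are
    permitted for debugging, and consumers that need specific structures
    validate their presence via :meth:`require`.
    """

    grid: VoxelGrid
    masks: Dict[str, np.ndarray] = field(default_factory=dict)

    REQUIRED = ("skeleton", "spleen", "lungs", "kidneys", "liver", "heart", "bowel", "body")

    def __post_init__(self) -> None:
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != self.grid.dims:
                raise ValueError(f"mask {name!r} shape {m.shape} != grid dims {self.grid.dims}")
            self.masks[name] = m
        self.validate()

    def validate(self) -> None:
        body = self.masks.get("body")
        if body is not None:
            for name, m in self.masks.items():
                if name != "body" and np.any(m & ~body):
                    raise ValueError(f"mask {name!r} extends outside the body")
        if "lungs" in self.masks and "kidneys" in self.masks:
            if np.any(self.masks["lungs"] & self.masks["kidneys"]):
                raise ValueError("lungs and kidneys masks overlap")
        oars = ("lungs", "kidneys", "liver", "heart", "bowel")
        for tgt in ("skeleton", "spleen"):
            if tgt not in self.masks:
                continue
            for oar in oars:
                if oar in self.masks and np.any(self.masks[tgt] & self.masks[oar]):
                    raise ValueError(f"{tgt} overlaps OAR {oar!r}")

    def require(self, names: Iterable[str]) -> None:
        missing = [n for n in names if n not in self.masks]
        if missing:
            raise KeyError(f"missing structure masks: {missing}")

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.masks:
            raise KeyError(f"missing structure mask: {name!r}")
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def names(self) -> list[str]:
        return list(self.masks)


def _check_ext(path: Path) -> None:
    if path.suffix.lower() not in _SUPPORTED_EXT:
        raise ValueError(
            f"unsupported volume extension {path.suffix!r}; use one of {sorted(_SUPPORTED_EXT)}"
        )


def write_volume(path: str | Path, volume: VoxelGrid | np.ndarray,
                 grid: VoxelGrid | None = None) -> Path:
    """Write a density grid or a binary mask to MetaImage/NRRD.

    Masks are stored as 8-bit volumes; a mask write needs ``grid`` for
    spacing/origin metadata.
    """
    path = Path(path)
    _check_ext(path)
    if isinstance(volume, VoxelGrid):
        arr = volume.density
        ref = volume
    else:
        arr = np.asarray(volume)
        if grid is None:
            raise ValueError("writing a bare array requires a reference grid")
        if arr.shape != grid.dims:
            raise ValueError(f"array shape {arr.shape} != grid dims {grid.dims}")
        ref = grid
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in ref.spacing))
    img.SetOrigin(tuple(float(o) for o in ref.origin))
    sitk.WriteImage(img, str(path))
    return path


def read_volume(path: str | Path) -> VoxelGrid:
    """Read a MetaImage/NRRD density volume."""
    path = Path(path)
    _check_ext(path)
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VoxelGrid(arr.astype(np.float64), tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def read_mask(path: str | Path, grid: VoxelGrid) -> np.ndarray:
    """Read a binary mask and check it matches ``grid``'s dims."""
    path = Path(path)
    _check_ext(path)
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    if arr.shape != grid.dims:
        raise ValueError(f"mask dims {arr.shape} do not match reference grid {grid.dims}")
    return arr > 0
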
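"""Radiological path lengths through a voxel grid.

Siddon-style exact traversal: the areal density (g/cm^2) along a segment
is the sum of voxel density times the geometric intersection length of
the segment with each traversed voxel.  The inner loops are numba-jitted;
a batched entry point traces many voxel-center endpoints from a common
source, which is how the dose engine computes per-voxel radiological
depth for a field.
"""

from __future__ import annotations

import numba
import numpy as np

from .grids import VoxelGrid

__all__ = ["radiological_path", "radiological_depths"]


@numba.njit(cache=True, fastmath=False)
def _trace_one(density, sx, sy, sz, ex, ey, ez, lox, loy, loz, spx, spy, spz):
    """Areal density (g/cm^2) from (sx,sy,sz) to (ex,ey,ez), world mm."""
    dx, dy, dz = ex - sx, ey - sy, ez - sz
    seg_len = np.sqrt(dx * dx + dy * dy + dz * dz)
    if seg_len == 0.0:
        return 0.0
    nx, ny, nz = density.shape
    # clip parameter range [t0, t1] to the grid bounding box (slab method)
    t0, t1 = 0.0, 1.0
    for axis in range(3):
        if axis == 0:
            d, s, lo, hi = dx, sx, lox, lox + nx * spx
        elif axis == 1:
            d, s, lo, hi = dy, sy, loy, loy + ny * spy
        else:
            d, s, lo, hi = dz, sz, loz, loz + nz * spz
        if d == 0.0:
            if s < lo or s > hi:
                return 0.0
        else:
            ta = (lo - s) / d
            tb = (hi - s) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    if t0 >= t1:
        return 0.0
    # entry voxel
    px = sx + t0 * dx
    py = sy + t0 * dy
    pz = sz + t0 * dz
    ix = int(np.floor((px - lox) / spx))
    iy = int(np.floor((py - loy) / spy))
    iz = int(np.floor((pz - loz) / spz))
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix > nx - 1:
        ix = nx - 1
    if iy > ny - 1:
        iy = ny - 1
    if iz > nz - 1:
        iz = nz - 1
    stepx = 1 if dx > 0 else (-1 if dx < 0 else 0)
    stepy = 1 if dy > 0 else (-1 if dy < 0 else 0)
    stepz = 1 if dz > 0 else (-1 if dz < 0 else 0)
    big = 1e30
    if dx != 0.0:
        nxt = lox + (ix + (1 if stepx > 0 else 0)) * spx
        tmaxx = (nxt - sx) / dx
        tdx = spx / abs(dx)
    else:
        tmaxx, tdx = big, big
    if dy != 0.0:
        nxt = loy + (iy + (1 if stepy > 0 else 0)) * spy
        tmaxy = (nxt - sy) / dy
        tdy = spy / abs(dy)
    else:
        tmaxy, tdy = big, big
    if dz != 0.0:
        nxt = loz + (iz + (1 if stepz > 0 else 0)) * spz
        tmaxz = (nxt - sz) / dz
        tdz = spz / abs(dz)
    else:
        tmaxz, tdz = big, big
    total = 0.0
    t = t0
    while t < t1 - 1e-14:
        if tmaxx <= tmaxy and tmaxx <= tmaxz:
            t_next = tmaxx
        elif tmaxy <= tmaxz:
            t_next = tmaxy
        else:
            t_next = tmaxz
        if t_next > t1:
            t_next = t1
        if t_next > t:
            total += density[ix, iy, iz] * (t_next - t)
        t = t_next
        if t >= t1 - 1e-14:
            break
        if tmaxx <= tmaxy and tmaxx <= tmaxz:
            ix += stepx
            tmaxx += tdx
            if ix < 0 or ix >= nx:
                break
        elif tmaxy <= tmaxz:
            iy += stepy
            tmaxy += tdy
            if iy < 0 or iy >= ny:
                break
        else:
            iz += stepz
            tmaxz += tdz
            if iz < 0 or iz >= nz:
                break
    # total is sum(density * dt); multiply by segment length (mm -> cm)
    return total * seg_len * 0.1


@numba.njit(cache=True, parallel=False)
def _trace_many(density, src, targets, lo, sp):
    out = np.empty(targets.shape[0])
    for i in range(targets.shape[0]):
        out[i] = _trace_one(
            density, src[0], src[1], src[2],
            targets[i, 0], targets[i, 1], targets[i, 2],
            lo[0], lo[1], lo[2], sp[0], sp[1], sp[2],
        )
    return out


def radiological_path(grid: VoxelGrid, src, dst) -> float:
    """Areal density (g/cm^2) of the segment src->dst through ``grid``.

    Exactly symmetric in its endpoints (the traversal direction is
    canonicalized), and 0 when the segment misses the grid.
    """
    a = np.asarray(src, dtype=np.float64)
    b = np.asarray(dst, dtype=np.float64)
    # canonical endpoint order makes the fp result order-independent
    if tuple(b.tolist()) < tuple(a.tolist()):
        a, b = b, a
    lo = grid.extent_mm()[:, 0]
    sp = np.asarray(grid.spacing)
    return float(_trace_one(grid.density, a[0], a[1], a[2], b[0], b[1], b[2],
                            lo[0], lo[1], lo[2], sp[0], sp[1], sp[2]))


def radiological_depths(grid: VoxelGrid, src, targets: np.ndarray) -> np.ndarray:
    """Areal densities from one source point to many target points (mm)."""
    lo = grid.extent_mm()[:, 0]
    sp = np.asarray(grid.spacing)
    return _trace_many(grid.density,
                       np.asarray(src, dtype=np.float64),
                       np.ascontiguousarray(targets, dtype=np.float64), lo, sp)
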
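"""Greedy rectangular-aperture decomposition of a fluence map.

A sparse orthogonal collimator forms rectangular apertures with four
tungsten leaf pairs, so a deliverable field is a weighted sum of
axis-aligned rectangles on the beamlet grid.  ``decompose_rectangles``
peels a non-negative fluence map greedily: at each step it selects, by
exhaustive search, the rectangle/weight pair that maximally reduces the
L1 residual, where the weight is the residual minimum inside the
rectangle (so the reconstruction never overshoots the map).  Ties are
broken toward larger area, then smallest (r0, c0) row-major, making the
decomposition deterministic.  The number of rectangles a map needs is
emergent — it grows with the size and complexity of the target region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numba
import numpy as np

__all__ = ["RectangleAperture", "decompose_rectangles", "DecompositionResult"]

_TIE_REL = 1e-12


@dataclass(frozen=True)
class RectangleAperture:
    """One weighted rectangle: half-open index intervals on the beamlet grid."""

    field: int
    r0: int
    r1: int
    c0: int
    c1: int
    weight: float

    def __post_init__(self) -> None:
        if not (self.r0 < self.r1 and self.c0 < self.c1):
            raise ValueError("rectangle intervals must be non-empty")
        if self.weight <= 0:
            raise ValueError("rectangle weight must be positive")

    @property
    def area(self) -> int:
        return (self.r1 - self.r0) * (self.c1 - self.c0)

    def indicator(self, shape: Tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape)
        out[self.r0:self.r1, self.c0:self.c1] = 1.0
        return out


@numba.njit(cache=True)
def _best_rectangle(res):
    """Exhaustive argmax of weight*area with deterministic tie-breaks.

    weight = min of the residual inside the rectangle.  Returns
    (r0, r1, c0, c1, weight, score); score 0 when the residual is
    everywhere non-positive.
    """
    nr, nc = res.shape
    best_score = 0.0
    best = (-1, -1, -1, -1, 0.0)
    colmin = np.empty(nc)
    for r0 in range(nr):
        for j in range(nc):
            colmin[j] = 1e300
        for r1 in range(r0, nr):
            for j in range(nc):
                v = res[r1, j]
                if v < colmin[j]:
                    colmin[j] = v
            h = r1 - r0 + 1
            for c0 in range(nc):
                m = 1e300
                for c1 in range(c0, nc):
                    if colmin[c1] < m:
                        m = colmin[c1]
                    if m <= 0.0:
                        break
                    score = m * h * (c1 - c0 + 1)
                    better = False
                    if score > best_score * (1.0 + _TIE_REL):
                        better = True
                    elif score >= best_score * (1.0 - _TIE_REL) and best[0] >= 0:
                        # tie: prefer larger area, then smallest (r0, c0) row-major
                        area = h * (c1 - c0 + 1)
                        barea = (best[1] - best[0] + 1) * (best[3] - best[2] + 1)
                        if area > barea:
                            better = True
                        elif area == barea:
                            if (r0, c0) < (best[0], best[2]):
                                better = True
                    if better:
                        best_score = score
                        best = (r0, r1, c0, c1, m)
    return best[0], best[1], best[2], best[3], best[4], best_score


@dataclass
class DecompositionResult:
    rectangles: List[RectangleAperture]
    achieved_rel_error: float
    budget_exhausted: bool

    def reconstruct(self, shape: Tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape)
        for r in self.rectangles:
            out[r.r0:r.r1, r.c0:r.c1] += r.weight
        return out


def decompose_rectangles(fluence_map: np.ndarray, tol: float = 0.02,
                         budget: int = 128, field: int = 0) -> DecompositionResult:
    """Decompose a non-negative map into weighted rectangles.

    Stops when the L1 residual falls to ``tol`` times the map's L1 norm
    or when ``budget`` rectangles have been peeled (then flagged as
    ``budget_exhausted`` with the partial result).
    """
    if not (0 < tol < 1):
        raise ValueError("tol must be in (0, 1)")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    m = np.ascontiguousarray(fluence_map, dtype=np.float64)
    if m.ndim != 2:
        raise ValueError("fluence map must be 2-D")
    if np.any(m < 0):
        raise ValueError("fluence map must be non-negative")
    total = float(np.abs(m).sum())
    rects: List[RectangleAperture] = []
    if total == 0.0:
        return DecompositionResult(rects, 0.0, False)
    res = m.copy()
    while len(rects) < budget:
        rel = float(res.sum()) / total
        if rel <= tol:
            return DecompositionResult(rects, rel, False)
        r0, r1, c0, c1, w, score = _best_rectangle(res)
        if score <= 0.0:
            return DecompositionResult(rects, rel, False)
        rects.append(RectangleAperture(field, r0, r1 + 1, c0, c1 + 1, float(w)))
        res[r0:r1 + 1, c0:c1 + 1] -= w
    rel = float(np.maximum(res, 0.0).sum()) / total
    return DecompositionResult(rects, rel, rel > tol)
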
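"""Fluence-map optimization by monotone FISTA with a TV prox.

The inverse problem is a composite objective over the non-negative
beamlet weight vector ``x``::

    F(x) = sum_s (w_s / n_s) * || penalty_s(D_s x) ||^2  +  lam * TV(x)

where each structure ``s`` contributes a one-sided quadratic: targets
penalize underdose below their prescription, organs at risk (and the
integral-dose region) penalize overdose above their goal.  ``TV`` is the
anisotropic total variation of each field's fluence map along its two
leaf axes, whose prox (jointly with the non-negativity constraint) is
computed exactly by Dykstra-iterated row/column 1-D TV solves.

The solver is FISTA with backtracking on the Lipschitz estimate, a
gradient-based adaptive restart, and the monotone (MFISTA) safeguard so
the recorded objective trace is non-increasing.  Cold start at zero;
deterministic for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np

from .engine import DoseInfluenceMatrix
from .grids import StructureSet
from .tvprox import prox_tv_row_col

__all__ = ["StructureGoal", "ObjectiveSpec", "FluencePlan", "optimize_fluence"]


@dataclass
class StructureGoal:
    """One structure's term in the objective.

    kind 'target': quadratic underdose penalty below ``goal_gy``;
    kind 'oar': quadratic overdose penalty above ``goal_gy``.
    """

    weight: float
    goal_gy: float
    kind: str = "oar"

    def __post_init__(self) -> None:
        if self.kind not in ("target", "oar"):
            raise ValueError("kind must be 'target' or 'oar'")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass
class ObjectiveSpec:
    """Objective weights and solver controls.

    ``tv_lambda_rel`` scales the TV strength relative to the estimated
    Lipschitz constant of the smooth part (so its effect is invariant to
    the overall scale of the influence matrix); ``tv_lambda_abs``, when
    set, pins the TV weight in absolute units instead.
    """

    goals: Dict[str, StructureGoal]
    tv_lambda_rel: float = 0.05
    tv_lambda_abs: float | None = None
    max_iter: int = 2000
    tol: float = 1e-6
    tol_window: int = 10

    def __post_init__(self) -> None:
        if not any(g.kind == "target" and g.weight > 0 for g in self.goals.values()):
            raise ValueError("objective needs a target structure with positive weight")
        if self.tv_lambda_rel < 0:
            raise ValueError("TV strength must be >= 0")
        if self.max_iter < 1:
            raise ValueError("iteration cap must be >= 1")


@dataclass
class FluencePlan:
    """Optimized per-field fluence maps plus the objective trace."""

    maps: List[np.ndarray]
    trace: np.ndarray
    converged: bool
    n_iter: int

    @property
    def weights(self) -> np.ndarray:
        return np.concatenate([m.ravel() for m in self.maps])


def _structure_rows(D: DoseInfluenceMatrix,
                    structures: "StructureSet | Mapping[str, np.ndarray]",
                    names: Sequence[str]) -> Dict[str, np.ndarray]:
    """Map structure masks (or precomputed row indices) to support rows."""
    masks = structures.masks if isinstance(structures, StructureSet) else structures
    rows: Dict[str, np.ndarray] = {}
    n_vox = int(np.prod(D.grid_dims))
    lut = np.full(n_vox, -1, dtype=np.int64)
    lut[D.voxel_indices] = np.arange(D.voxel_indices.size)
    for name in names:
        if name not in masks:
            raise KeyError(f"objective references unknown structure {name!r}")
        m = np.asarray(masks[name])
        if m.dtype == bool:
            r = lut[np.flatnonzero(m.reshape(-1))]
            r = r[r >= 0]
        else:
            r = m.astype(np.int64).ravel()
        if r.size == 0:
            raise ValueError(f"structure {name!r} has no voxels in the planning support")
        rows[name] = r
    return rows


def optimize_fluence(D: DoseInfluenceMatrix,
                     structures: "StructureSet | Mapping[str, np.ndarray]",
                     objective: ObjectiveSpec) -> FluencePlan:
    """Minimize the composite objective over non-negative fluence.

    Non-convergence at the iteration cap is flagged on the returned plan
    (``converged=False``), not raised.
    """
    A = D.matrix.tocsr()
    n_beam = A.shape[1]
    rows = _structure_rows(D, structures, list(objective.goals))
    terms = [(name, objective.goals[name], rows[name]) for name in objective.goals
             if objective.goals[name].weight > 0]

    shapes = [(g.n_rows, g.n_cols) for g in D.geometries]
    offs = np.concatenate([[0], np.cumsum([r * c for r, c in shapes])])
    if offs[-1] != n_beam:
        raise ValueError("geometry beamlet counts do not match the matrix")

    def smooth(dose_vec):
        f = 0.0
        for _, goal, r in terms:
            d = dose_vec[r]
            e = np.maximum(goal.goal_gy - d, 0.0) if goal.kind == "target" \
                else np.maximum(d - goal.goal_gy, 0.0)
            f += goal.weight / r.size * float(e @ e)
        return f

    def gradient(dose_vec):
        mult = np.zeros(A.shape[0])
        for _, goal, r in terms:
            d = dose_vec[r]
            if goal.kind == "target":
                np.add.at(mult, r, -2.0 * goal.weight / r.size * np.maximum(goal.goal_gy - d, 0.0))
            else:
                np.add.at(mult, r, 2.0 * goal.weight / r.size * np.maximum(d - goal.goal_gy, 0.0))
        return A.T @ mult

    # Lipschitz upper bound of the smooth part: 2 * lmax(A^T W A) with the
    # per-voxel weight w_s/n_s summed over structures (one-sided Hessian <= full)
    wvox = np.zeros(A.shape[0])
    for _, goal, r in terms:
        np.add.at(wvox, r, 2.0 * goal.weight / r.size)
    rng = np.random.default_rng(0)
    v = rng.standard_normal(n_beam)
    v /= np.linalg.norm(v)
    L = 1.0
    for _ in range(25):
        u = A.T @ (wvox * (A @ v))
        nrm = np.linalg.norm(u)
        if nrm == 0:
            break
        L = nrm
        v = u / nrm
    L = max(L, 1e-12)
    lam = (objective.tv_lambda_abs if objective.tv_lambda_abs is not None
           else objective.tv_lambda_rel * L)

    def prox(vec, step):
        if lam == 0:
            return np.maximum(vec, 0.0)
        out = np.empty_like(vec)
        for k, (r, c) in enumerate(shapes):
            seg = vec[offs[k]:offs[k + 1]].reshape(r, c)
            out[offs[k]:offs[k + 1]] = prox_tv_row_col(seg, lam * step).ravel()
        return out

    def tv_value(vec):
        if lam == 0:
            return 0.0
        t = 0.0
        for k, (r, c) in enumerate(shapes):
            m = vec[offs[k]:offs[k + 1]].reshape(r, c)
            t += float(np.abs(np.diff(m, axis=0)).sum() + np.abs(np.diff(m, axis=1)).sum())
        return lam * t

    x = np.zeros(n_beam)
    y = x.copy()
    t_mom = 1.0
    dose_x = np.zeros(A.shape[0])
    F_x = smooth(dose_x) + tv_value(x)
    trace = [F_x]
    converged = False
    it = 0
    for it in range(1, objective.max_iter + 1):
        dose_y = A @ y
        f_y = smooth(dose_y)
        g = gradient(dose_y)
        # backtracking on L
        while True:
            z = prox(y - g / L, 1.0 / L)
            dz = z - y
            dose_z = A @ z
            f_z = smooth(dose_z)
            if f_z <= f_y + g @ dz + 0.5 * L * float(dz @ dz) + 1e-12 * max(1.0, abs(f_y)):
                break
            L *= 2.0
        F_z = f_z + tv_value(z)
        # monotone safeguard: keep the better of z and the previous iterate
        if F_z <= F_x:
            x_new, F_new, dose_new = z, F_z, dose_z
        else:
            x_new, F_new, dose_new = x, F_x, dose_x
        # gradient-based adaptive restart: drop momentum when the update
        # direction opposes the momentum direction
        if float((y - z) @ (z - x)) > 0.0:
            t_new = 1.0
            y = x_new.copy()
        else:
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
            y = (x_new + (t_mom / t_new) * (z - x_new)
                 + ((t_mom - 1.0) / t_new) * (x_new - x))
        x, F_x, dose_x = x_new, F_new, dose_new
        t_mom = t_new
        trace.append(F_x)
        w = objective.tol_window
        if it >= w:
            past = trace[-w - 1]
            if abs(past - F_x) <= objective.tol * max(abs(F_x), 1e-12):
                converged = True
                break

    maps = [x[offs[k]:offs[k + 1]].reshape(r, c).copy() for k, (r, c) in enumerate(shapes)]
    return FluencePlan(maps, np.asarray(trace), converged, it)
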
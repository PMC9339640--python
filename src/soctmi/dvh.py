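"""Dose-volume histograms, scalar dose metrics and cohort statistics.

All scalar metrics are percentages of the prescription dose.  Cohort
summaries use the sample standard deviation (n-1 denominator), and
report rounding is one decimal, round-half-away-from-zero — the
conventions of the published comparison tables this module is designed
to reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grids import StructureSet

__all__ = [
    "DVHCurve", "compute_dvh", "average_dvh",
    "median_dose_percent", "mean_dose_percent", "integral_dose_percent",
    "compute_metric_table", "summarize_cohort", "compare_plans",
    "round_half_away",
]


def round_half_away(x, decimals: int = 1):
    """Round half away from zero (the tables' convention; numpy rounds half to even)."""
    x = np.asarray(x, dtype=np.float64)
    factor = 10.0**decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of the structure receiving >= each dose edge."""

    structure: str
    edges_gy: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.edges_gy = np.asarray(self.edges_gy, dtype=np.float64)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=np.float64)
        if self.edges_gy.shape != self.volume_fraction.shape:
            raise ValueError("edges and volume fractions must align")

    def v_at(self, dose_gy: float) -> float:
        """V(d): fraction receiving at least ``dose_gy`` (step lookup)."""
        i = np.searchsorted(self.edges_gy, dose_gy, side="right") - 1
        if i < 0:
            return 1.0
        return float(self.volume_fraction[i])

    def d50_gy(self) -> float:
        """Largest dose edge still covering half the volume."""
        idx = np.flatnonzero(self.volume_fraction >= 0.5)
        return float(self.edges_gy[idx[-1]]) if idx.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dose_gy": self.edges_gy,
                             "volume_fraction": self.volume_fraction})


def compute_dvh(dose: np.ndarray, mask: np.ndarray, bin_width_gy: float = 0.1,
                structure: str = "", max_dose_gy: float | None = None) -> DVHCurve:
    """Exact cumulative DVH of the masked voxels on uniform dose bins."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty structure mask")
    if bin_width_gy <= 0:
        raise ValueError("bin width must be positive")
    vals = np.sort(np.asarray(dose)[mask].ravel())
    top = max_dose_gy if max_dose_gy is not None else float(vals[-1])
    edges = np.arange(0.0, top + 2 * bin_width_gy, bin_width_gy)
    frac = 1.0 - np.searchsorted(vals, edges, side="left") / vals.size
    return DVHCurve(structure, edges, frac)


def average_dvh(curves: Sequence[DVHCurve]) -> DVHCurve:
    """Pointwise mean of cohort DVHs sharing the same bin edges."""
    if not curves:
        raise ValueError("no curves to average")
    edges = curves[0].edges_gy
    for c in curves[1:]:
        if c.edges_gy.shape != edges.shape or not np.allclose(c.edges_gy, edges):
            raise ValueError("DVH curves have mismatched bin edges")
    vf = np.mean([c.volume_fraction for c in curves], axis=0)
    return DVHCurve(curves[0].structure, edges.copy(), vf)


def _masked(dose: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty structure mask")
    return np.asarray(dose)[mask]


def median_dose_percent(dose: np.ndarray, mask: np.ndarray, prescription_gy: float) -> float:
    """D50 as a percentage of prescription (midpoint-interpolated median)."""
    if prescription_gy <= 0:
        raise ValueError("prescription must be positive")
    return 100.0 * float(np.median(_masked(dose, mask))) / prescription_gy


def mean_dose_percent(dose: np.ndarray, mask: np.ndarray, prescription_gy: float) -> float:
    if prescription_gy <= 0:
        raise ValueError("prescription must be positive")
    return 100.0 * float(np.mean(_masked(dose, mask))) / prescription_gy


def integral_dose_percent(dose: np.ndarray, region_mask: np.ndarray,
                          prescription_gy: float) -> float:
    """Mean dose over the integral-dose region (body minus skeleton and
    spleen), as % of prescription.  Unit-mass weighting."""
    return mean_dose_percent(dose, region_mask, prescription_gy)


def compute_metric_table(dose: np.ndarray, structures: StructureSet,
                         prescription_gy: float, subject: str, plan: str,
                         structure_names: Iterable[str] = ("lungs", "kidneys",
                                                           "liver", "heart", "bowel"),
                         integral_region: np.ndarray | None = None) -> pd.DataFrame:
    """Per-structure metric rows for one subject/plan.

    The ``integral`` row's ``mean_pct`` is the integral dose percent.
    """
    rows: List[dict] = []
    for name in structure_names:
        m = structures[name]
        rows.append({"subject": subject, "plan": plan, "structure": name,
                     "median_pct": median_dose_percent(dose, m, prescription_gy),
                     "mean_pct": mean_dose_percent(dose, m, prescription_gy)})
    if integral_region is not None:
        rows.append({"subject": subject, "plan": plan, "structure": "integral",
                     "median_pct": median_dose_percent(dose, integral_region, prescription_gy),
                     "mean_pct": integral_dose_percent(dose, integral_region, prescription_gy)})
    return pd.DataFrame(rows)


def summarize_cohort(metrics: pd.DataFrame, value: str = "median_pct") -> pd.DataFrame:
    """Cohort mean and sample SD (n-1) per (plan, structure).

    ``mean_1dp``/``sd_1dp`` carry the report rounding; full precision is
    retained in ``mean``/``sd``.  SD is absent (NaN) for n < 2.
    """
    g = metrics.groupby(["plan", "structure"])[value]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan,
                n="count").reset_index()
    out["mean_1dp"] = round_half_away(out["mean"].to_numpy())
    out["sd_1dp"] = np.where(np.isnan(out["sd"]), np.nan,
                             round_half_away(np.nan_to_num(out["sd"].to_numpy())))
    return out


def compare_plans(metrics: pd.DataFrame, plan_a: str, plan_b: str,
                  value: str = "median_pct", test: str = "ttest") -> pd.DataFrame:
    """Paired comparison of two plans on the same subjects.

    Per structure: mean and SD of the per-subject paired differences
    (A - B), the reduction versus prescription ``100 - mean(B)``, and a
    two-sided p-value from a paired t-test (default) or Wilcoxon
    signed-rank test.
    """
    if test not in ("ttest", "wilcoxon"):
        raise ValueError("test must be 'ttest' or 'wilcoxon'")
    rows = []
    for structure, sub in metrics.groupby("structure"):
        a = sub[sub["plan"] == plan_a].set_index("subject")[value]
        b = sub[sub["plan"] == plan_b].set_index("subject")[value]
        if set(a.index) != set(b.index) or a.index.has_duplicates:
            raise ValueError(f"subject mismatch between plans for {structure!r}")
        b = b.reindex(a.index)
        diff = (a - b).to_numpy()
        if test == "ttest":
            p = stats.ttest_rel(a.to_numpy(), b.to_numpy()).pvalue if len(diff) > 1 else np.nan
        else:
            p = stats.wilcoxon(a.to_numpy(), b.to_numpy()).pvalue if len(diff) > 1 else np.nan
        rows.append({
            "structure": structure,
            "n": len(diff),
            f"mean_{plan_a}": float(a.mean()),
            f"mean_{plan_b}": float(b.mean()),
            "mean_diff": float(diff.mean()),
            "sd_diff": float(diff.std(ddof=1)) if len(diff) > 1 else np.nan,
            "reduction_vs_prescription": 100.0 - float(b.mean()),
            "p_value": float(p) if p == p else np.nan,
        })
    return pd.DataFrame(rows)
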
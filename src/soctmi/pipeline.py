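"""Reproducible cohort pipeline and report generation.

For each subject seed: generate a phantom, plan both techniques, compute
the metric rows and DVH curves; then aggregate the cohort (mean ± SD),
run the paired comparison, and emit the report files.  Fully
deterministic for a fixed master seed (subject seeds are master + index).

``verify_reference_statistics`` is a self-test of the analytics stack:
it recomputes every cohort Average/SD cell and reduction figure from a
bundled reference cohort of per-subject median organ doses and checks
them against the expected values to one decimal.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from io import StringIO
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .dvh import (DVHCurve, average_dvh, compare_plans, compute_dvh,
                  compute_metric_table, round_half_away, summarize_cohort)
from .grids import StructureSet, VoxelGrid
from .phantom import PhantomConfig, generate_phantom, integral_dose_region, ptv_mask
from .planner3d import auto_place_regions, compute_3d_plan
from .soc import SOCPlanConfig, plan_soc_tmi

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "report_table",
           "verify_reference_statistics", "reference_cohort"]

_OARS = ("bowel", "heart", "kidneys", "lungs", "liver")


@dataclass
class RunConfig:
    """Top-level study configuration."""

    cohort_size: int = 5
    master_seed: int = 0
    prescription_gy: float = 12.0
    grid_spacing_mm: float = 1.0
    jitter_mm: float = 0.5
    dvh_bin_gy: float = 0.25
    # fixed common axis for cohort-averaged curves; generously above the
    # bone/junction peaks of the baseline plan (~6x prescription)
    dvh_max_gy: float = 100.0
    soc: SOCPlanConfig = field(default_factory=lambda: SOCPlanConfig(max_iter=300))

    def __post_init__(self) -> None:
        if self.cohort_size < 1:
            raise ValueError("cohort size must be >= 1")
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be positive")
        self.soc.prescription_gy = self.prescription_gy

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "soc" in raw:
            raw["soc"] = SOCPlanConfig(**raw["soc"])
        return cls(**raw)


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    summary: pd.DataFrame
    comparison: pd.DataFrame
    average_dvhs: Dict[str, Dict[str, DVHCurve]]  # plan -> structure -> curve
    manifest: dict
    out_dir: Optional[Path] = None


def _config_hash(config: RunConfig) -> str:
    def enc(o):
        if hasattr(o, "__dict__"):
            return {k: enc(v) for k, v in o.__dict__.items()}
        if isinstance(o, (list, tuple)):
            return [enc(v) for v in o]
        if isinstance(o, dict):
            return {k: enc(v) for k, v in o.items()}
        return o
    blob = json.dumps(enc(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _subject_curves(dose, structures, ptv, bin_gy, max_gy) -> Dict[str, DVHCurve]:
    curves = {}
    for name in _OARS:
        curves[name] = compute_dvh(dose, structures[name], bin_gy, name, max_gy)
    curves["ptv"] = compute_dvh(dose, ptv, bin_gy, "ptv", max_gy)
    return curves


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full cohort study; write report files when ``out_dir`` given."""
    sp = config.grid_spacing_mm
    metric_frames: List[pd.DataFrame] = []
    curves: Dict[str, Dict[str, List[DVHCurve]]] = {"SOC": {}, "3D": {}}
    stages: List[dict] = []

    for i in range(config.cohort_size):
        sid = f"m{i + 1}"
        seed = config.master_seed + i
        stage = "phantom"
        try:
            pcfg = PhantomConfig(spacing=(sp, sp, sp), seed=seed, jitter_mm=config.jitter_mm)
            grid, structures = generate_phantom(pcfg)
            ptv = ptv_mask(structures, config.soc.ptv_margin_mm)
            region = integral_dose_region(structures)

            stage = "soc_plan"
            soc = plan_soc_tmi(grid, structures, replace(config.soc), keep_influence=False)

            stage = "3d_plan"
            regions = auto_place_regions(structures)
            p3d = compute_3d_plan(grid, structures, regions, config.prescription_gy,
                                  config.soc.attenuation, config.soc.sid_mm,
                                  config.soc.beamlet_mm)

            stage = "metrics"
            for plan_name, dose in (("SOC", soc.dose), ("3D", p3d.dose)):
                metric_frames.append(compute_metric_table(
                    dose, structures, config.prescription_gy, sid, plan_name,
                    structure_names=_OARS, integral_region=region))
                subj = _subject_curves(dose, structures, ptv,
                                       config.dvh_bin_gy, config.dvh_max_gy)
                for sname, curve in subj.items():
                    curves[plan_name].setdefault(sname, []).append(curve)
            stages.append({"subject": sid, "seed": seed,
                           "soc_rectangles": soc.rectangles_per_field,
                           "soc_converged": bool(soc.optimized.converged),
                           "junction_clusters": len(p3d.junctions)})
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline stage {stage!r} failed for subject {sid}") from exc

    metrics = (pd.concat(metric_frames, ignore_index=True) if metric_frames
               else pd.DataFrame(columns=["subject", "plan", "structure",
                                          "median_pct", "mean_pct"]))
    summary = summarize_cohort(metrics) if len(metrics) else pd.DataFrame(
        columns=["plan", "structure", "mean", "sd", "n", "mean_1dp", "sd_1dp"])
    comparison = (compare_plans(metrics, "3D", "SOC") if config.cohort_size >= 1
                  and len(metrics) else pd.DataFrame())
    avg = {plan: {s: average_dvh(cs) for s, cs in per.items()}
           for plan, per in curves.items()}

    manifest = {"config_hash": _config_hash(config),
                "cohort_size": config.cohort_size,
                "master_seed": config.master_seed,
                "prescription_gy": config.prescription_gy,
                "grid_spacing_mm": sp,
                "stages": stages}

    result = PipelineResult(metrics, summary, comparison, avg, manifest)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.10g"
        metrics.to_csv(out / "metrics.csv", index=False, float_format=fmt)
        summary.to_csv(out / "summary.csv", index=False, float_format=fmt)
        comparison.to_csv(out / "comparison.csv", index=False, float_format=fmt)
        report_table(metrics).to_csv(out / "report_table.csv", float_format=fmt)
        for plan, per in avg.items():
            for sname, curve in per.items():
                curve.to_frame().to_csv(out / f"dvh_{plan}_{sname}.csv",
                                        index=False, float_format=fmt)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        result.out_dir = out
    return result


def report_table(metrics: pd.DataFrame, value: str = "median_pct") -> pd.DataFrame:
    """Cohort table in the published layout.

    Per-subject rows, then Average and SD rows; columns grouped by
    structure then plan; all cells rounded to one decimal.
    """
    cols = pd.MultiIndex.from_product([[], []], names=["structure", "plan"])
    if metrics.empty:
        return pd.DataFrame(columns=cols)
    wide = metrics.pivot_table(index="subject", columns=["structure", "plan"],
                               values=value, sort=False)
    order = [s for s in ("bowel", "heart", "kidneys", "lungs", "liver", "integral")
             if s in metrics["structure"].unique()]
    wide = wide.reindex(columns=pd.MultiIndex.from_product(
        [order, ["SOC", "3D"]], names=["structure", "plan"]))
    wide = wide.sort_index()
    avg = wide.mean(axis=0)
    sd = wide.std(axis=0, ddof=1)
    wide.loc["Average"] = avg
    wide.loc["SD"] = sd
    return wide.apply(lambda col: round_half_away(col.to_numpy()), axis=0)


# ----------------------------------------------------------- reference check


def reference_cohort() -> pd.DataFrame:
    """The bundled per-subject reference median doses (% of prescription)."""
    text = resources.files("soctmi.data").joinpath(
        "reference_cohort_median_dose_percent.csv").read_text()
    return pd.read_csv(StringIO(text))


def _expected() -> dict:
    text = resources.files("soctmi.data").joinpath(
        "reference_expected_statistics.json").read_text()
    return json.loads(text)


def verify_reference_statistics(cohort: pd.DataFrame | None = None) -> List[dict]:
    """Recompute the reference cohort statistics and check each cell.

    Returns one record per check: ``{"name", "expected", "computed",
    "passed"}``, comparing at one decimal.  Feeding a perturbed cohort
    makes exactly the affected checks fail, which is the sensitivity
    property the self-test relies on.
    """
    cohort = cohort if cohort is not None else reference_cohort()
    expected = _expected()
    summary = summarize_cohort(cohort)
    comparison = compare_plans(cohort, "3D", "SOC")
    checks: List[dict] = []

    def add(name, exp, comp):
        comp_r = round_half_away(comp)
        checks.append({"name": name, "expected": float(exp),
                       "computed": comp_r, "passed": abs(comp_r - exp) < 1e-9})

    for plan, per in expected["summary"].items():
        for structure, cells in per.items():
            row = summary[(summary["plan"] == plan) & (summary["structure"] == structure)]
            add(f"{plan}/{structure}/mean", cells["mean"], float(row["mean"].iloc[0]))
            add(f"{plan}/{structure}/sd", cells["sd"], float(row["sd"].iloc[0]))
    for structure, exp in expected["paired_reduction"].items():
        row = comparison[comparison["structure"] == structure]
        add(f"paired_reduction/{structure}", exp, float(row["mean_diff"].iloc[0]))
    for structure, exp in expected["reduction_vs_prescription"].items():
        row = comparison[comparison["structure"] == structure]
        add(f"reduction_vs_prescription/{structure}", exp,
            float(row["reduction_vs_prescription"].iloc[0]))
    return checks
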
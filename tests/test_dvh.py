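import numpy as np
import pandas as pd
import pytest

from soctmi.dvh import (DVHCurve, average_dvh, compare_plans, compute_dvh,
                        integral_dose_percent, mean_dose_percent,
                        median_dose_percent, round_half_away, summarize_cohort)
from soctmi.pipeline import reference_cohort


def test_round_half_away_matches_table_convention():
    assert round_half_away(2.25) == 2.3       # numpy's round gives 2.2
    assert round_half_away(-2.25) == -2.3
    assert round_half_away(17.18) == 17.2
    assert round_half_away(9.818) == 9.8


def test_uniform_dose_gives_step_dvh():
    dose = np.full((5, 5, 5), 6.0)
    mask = np.ones((5, 5, 5), bool)
    curve = compute_dvh(dose, mask, 0.5)
    assert curve.v_at(0.0) == 1.0
    assert curve.v_at(6.0) == 1.0
    assert curve.v_at(6.5) == 0.0
    assert np.all(np.diff(curve.volume_fraction) <= 0)
    # differential histogram integrates to one
    assert np.sum(-np.diff(curve.volume_fraction)) == pytest.approx(1.0)


def test_two_level_dose_crosses_at_half_volume():
    dose = np.concatenate([np.full(50, 1.0), np.full(50, 3.0)]).reshape(4, 5, 5)
    mask = np.ones((4, 5, 5), bool)
    curve = compute_dvh(dose, mask, 0.5)
    assert curve.v_at(2.0) == 0.5


def test_dvh_matches_sort_and_count_oracle():
    rng = np.random.default_rng(0)
    dose = rng.uniform(0, 10, (10, 10, 1))
    mask = np.ones(dose.shape, bool)
    curve = compute_dvh(dose, mask, 0.25)
    flat = dose.ravel()
    for d, v in zip(curve.edges_gy, curve.volume_fraction):
        assert v == pytest.approx(np.mean(flat >= d), abs=1e-12)


def test_dvh_rejects_empty_mask():
    with pytest.raises(ValueError, match="empty"):
        compute_dvh(np.ones((3, 3, 3)), np.zeros((3, 3, 3), bool), 0.1)


def test_median_dose_percent_examples():
    mask = np.ones(8, bool)
    assert median_dose_percent(np.full(8, 6.0), mask, 12.0) == 50.0
    three = np.array([1.0, 2.0, 3.0])
    got = median_dose_percent(three, np.ones(3, bool), 12.0)
    assert got == pytest.approx(100.0 * 2.0 / 12.0)
    rng = np.random.default_rng(1)
    dose = rng.uniform(0, 20, 10_000)
    want = 100.0 * np.percentile(dose, 50) / 12.0
    assert median_dose_percent(dose, np.ones(dose.size, bool), 12.0) == \
        pytest.approx(want, abs=1e-12)


def test_integral_dose_percent_examples():
    mask = np.ones(4, bool)
    assert integral_dose_percent(np.full(4, 12.0), mask, 12.0) == 100.0
    assert integral_dose_percent(np.zeros(4), mask, 12.0) == 0.0
    two = np.array([0.0, 12.0])
    assert integral_dose_percent(two, np.ones(2, bool), 12.0) == 50.0
    assert mean_dose_percent(two, np.ones(2, bool), 12.0) == 50.0


def test_cohort_summary_reproduces_reference_cells():
    cohort = reference_cohort()
    summary = summarize_cohort(cohort)
    def cell(plan, structure, col):
        row = summary[(summary["plan"] == plan) & (summary["structure"] == structure)]
        return float(row[col].iloc[0])
    assert round_half_away(cell("SOC", "kidneys", "mean")) == 1.6
    assert round_half_away(cell("SOC", "bowel", "sd")) == 9.8
    assert cell("SOC", "kidneys", "n") == 5


def test_summary_sd_edge_cases():
    df = pd.DataFrame({"subject": ["a", "b", "c"], "plan": "P", "structure": "s",
                       "median_pct": [2.0, 2.0, 2.0]})
    out = summarize_cohort(df)
    assert out["sd"].iloc[0] == 0.0
    single = summarize_cohort(df.iloc[:1])
    assert np.isnan(single["sd"].iloc[0])


def test_compare_plans_reproduces_reference_reductions():
    cohort = reference_cohort()
    comp = compare_plans(cohort, "3D", "SOC").set_index("structure")
    assert round_half_away(comp.loc["lungs", "mean_diff"]) == 48.4
    assert round_half_away(comp.loc["kidneys", "reduction_vs_prescription"]) == 98.4
    assert comp.loc["lungs", "p_value"] < 0.05
    # identical tables on both sides -> zero differences
    soc = cohort[cohort["plan"] == "SOC"]
    both = pd.concat([soc.assign(plan="A"), soc.assign(plan="B")])
    same = compare_plans(both, "A", "B")
    assert np.allclose(same["mean_diff"], 0.0)


def test_compare_plans_rejects_subject_mismatch():
    cohort = reference_cohort()
    broken = cohort[~((cohort["subject"] == "m5") & (cohort["plan"] == "SOC"))]
    with pytest.raises(ValueError, match="mismatch"):
        compare_plans(broken, "3D", "SOC")


def test_wilcoxon_option_runs():
    cohort = reference_cohort()
    comp = compare_plans(cohort, "3D", "SOC", test="wilcoxon")
    assert (comp["p_value"] <= 1.0).all()
    with pytest.raises(ValueError, match="test"):
        compare_plans(cohort, "3D", "SOC", test="bootstrap")


def test_average_dvh_properties():
    edges = np.arange(0, 5.0, 0.5)
    a = DVHCurve("s", edges, (edges <= 2.0).astype(float))
    b = DVHCurve("s", edges, (edges <= 3.0).astype(float))
    avg = average_dvh([a, b])
    assert np.array_equal(average_dvh([a, a]).volume_fraction, a.volume_fraction)
    assert avg.v_at(2.5) == 0.5  # midpoint plateau between the two steps
    rng = np.random.default_rng(2)
    curves = []
    for _ in range(5):
        vf = np.sort(rng.uniform(0, 1, edges.size))[::-1]
        vf[0] = 1.0
        curves.append(DVHCurve("s", edges, vf))
    m = average_dvh(curves)
    assert np.all(np.diff(m.volume_fraction) <= 1e-12)
    with pytest.raises(ValueError, match="bin"):
        average_dvh([a, DVHCurve("s", edges[:-1], a.volume_fraction[:-1])])


def test_d50_from_curve_agrees_with_direct_median():
    rng = np.random.default_rng(3)
    dose = rng.uniform(0, 15, (12, 12, 12))
    mask = rng.random((12, 12, 12)) < 0.4
    bin_w = 0.1
    curve = compute_dvh(dose, mask, bin_w)
    direct = np.median(dose[mask])
    assert abs(curve.d50_gy() - direct) <= bin_w
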
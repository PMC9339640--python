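"""Recompute the reference cohort's summary statistics.

The package bundles a reference table of per-subject median organ doses
(percent of prescription, five subjects, both techniques).  This script
feeds it through the same summarize/compare code used for synthetic
cohorts and prints every recomputed cell next to its expected value —
the self-test of the analytics stack.
"""

from soctmi import verify_reference_statistics

checks = verify_reference_statistics()
width = max(len(c["name"]) for c in checks)
for c in checks:
    mark = "ok" if c["passed"] else "FAIL"
    print(f"[{mark}] {c['name']:<{width}}  computed {c['computed']:6.1f}  "
          f"expected {c['expected']:6.1f}")
n_ok = sum(c["passed"] for c in checks)
print(f"{n_ok}/{len(checks)} statistics reproduced to one decimal")
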
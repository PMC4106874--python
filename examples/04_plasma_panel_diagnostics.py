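"""Evaluate a plasma cfDNA methylation panel on a case/control cohort.

Simulates MSP-style binary calls for a 42-case / 50-control cohort at the
validation study's positivity rates (exact marginals), then computes each
gene's sensitivity, specificity and tie-corrected Mann-Whitney AUC, plus
the any-positive three-gene panel.  For a binary marker the AUC equals
(sensitivity + specificity) / 2; combining genes raises sensitivity while
specificity stays at 100% because controls are never methylated here.
"""

from escmeth import (
    CohortConfig,
    diagnostics_from_calls,
    generate_call_cohort,
)

config = CohortConfig(seed=2)  # default rates = the three-gene study rates
calls = generate_call_cohort(config)
results = diagnostics_from_calls(calls, ["EPB41L3", "GPX3", "COL14A1"])

print(f"{'marker':<10} {'sens%':>6} {'spec%':>6} {'AUC':>6}  95% CI")
for marker, res in results.items():
    print(
        f"{marker:<10} {res.sensitivity_percent:>6} "
        f"{res.specificity_percent:>6} {res.auc:>6.3f}  "
        f"({res.auc_ci_low:.3f}-{res.auc_ci_high:.3f})"
    )
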
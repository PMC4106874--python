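"""Test tumor-tissue methylation calls against clinical covariates.

Simulates the case cohort's clinical table with a planted effect — pT3
tumors are 6x more likely among EPB41L3-methylated cases — and runs the
gene x covariate contingency analysis (Pearson chi-square, or Fisher's
exact test when expected counts drop below 5).  The planted pT association
should surface with a small p-value; other covariates stay null.  The
Bonferroni column flags significance at alpha / n_genes.
"""

from escmeth import (
    CohortConfig,
    clinico_association_report,
    generate_call_cohort,
    generate_clinical_covariates,
)

config = CohortConfig(
    seed=3,
    covariate_effects={"pt": {"T3": {"EPB41L3": 6.0}}},
)
calls = generate_call_cohort(config)
clinical = generate_clinical_covariates(calls, config)

report = clinico_association_report(
    calls, clinical, ["EPB41L3", "GPX3", "COL14A1"],
    compartment="tumor_tissue",
)
report["p_value"] = report["p_value"].round(4)
report["statistic"] = report["statistic"].round(3)
print(report.to_string(index=False))
planted = report[(report["gene"] == "EPB41L3") & (report["covariate"] == "pt")]
print(f"\nplanted pT effect on EPB41L3: p = {planted['p_value'].iloc[0]}")
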
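# Methods

`escmeth` implements the analysis chain of a small-cohort tumor DNA
methylome study with a plasma-biomarker validation arm. This note records
the models, the defaults and why they are what they are, and what the
synthetic data do and do not establish.

## Value scales and transforms

Methylation arrays report a methylated (M) and unmethylated (U)
fluorescence intensity per CpG probe. The package works on two scales:

- beta = M / (M + U + offset), the methylated fraction in [0, 1];
- M-value = log2((M + offset) / (U + offset)), related to beta by the
  logit2 transform M = log2(beta / (1 - beta)).

Differential testing runs on the M scale because its variance is roughly
constant across the methylation range, whereas beta values are
heteroscedastic near 0 and 1. The intensity offset defaults to 1 (a unit
offset keeps dark probes finite without distorting bright ones) and is
exposed as an argument. Beta values of exactly 0 or 1 are clipped to
[1e-6, 1 - 1e-6] with a warning before the logit; the round trip
beta -> M -> beta is exact to 1e-12 inside that range.

## Normalization and unsupervised structure

`quantile_normalize` forces every sample onto the cross-sample rank-mean
reference distribution: sort each sample, average across samples per rank,
and map each sample's values back by rank. Ties within a sample receive
the mean of the reference values over the tied rank span, which makes the
operation idempotent. The method is an assumption — array studies often
say only "normalized" — so it is optional in the pipeline
(`PipelineConfig.normalize`, off by default since the simulator already
emits comparable samples). Box summaries use linear-interpolation
(type-7) quantiles, stated explicitly so the printed five-number
summaries are reproducible elsewhere.

`hierarchical_cluster` is agglomerative with distance
1 - Pearson correlation between item profiles and average linkage, the
common choice for array heatmaps; euclidean distance and
complete/ward linkage are available. Zero-variance items get correlation
0 to everything (with a warning) rather than NaN. Missing values are
never imputed anywhere; operations fail loudly, because silent imputation
at n = 4 per group would be untestable.

## Differential methylation calling

Tumor samples are compared against the pooled adjacent + normal reference
(the two non-tumor groups cluster together, and pooling doubles the
reference size at this scale). Per probe, a two-sample t-test on
M-values; p-values adjusted by Benjamini-Hochberg step-up
(q(i) = min over j >= i of m p(j)/j); a probe is a DMC when q < alpha
(default 0.05) and the effect criterion holds.

Two numerical choices deserve a note:

- **Pooled vs Welch variance.** `dmc_pipeline` defaults to the
  pooled-variance t. With four tumor samples, the Welch test's
  Welch–Satterthwaite degrees of freedom drop to ~6 and its heavy
  critical values cost real power: on the default simulated design
  (10,000 probes, delta-M 2.5, noise SD 0.5) pooled testing recovers
  ~99% of planted probes and Welch only ~83%, at the same ~1% false
  discovery proportion. Pooling also matches how microarray
  class-comparison tools test at this sample size. `group_ttest`
  itself defaults to Welch (the safer choice when group variances may
  differ) and both are selectable everywhere. Probes with zero variance
  in both groups are handled explicitly: equal means give p = 1, unequal
  means give p = 0 with a degeneracy flag.
- **The effect threshold.** "Two-fold methylation change" is ambiguous on
  the M scale. The default reading (`mode="delta"`) is a two-fold change
  of the methylated/unmethylated intensity ratio, i.e.
  |delta-M| >= log2(2) = 1. A literal M-ratio mode (`mode="ratio"`,
  |M_tumor / M_ref| >= 2 or its reciprocal) is provided; neither is
  asserted as canonical.

`summarize_context` reports the CpG-island / shore / shelf / open-sea
composition of hyper- and hypo-DMCs separately, plus the aggregate
island + shore + shelf fraction; a direction with no calls is omitted
rather than reported as 0/0.

## Expression integration

Differential expression uses probe-level Welch t-tests on log2 values
with BH-FDR, then collapses probes to genes keeping the probe with the
highest mean intensity (a standard, if arbitrary, collapse; the
alternative — averaging probes — blurs fold changes). A gene is called at
q < 0.05 and |log2FC| >= 1.

The funnel: DMCs whose annotation pairs a gene with a proximal-promoter
region class — TSS1500, TSS200, 5'UTR or 1st exon (configurable) — are
grouped by gene; the gene's methylation direction is the majority vote of
its promoter DMCs, and exact ties drop the gene with a warning (no
principled winner exists). Probe annotations with semicolon-delimited
multi-gene fields are paired position-wise with their region list, the
450K manifest convention. The methylation and expression gene sets are
intersected; candidates are the common genes whose expression direction
opposes their methylation direction. Candidates are ranked by
|mean promoter delta-M| x |expression log2FC| (ties by smaller best DMC
q, then symbol). This score is an explicit stand-in for the kind of
unpublished "largest combined difference" ranking used to pick small
validation panels; it is monotone in both evidence axes and has no other
justification.

## Binary-call association and diagnostics

MSP (methylation-specific PCR) gives a binary methylated/unmethylated
call per subject, gene and compartment (tumor tissue, adjacent tissue,
plasma). Frequencies are printed to 0.1% with half-up rounding, the
convention of clinical tables.

Contingency tests: Pearson chi-square without continuity correction
(on 2x2 tables this equals n(ad - bc)^2 / (row and column margin
product)), or the two-sided Fisher exact test (sum of hypergeometric
probabilities of all tables, fixed margins, no more probable than the
observed one). `choose_test` dispatches 2x2 tables to Fisher when any
expected count is below 5 — the textbook rule; the boundary value 5
itself uses chi-square — and always computes and logs both p-values.
Covariates with three or more levels use Pearson chi-square only
(Fisher–Freeman–Halton is out of scope). Family-wise correction is
Bonferroni: alpha / n_tests (0.05 / 3 ≈ 0.017 for a three-gene panel).

Diagnostics: for a binary marker the Mann–Whitney AUC with midrank tie
handling, AUC = P(case > control) + 0.5 P(tie) over all case–control
pairs, reduces exactly to (sensitivity + specificity) / 2; the
implementation computes the pair form and the tests assert the identity
to 1e-12. The 95% CI uses the Hanley–McNeil standard error
(Q1 = A/(2-A), Q2 = 2A^2/(1+A)), clipped to [0, 1]; other software may
print slightly different CIs (e.g. binomial-based), so the point AUC is
the comparable quantity. The panel rule scores a subject positive when
any gene in the marker set is methylated in plasma, so panel positives
equal the union of the per-gene positive sets.

## The synthetic-data generator

The generator's defaults are the study design the pipeline targets:

| parameter | default | meaning |
|---|---|---|
| n_tumor / n_adjacent / n_normal | 4 / 4 / 4 | array cohort |
| n_probes | 10,000 | desk-scale probe count |
| frac_hyper / frac_hypo | 0.025 / 0.025 | 250 + 250 planted probes |
| delta_m_effect | 2.5 | planted tumor shift, M-units |
| noise_sd | 0.5 | within-group M-value SD |
| adjacent_effect_frac | 0.2 | leak of the tumor effect into adjacent tissue |
| frac_promoter | 0.5 | promoter-annotated probes per gene block |
| probes_per_gene | 4 | manifest layout |
| inverse_link_prob | 0.8 | chance a planted gene also gets an expression effect |
| expr_log2fc, n_expr_pairs | 2.0, 17 | expression arm |
| n_cases / n_controls | 42 / 50 | MSP validation cohort |

Baseline per-probe M-values are drawn from a three-mode mixture
(unmethylated ≈ −3, hemimethylated ≈ 0, methylated ≈ +3; weights
0.4/0.2/0.4) to mimic the bimodal array landscape, which gives clustering
and heatmaps realistic structure. Planted probes shift the tumor mean by
±delta_m_effect; adjacent samples receive a 0.2 fraction of that shift,
emulating field cancerization in histologically normal surrounding
tissue. M-values are simulated directly on the M scale (Gaussian noise):
the analysis consumes M-values, and intensity-pair emission exists only
through `m_from_intensities` for exercising the transform. Within-group
noise SD is chosen for test power, not measured realism — small array
studies do not publish their per-probe variances.

Planted probes occupy contiguous gene blocks (promoter probes first), so
every planted gene has one methylation direction and at least one planted
promoter DMC; genes flagged inverse-consistent (probability
`inverse_link_prob`) receive an opposite-direction expression shift of
magnitude `expr_log2fc`. The expression array has one probe per gene plus
a few unmapped probes to exercise the filtering path.

The MSP cohort generator hits per-gene/per-compartment positivity rates
(defaulting to the validation study's printed frequencies) exactly when
`exact_marginals` is on: the round(rate x n) positives go to the subjects
with the highest values of a shared Beta(2, 2) latent propensity plus
per-gene noise (SD 0.25). The shared propensity correlates a subject's
calls across genes, so the any-positive panel union stays below the sum
of the marginals — the simplest mechanism with that property. Clinical
covariates are drawn from the marginal frequencies of a small surgical
cohort (male-predominant, mostly ≥60 years, mostly pT3); optional
covariate effects multiply a stratum's probability for call-positive
subjects, inducing associations of controlled direction.

What the simulator does **not** model: Infinium I/II probe-type chemistry
bias, batch effects, SNP-affected probes, beta-value boundary
compression, missing calls, or realistic linkage between tissue and
plasma positivity beyond the shared propensity. Passing tests therefore
demonstrate the statistical machinery under the assumed Gaussian M-value
model, not robustness to array artifacts.

## Problem sizes and determinism

Every generator takes an integer seed and is bit-reproducible;
identical seeds give byte-identical written tables. The test suite and
the reproduction script use fixtures of 10,000 probes, 2 x 17 expression
samples and 42/50-subject cohorts — sizes at which every statistical
property of interest (FDR control, planted-signal recovery, funnel
exactness, calibration of association p-values) is measurable in seconds
on one core. Power statements elsewhere in this note refer to these
sizes.

## Known limitations

- Real-study probe counts (hundreds of thousands) and the resulting
  genome-scale funnel numbers are out of desk scale; the pipeline prints
  the analogous funnel on any input but makes no claims about matching
  published genome-wide counts.
- The test-dispatch rule (expected < 5) approximates but cannot
  guarantee agreement with any particular published table's choice of
  chi-square vs Fisher.
- R x C tables with more than two levels use chi-square regardless of
  sparseness.
- The rank score for candidate genes is a documented stand-in, not a
  validated prioritization method.
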
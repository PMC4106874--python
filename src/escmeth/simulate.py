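"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure of a small 450K-style
tumor/adjacent/normal methylation study with a companion expression array
and an MSP (methylation-specific PCR) validation cohort:

* a probe x sample M-value matrix (4 tumor / 4 adjacent / 4 normal by
  default) with planted hyper- and hypomethylated probes,
* a gene x sample log2 expression matrix (17 tumor / 17 normal pairs by
  default) in which a configurable fraction of methylation-affected genes
  receive an inverse expression shift,
* subject x gene binary methylation call tables for tissue and plasma
  compartments of a case/control cohort (42 cases / 50 controls by
  default), with exact marginal positive counts on request,
* per-case clinical covariates, optionally associated with the calls.

All generators are deterministic given their seed; the ground truth of
what was planted is returned alongside the data so recovery can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MethylationDataset
from .exceptions import ConfigError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CohortConfig",
    "ExpressionDataset",
    "generate_methylation_dataset",
    "generate_expression_dataset",
    "generate_call_cohort",
    "generate_clinical_covariates",
    "STUDY_RATES",
    "CLINICAL_COVARIATES",
]

# baseline M-value mixture mimicking the bimodal 450K landscape:
# unmethylated probes near -3, hemimethylated near 0, methylated near +3
_BASELINE_MEANS = (-3.0, 0.0, 3.0)
_BASELINE_WEIGHTS = (0.4, 0.2, 0.4)
_BASELINE_JITTER_SD = 0.3

# CpG-island context sampling probabilities: planted hypermethylated probes
# are island/shore/shelf enriched, as promoter CGI gain is the dominant
# hypermethylation mode in carcinoma methylomes
_CTX_LABELS = ("island", "n_shore", "s_shore", "n_shelf", "s_shelf", "open_sea")
_CTX_P_HYPER = (0.45, 0.10, 0.10, 0.05, 0.05, 0.25)
_CTX_P_OTHER = (0.15, 0.06, 0.06, 0.03, 0.03, 0.67)

#: per-gene positivity rates of the MSP validation study: methylation-positive
#: fractions in tumor tissue, paired surrounding tissue, case plasma and
#: control plasma for the three panel genes
STUDY_RATES: dict[str, dict[str, float]] = {
    "EPB41L3": {
        "tumor_tissue": 25 / 42,
        "adjacent_tissue": 2 / 42,
        "case_plasma": 13 / 42,
        "control_plasma": 0.0,
    },
    "GPX3": {
        "tumor_tissue": 23 / 42,
        "adjacent_tissue": 4 / 42,
        "case_plasma": 17 / 42,
        "control_plasma": 0.0,
    },
    "COL14A1": {
        "tumor_tissue": 19 / 42,
        "adjacent_tissue": 5 / 42,
        "case_plasma": 13 / 42,
        "control_plasma": 0.0,
    },
}

COMPARTMENTS = ("tumor_tissue", "adjacent_tissue", "case_plasma", "control_plasma")

#: clinical covariates with the levels and marginal frequencies of a small
#: surgical ESCC cohort (male-predominant, mostly >= 60 y, mostly pT3, mostly
#: moderately differentiated)
CLINICAL_COVARIATES: dict[str, dict[str, float]] = {
    "gender": {"male": 27 / 42, "female": 15 / 42},
    "age_group": {"<60": 11 / 42, ">=60": 31 / 42},
    "family_history": {"yes": 17 / 42, "no": 25 / 42},
    "tumor_size": {"<5cm": 27 / 42, ">=5cm": 15 / 42},
    "differentiation": {"well": 6 / 42, "moderate": 29 / 42, "poor": 7 / 42},
    "pt": {"T1-2": 15 / 42, "T3": 27 / 42},
    "pn": {"N0-1": 34 / 42, "N2": 8 / 42},
    "smoking": {"smoker": 18 / 41, "nonsmoker": 23 / 41},
    "alcohol": {"drinker": 9 / 41, "nondrinker": 32 / 41},
}


@dataclass
class SimulationConfig:
    """Parameters of the methylation + expression simulation.

    Sample counts default to the 4/4/4 array design; ``delta_m_effect`` is
    the planted tumor-vs-reference mean shift in M-units (log2 scale) and
    ``noise_sd`` the within-group M-value standard deviation.
    ``adjacent_effect_frac`` leaks that fraction of the tumor effect into
    adjacent samples, emulating field cancerization in surrounding tissue.
    """

    n_tumor: int = 4
    n_adjacent: int = 4
    n_normal: int = 4
    n_probes: int = 10_000
    frac_hyper: float = 0.025
    frac_hypo: float = 0.025
    delta_m_effect: float = 2.5
    noise_sd: float = 0.5
    frac_promoter: float = 0.5
    inverse_link_prob: float = 0.8
    expr_log2fc: float = 2.0
    n_expr_pairs: int = 17
    probes_per_gene: int = 4
    adjacent_effect_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_adjacent", "n_normal", "n_probes",
                     "n_expr_pairs", "probes_per_gene"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("frac_hyper", "frac_hypo", "frac_promoter",
                     "inverse_link_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.frac_hyper + self.frac_hypo > 1.0:
            raise ConfigError("frac_hyper + frac_hypo must be <= 1")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if not 0.0 <= self.adjacent_effect_frac <= 1.0:
            raise ConfigError("adjacent_effect_frac outside [0, 1]")


@dataclass
class GroundTruth:
    """What the generator planted.

    ``probe_status`` maps probe_id -> hyper/hypo/null; ``gene_meth_direction``
    maps gene -> hyper/hypo/null (direction of its planted promoter DMCs);
    ``gene_expr_direction`` maps gene -> up/down/null; ``inverse_consistent``
    flags genes planted with a promoter methylation change and an opposite
    expression change.
    """

    probe_status: pd.Series
    gene_meth_direction: pd.Series
    gene_expr_direction: pd.Series
    inverse_consistent: pd.Series

    @property
    def planted_probes(self) -> pd.Index:
        return self.probe_status.index[self.probe_status != "null"]

    @property
    def planted_inverse_genes(self) -> list[str]:
        return sorted(self.inverse_consistent.index[self.inverse_consistent])


@dataclass
class ExpressionDataset:
    """Probe x sample log2 expression matrix with probe -> gene map."""

    values: pd.DataFrame
    probe_to_gene: pd.Series  # expression probe_id -> gene symbol (NaN = unmapped)
    groups: pd.Series  # sample_id -> "tumor" | "normal"

    def sample_ids(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def _plant_layout(config: SimulationConfig) -> tuple[np.ndarray, int, int]:
    """Probe status vector; hyper block first, hypo aligned to a gene start."""
    n_hyper = round(config.frac_hyper * config.n_probes)
    n_hypo = round(config.frac_hypo * config.n_probes)
    ppg = config.probes_per_gene
    hypo_start = math.ceil(n_hyper / ppg) * ppg
    if hypo_start + n_hypo > config.n_probes:
        raise ConfigError("too many planted probes for n_probes with this layout")
    status = np.array(["null"] * config.n_probes, dtype=object)
    status[:n_hyper] = "hyper"
    status[hypo_start:hypo_start + n_hypo] = "hypo"
    return status, n_hyper, n_hypo


def _make_manifest(config: SimulationConfig, status: np.ndarray,
                   rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_probes
    ppg = config.probes_per_gene
    probe_ids = [f"cg{i:08d}" for i in range(n)]
    gene_idx = np.arange(n) // ppg
    genes = np.array([f"GENE{g:05d}" for g in gene_idx])
    # first round(frac_promoter * ppg) probes of each gene block are promoter
    n_prom = round(config.frac_promoter * ppg)
    within = np.arange(n) % ppg
    prom_labels = ["TSS200", "TSS1500", "5UTR", "1stExon"]
    body_labels = ["Body", "3UTR"]
    regions = np.where(
        within < n_prom,
        [prom_labels[w % len(prom_labels)] for w in within],
        [body_labels[w % len(body_labels)] for w in within],
    )
    ctx = np.empty(n, dtype=object)
    hyper_mask = status == "hyper"
    ctx[hyper_mask] = rng.choice(_CTX_LABELS, size=int(hyper_mask.sum()),
                                 p=_CTX_P_HYPER)
    ctx[~hyper_mask] = rng.choice(_CTX_LABELS, size=int((~hyper_mask).sum()),
                                  p=_CTX_P_OTHER)
    chrom = (gene_idx % 22) + 1
    pos = (np.arange(n) % ppg) * 500 + (gene_idx * 100_000) % 200_000_000 + 1
    return pd.DataFrame(
        {
            "chromosome": [f"chr{c}" for c in chrom],
            "position": pos.astype(int),
            "gene": genes,
            "gene_region": regions,
            "cgi_context": ctx,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )


def generate_methylation_dataset(
    config: SimulationConfig,
) -> tuple[MethylationDataset, GroundTruth]:
    """Simulate the probe x sample M-value matrix and its ground truth.

    Null probes share a per-probe baseline drawn from a bimodal mixture
    (unmethylated / hemimethylated / methylated modes near -3 / 0 / +3) with
    Gaussian noise of ``noise_sd``.  Planted hyper (hypo) probes shift the
    tumor group mean by +/- ``delta_m_effect``; adjacent samples receive
    ``adjacent_effect_frac`` of that shift, normal samples none.
    """
    rng = np.random.default_rng(config.seed)
    status, _, _ = _plant_layout(config)
    manifest = _make_manifest(config, status, rng)
    probe_ids = manifest.index
    n = config.n_probes

    comp = rng.choice(len(_BASELINE_MEANS), size=n, p=_BASELINE_WEIGHTS)
    baseline = np.array(_BASELINE_MEANS)[comp] + rng.normal(
        0.0, _BASELINE_JITTER_SD, size=n
    )
    shift = np.where(status == "hyper", config.delta_m_effect,
                     np.where(status == "hypo", -config.delta_m_effect, 0.0))

    sample_ids, groups, means = [], [], []
    for i in range(config.n_tumor):
        sample_ids.append(f"T{i + 1}")
        groups.append("tumor")
        means.append(baseline + shift)
    for i in range(config.n_adjacent):
        sample_ids.append(f"S{i + 1}")
        groups.append("adjacent")
        means.append(baseline + config.adjacent_effect_frac * shift)
    for i in range(config.n_normal):
        sample_ids.append(f"N{i + 1}")
        groups.append("normal")
        means.append(baseline)
    mean_mat = np.column_stack(means)
    values = mean_mat + rng.normal(0.0, config.noise_sd, size=mean_mat.shape)
    values_df = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    samples = pd.DataFrame(
        {"group": groups, "patient_id": [s if g != "normal" else "" for s, g in
                                         zip(sample_ids, groups)]},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    dataset = MethylationDataset(values=values_df, manifest=manifest,
                                 samples=samples, scale="M")

    truth = _gene_truth(config, manifest, status, rng)
    return dataset, truth


def _gene_truth(config: SimulationConfig, manifest: pd.DataFrame,
                status: np.ndarray, rng: np.random.Generator) -> GroundTruth:
    probe_status = pd.Series(status, index=manifest.index, name="status")
    promoter = manifest["gene_region"].isin(["TSS1500", "TSS200", "5UTR", "1stExon"])
    planted_prom = probe_status[(probe_status != "null") & promoter]
    genes = sorted(manifest["gene"].unique())
    meth_dir = pd.Series("null", index=pd.Index(genes, name="gene"), dtype=object)
    for gene, grp in manifest.loc[planted_prom.index].groupby("gene"):
        dirs = probe_status[grp.index].unique()
        # layout guarantees one direction per gene; guard anyway
        meth_dir[gene] = dirs[0] if len(dirs) == 1 else "null"
    expr_dir = pd.Series("null", index=meth_dir.index, dtype=object)
    inverse = pd.Series(False, index=meth_dir.index)
    affected = meth_dir.index[meth_dir != "null"]
    linked = rng.random(len(affected)) < config.inverse_link_prob
    for gene, is_linked in zip(affected, linked):
        if is_linked:
            expr_dir[gene] = "down" if meth_dir[gene] == "hyper" else "up"
            inverse[gene] = True
    return GroundTruth(
        probe_status=probe_status,
        gene_meth_direction=meth_dir,
        gene_expr_direction=expr_dir,
        inverse_consistent=inverse,
    )


def generate_expression_dataset(
    truth: GroundTruth, config: SimulationConfig
) -> ExpressionDataset:
    """Simulate the companion gene-expression array (one probe per gene).

    Inverse-consistent genes receive a tumor-vs-normal log2 shift of
    magnitude ``expr_log2fc`` with sign opposite to the planted methylation
    direction; all other genes are null.  A handful of unmapped probes
    exercise the probe -> gene filtering path downstream.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = list(truth.gene_meth_direction.index)
    n_genes = len(genes)
    probe_ids = [f"ep{i:06d}" for i in range(n_genes)]
    baseline = rng.normal(8.0, 1.0, size=n_genes)
    shift = np.zeros(n_genes)
    for i, g in enumerate(genes):
        if truth.inverse_consistent[g]:
            shift[i] = config.expr_log2fc if truth.gene_expr_direction[g] == "up" \
                else -config.expr_log2fc
    n_pairs = config.n_expr_pairs
    tumor_ids = [f"ET{i + 1}" for i in range(n_pairs)]
    normal_ids = [f"EN{i + 1}" for i in range(n_pairs)]
    tumor = baseline[:, None] + shift[:, None] + rng.normal(
        0.0, config.noise_sd, size=(n_genes, n_pairs))
    normal = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(n_genes, n_pairs))
    values = pd.DataFrame(
        np.hstack([tumor, normal]),
        index=pd.Index(probe_ids, name="probe_id"),
        columns=tumor_ids + normal_ids,
    )
    # a few unmapped control probes
    n_unmapped = min(10, max(2, n_genes // 100))
    un_ids = [f"epx{i:04d}" for i in range(n_unmapped)]
    un_vals = rng.normal(8.0, 1.0, size=(n_unmapped, 1)) + rng.normal(
        0.0, config.noise_sd, size=(n_unmapped, 2 * n_pairs))
    values = pd.concat([
        values,
        pd.DataFrame(un_vals, index=pd.Index(un_ids, name="probe_id"),
                     columns=values.columns),
    ])
    mapping = pd.Series(
        genes + [np.nan] * n_unmapped, index=values.index, name="gene"
    )
    groups = pd.Series(
        ["tumor"] * n_pairs + ["normal"] * n_pairs,
        index=pd.Index(tumor_ids + normal_ids, name="sample_id"),
        name="group",
    )
    return ExpressionDataset(values=values, probe_to_gene=mapping, groups=groups)


@dataclass
class CohortConfig:
    """Parameters of the MSP case/control call-table simulation.

    ``rates`` maps gene -> compartment -> positivity fraction; defaults to
    the three-gene validation-study rates.  With ``exact_marginals`` the
    positive count per gene/compartment is exactly ``round(rate * n)``,
    assigned to the subjects with the highest latent propensity + noise so
    per-gene calls within a subject are positively correlated and panel
    unions stay below the sum of marginals.
    """

    n_cases: int = 42
    n_controls: int = 50
    rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(r) for g, r in STUDY_RATES.items()}
    )
    exact_marginals: bool = True
    propensity_beta: tuple[float, float] = (2.0, 2.0)
    call_noise_sd: float = 0.25
    covariate_effects: dict[str, dict[str, dict[str, float]]] | None = None
    effect_compartment: str = "tumor_tissue"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigError("n_cases and n_controls must be >= 1")
        for gene, comps in self.rates.items():
            for comp, rate in comps.items():
                if comp not in COMPARTMENTS:
                    raise ConfigError(
                        f"unknown compartment {comp!r} for gene {gene}"
                    )
                if not 0.0 <= rate <= 1.0:
                    raise ConfigError(
                        f"rate {rate} for {gene}/{comp} outside [0, 1]"
                    )
        if self.covariate_effects:
            for cov in self.covariate_effects:
                if cov not in CLINICAL_COVARIATES:
                    raise ConfigError(f"unknown covariate {cov!r} in effects")


def generate_call_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate the subject x gene x compartment binary call table.

    Returns a long-format DataFrame with columns ``subject_id``, ``cohort``
    (case/control), ``compartment`` (tumor_tissue / adjacent_tissue /
    plasma), ``gene`` and ``call``.  Case subjects carry all three
    compartments; controls carry plasma only.
    """
    rng = np.random.default_rng(config.seed)
    case_ids = [f"P{i + 1:03d}" for i in range(config.n_cases)]
    control_ids = [f"C{i + 1:03d}" for i in range(config.n_controls)]
    a, b = config.propensity_beta
    prop_case = rng.beta(a, b, size=config.n_cases)
    prop_ctrl = rng.beta(a, b, size=config.n_controls)

    rows = []
    for gene in sorted(config.rates):
        comps = config.rates[gene]
        for comp, rate in sorted(comps.items()):
            is_control = comp == "control_plasma"
            ids = control_ids if is_control else case_ids
            prop = prop_ctrl if is_control else prop_case
            n = len(ids)
            if config.exact_marginals:
                k = round(rate * n)
                score = prop + rng.normal(0.0, config.call_noise_sd, size=n)
                positive = np.zeros(n, dtype=int)
                if k > 0:
                    top = np.argsort(-score, kind="stable")[:k]
                    positive[top] = 1
            else:
                p = np.clip(rate * prop / max(prop.mean(), 1e-12), 0.0, 1.0)
                positive = (rng.random(n) < p).astype(int)
            compartment = "plasma" if comp in ("case_plasma", "control_plasma") \
                else comp
            cohort = "control" if is_control else "case"
            for sid, call in zip(ids, positive):
                rows.append((sid, cohort, compartment, gene, int(call)))
    calls = pd.DataFrame(
        rows, columns=["subject_id", "cohort", "compartment", "gene", "call"]
    )
    return calls.sort_values(
        ["cohort", "subject_id", "compartment", "gene"]
    ).reset_index(drop=True)


def generate_clinical_covariates(
    cohort: pd.DataFrame, config: CohortConfig
) -> pd.DataFrame:
    """Simulate per-case clinical covariates, optionally call-associated.

    Each case receives one level per covariate, drawn from the cohort's
    marginal frequencies.  ``config.covariate_effects`` (covariate ->
    level -> gene -> multiplier) tilts the level probabilities of subjects
    positive for the effect gene in ``config.effect_compartment``: the
    level's probability is multiplied and renormalized, which induces a
    call/covariate association of the corresponding direction.
    """
    rng = np.random.default_rng(config.seed + 7)
    cases = sorted(cohort.loc[cohort["cohort"] == "case", "subject_id"].unique())
    effects = config.covariate_effects or {}
    call_lookup: dict[str, dict[str, int]] = {}
    for gene in config.rates:
        sub = cohort[
            (cohort["gene"] == gene)
            & (cohort["compartment"] == _effect_compartment_name(config))
            & (cohort["cohort"] == "case")
        ]
        call_lookup[gene] = dict(zip(sub["subject_id"], sub["call"]))
    out: dict[str, list[str]] = {cov: [] for cov in CLINICAL_COVARIATES}
    for sid in cases:
        for cov, levels in CLINICAL_COVARIATES.items():
            names = list(levels)
            probs = np.array([levels[lv] for lv in names], dtype=float)
            if cov in effects:
                for lv, gene_mults in effects[cov].items():
                    if lv not in levels:
                        raise ConfigError(f"unknown level {lv!r} of covariate {cov!r}")
                    mult = 1.0
                    for gene, m in gene_mults.items():
                        if gene not in config.rates:
                            raise ConfigError(f"unknown gene {gene!r} in effects")
                        if call_lookup[gene].get(sid, 0) == 1:
                            mult *= m
                    probs[names.index(lv)] *= mult
            probs = probs / probs.sum()
            out[cov].append(str(rng.choice(names, p=probs)))
    return pd.DataFrame(out, index=pd.Index(cases, name="subject_id"))


def _effect_compartment_name(config: CohortConfig) -> str:
    comp = config.effect_compartment
    return "plasma" if comp in ("case_plasma", "control_plasma") else comp
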
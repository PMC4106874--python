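"""End-to-end pipeline: simulate -> normalize -> cluster -> DMC ->
integrate -> associate -> diagnose, with a provenance manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .biomarkers import clinico_association_report, diagnostics_from_calls
from .core import hierarchical_cluster, quantile_normalize, sample_distribution_summary
from .dmc import dmc_pipeline, summarize_context
from .exceptions import ConfigError
from .integration import integration_pipeline
from .io import (
    write_calls_csv,
    write_clinical_csv,
    write_expression,
    write_ground_truth,
    write_json,
    write_manifest_csv,
    write_methylation_tsv,
    write_sample_sheet_csv,
)
from .simulate import (
    CohortConfig,
    SimulationConfig,
    generate_call_cohort,
    generate_clinical_covariates,
    generate_expression_dataset,
    generate_methylation_dataset,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "simulate_all"]


@dataclass
class PipelineConfig:
    """Thresholds and options of the full analysis run.

    Defaults mirror the analysis design: FDR alpha 0.05, effect threshold
    1.0 M-units (a two-fold intensity-ratio change), expression fold-change
    2, any-positive panel of the top 3 candidates.
    """

    outdir: str = "escmeth_out"
    alpha: float = 0.05
    delta_m_threshold: float = 1.0
    fc_threshold: float = 2.0
    dmc_mode: str = "delta"
    cluster_k: int = 2
    cluster_metric: str = "correlation"
    cluster_method: str = "average"
    top_k: int = 3
    seed: int = 0
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.delta_m_threshold <= 0 or self.fc_threshold <= 0:
            raise ConfigError("thresholds must be positive")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_all(outdir, sim_config: SimulationConfig,
                 cohort_config: CohortConfig) -> dict[str, Path]:
    """Generate every synthetic input table into ``outdir``; returns paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, truth = generate_methylation_dataset(sim_config)
    expr = generate_expression_dataset(truth, sim_config)
    calls = generate_call_cohort(cohort_config)
    clinical = generate_clinical_covariates(calls, cohort_config)
    paths = {
        "methylation": out / "methylation.tsv",
        "manifest": out / "manifest.csv",
        "samples": out / "samples.csv",
        "expression": out / "expression.tsv",
        "expression_map": out / "expression_map.csv",
        "expression_samples": out / "expression_samples.csv",
        "calls": out / "calls.csv",
        "clinical": out / "clinical.csv",
        "truth_probes": out / "truth_probes.tsv",
        "truth_genes": out / "truth_genes.tsv",
    }
    write_methylation_tsv(dataset, paths["methylation"])
    write_manifest_csv(dataset.manifest, paths["manifest"])
    write_sample_sheet_csv(dataset.samples, paths["samples"])
    write_expression(expr, paths["expression"], paths["expression_map"],
                     paths["expression_samples"])
    write_calls_csv(calls, paths["calls"])
    write_clinical_csv(clinical, paths["clinical"])
    write_ground_truth(truth, paths["truth_probes"], paths["truth_genes"])
    return paths


def run_pipeline(
    config: PipelineConfig,
    dataset,
    expr,
    calls: pd.DataFrame,
    clinical: pd.DataFrame,
    panel_genes: list[str] | None = None,
    input_paths: dict | None = None,
) -> dict:
    """Execute every analysis stage and write the artifact tables.

    Stages: optional quantile normalization, sample distribution summary,
    sample clustering, tumor-vs-reference DMC calling with context summary,
    the expression-integration funnel, clinicopathological association,
    and plasma diagnostics for the panel genes (default: top-ranked
    candidates that exist in the call table, else all call-table genes).
    Returns a dict with the in-memory results; tables land in
    ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage_times: dict[str, float] = {}

    def tick(stage: str) -> None:
        stage_times[stage] = round(time.time() - t0, 3)
        logger.info("stage %s done at %.2fs", stage, stage_times[stage])

    dataset = dataset.to_m()
    if config.normalize:
        dataset = quantile_normalize(dataset)
    summary = sample_distribution_summary(dataset)
    summary.to_csv(out / "sample_summary.tsv", sep="\t",
                   index_label="sample_id")
    tick("normalize")

    clusters = hierarchical_cluster(
        dataset, axis="samples", k=config.cluster_k,
        metric=config.cluster_metric, method=config.cluster_method,
    )
    pd.DataFrame(
        {"cluster": clusters.labels,
         "group": dataset.samples.loc[clusters.labels.index, "group"]}
    ).to_csv(out / "sample_clusters.tsv", sep="\t", index_label="sample_id")
    tick("cluster")

    dmcs = dmc_pipeline(
        dataset, alpha=config.alpha,
        delta_m_threshold=config.delta_m_threshold, mode=config.dmc_mode,
    )
    dmc_table = dataset.manifest.join(dmcs, how="right")
    dmc_table.to_csv(out / "dmc_table.tsv", sep="\t", index_label="probe_id",
                     float_format="%.6g")
    context = summarize_context(dmcs, dataset.manifest)
    write_json(
        {
            "cgi_associated_fraction": context.cgi_associated_fraction,
            "counts": {d: c.to_dict() for d, c in context.counts.items()},
        },
        out / "context_summary.json",
    )
    tick("dmc")

    candidates, top, funnel = integration_pipeline(
        dmcs, dataset.manifest, expr,
        alpha=config.alpha, fc_threshold=config.fc_threshold,
        top_k=config.top_k,
    )
    candidates.to_csv(out / "candidates.tsv", sep="\t", index_label="gene",
                      float_format="%.6g")
    write_json(funnel.to_dict(), out / "funnel.json")
    tick("integrate")

    call_genes = sorted(calls["gene"].unique())
    if panel_genes is None:
        panel_genes = [g for g in top.index if g in call_genes] or call_genes
    assoc = clinico_association_report(
        calls, clinical, call_genes, compartment="tumor_tissue",
        alpha=config.alpha,
    )
    assoc.to_csv(out / "associations.tsv", sep="\t", index=False,
                 float_format="%.6g")
    tick("associate")

    diagnostics = diagnostics_from_calls(calls, panel_genes, "plasma")
    write_json({k: v.to_dict() for k, v in diagnostics.items()},
               out / "diagnostics.json")
    tick("diagnose")

    manifest = {
        "escmeth_version": __version__,
        "parameters": asdict(config),
        "panel_genes": panel_genes,
        "stage_seconds": stage_times,
        "input_checksums": {
            str(k): _sha256(Path(v)) for k, v in (input_paths or {}).items()
            if Path(v).is_file()
        },
    }
    write_json(manifest, out / "run_manifest.json")
    return {
        "summary": summary,
        "clusters": clusters,
        "dmcs": dmcs,
        "context": context,
        "candidates": candidates,
        "top_candidates": top,
        "funnel": funnel,
        "associations": assoc,
        "diagnostics": diagnostics,
    }
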
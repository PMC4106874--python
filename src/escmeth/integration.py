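"""Methylation x expression integration: the candidate-gene funnel.

Promoter DMCs are collapsed to genes; differentially expressed genes are
called from the companion expression array; the two gene sets are
intersected and only genes whose expression change opposes their
methylation change (hypermethylated + down-regulated, or hypomethylated +
up-regulated) survive.  Survivors are ranked by the product of the absolute
mean promoter delta-M and the absolute expression log2 fold change — an
explicit stand-in for an unpublished "most significant difference" score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dmc import bh_fdr
from .exceptions import DataValidationError
from .simulate import ExpressionDataset

__all__ = [
    "PROMOTER_REGIONS",
    "FunnelReport",
    "call_de_genes",
    "map_promoter_dmcs_to_genes",
    "intersect_inverse",
    "rank_candidates",
    "integration_pipeline",
]

logger = logging.getLogger(__name__)

#: gene-region annotation classes counted as proximal promoter
PROMOTER_REGIONS = ("TSS1500", "TSS200", "5UTR", "1stExon")


@dataclass
class FunnelReport:
    """Stage counts of the integration funnel."""

    n_dmcs: int
    n_promoter_dmcs: int
    n_meth_genes: int
    n_expr_probes: int
    n_expr_genes: int
    n_common: int
    n_inverse: int

    def validate(self) -> None:
        ok = (
            self.n_inverse <= self.n_common
            <= min(self.n_meth_genes, self.n_expr_genes)
            and self.n_promoter_dmcs <= self.n_dmcs
        )
        if not ok:
            raise DataValidationError(f"inconsistent funnel counts: {asdict(self)}")

    def to_dict(self) -> dict[str, int]:
        return asdict(self)


def call_de_genes(
    expr: ExpressionDataset,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-gene differential expression between tumor and normal samples.

    Probe-level Welch t-tests on log2 values with BH-FDR adjustment; probes
    are then collapsed to genes keeping the probe with the highest mean
    intensity.  A gene is differentially expressed when ``q < alpha`` and
    ``|log2FC| >= log2(fc_threshold)`` with log2FC = tumor - normal.
    Unmapped probes are dropped (count logged).

    Returns a DataFrame indexed by gene with columns ``probe_id``,
    ``log2fc``, ``t``, ``p``, ``q``, ``de`` and ``direction`` (up/down/ns);
    the number of probes tested is stored in ``.attrs["n_expr_probes"]``.
    """
    tumor = expr.sample_ids("tumor")
    normal = expr.sample_ids("normal")
    if len(tumor) < 2 or len(normal) < 2:
        raise DataValidationError("each expression group needs >= 2 samples")
    mapped = expr.probe_to_gene.dropna()
    n_dropped = len(expr.values) - len(mapped)
    if n_dropped:
        logger.info("dropped %d unmapped expression probes", n_dropped)
    values = expr.values.loc[mapped.index]
    a = values[tumor].to_numpy(dtype=float)
    b = values[normal].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.nan_to_num(p, nan=1.0)
    probe_res = pd.DataFrame(
        {
            "gene": mapped.to_numpy(),
            "log2fc": a.mean(axis=1) - b.mean(axis=1),
            "mean_intensity": values.to_numpy(dtype=float).mean(axis=1),
            "t": t,
            "p": p,
        },
        index=values.index,
    )
    probe_res["q"] = bh_fdr(probe_res["p"].to_numpy())
    # collapse to gene: keep the brightest probe
    best = probe_res.sort_values(
        ["gene", "mean_intensity"], ascending=[True, False]
    ).groupby("gene", sort=True).head(1)
    out = best.set_index("gene").drop(columns=["mean_intensity"])
    out.index.name = "gene"
    out = out.rename_axis("gene")
    out.insert(0, "probe_id", best.index.to_numpy())
    out["de"] = (out["q"] < alpha) & (
        out["log2fc"].abs() >= np.log2(fc_threshold)
    )
    out["direction"] = np.where(
        ~out["de"], "ns", np.where(out["log2fc"] > 0, "up", "down")
    )
    out.attrs["n_expr_probes"] = int(len(probe_res))
    return out


def _split_pairwise(gene_field: str, region_field: str) -> list[tuple[str, str]]:
    """Pair semicolon-delimited gene and region lists position-wise."""
    genes = str(gene_field).split(";")
    regions = str(region_field).split(";")
    if len(genes) == len(regions):
        return list(zip(genes, regions))
    if len(regions) == 1:
        return [(g, regions[0]) for g in genes]
    raise DataValidationError(
        f"gene/gene_region list length mismatch: {gene_field!r} vs {region_field!r}"
    )


def map_promoter_dmcs_to_genes(
    dmcs: pd.DataFrame,
    manifest: pd.DataFrame,
    promoter_regions: tuple[str, ...] = PROMOTER_REGIONS,
) -> pd.DataFrame:
    """Collapse promoter DMCs to per-gene methylation-direction records.

    Keeps DMCs (status hyper/hypo) whose annotation pairs the gene with a
    promoter region class; a probe annotated to several genes contributes to
    each gene whose paired region is promoter.  Per gene the direction is
    the majority direction of its promoter DMCs; genes with a tie are
    dropped with a warning.

    Returns a DataFrame indexed by gene with ``meth_direction``,
    ``n_promoter_dmcs``, ``best_dmc_q``, ``mean_delta_m``; total DMC and
    promoter-DMC counts are stored in ``.attrs``.
    """
    called = dmcs[dmcs["status"].isin(["hyper", "hypo"])]
    missing = called.index.difference(manifest.index)
    if len(missing):
        raise DataValidationError(
            f"DMC probes missing from manifest: {list(missing[:5])}"
        )
    records = []
    promoter_probes = set()
    for probe_id, row in called.iterrows():
        ann = manifest.loc[probe_id]
        for gene, region in _split_pairwise(ann["gene"], ann["gene_region"]):
            if region in promoter_regions and gene:
                records.append(
                    (gene, row["status"], row["q"], row["delta_m"])
                )
                promoter_probes.add(probe_id)
    result_rows = []
    if records:
        rec = pd.DataFrame(
            records, columns=["gene", "status", "q", "delta_m"]
        )
        for gene, grp in rec.groupby("gene", sort=True):
            n_hyper = int((grp["status"] == "hyper").sum())
            n_hypo = int((grp["status"] == "hypo").sum())
            if n_hyper == n_hypo:
                warnings.warn(
                    f"gene {gene} dropped: tie between {n_hyper} hyper and "
                    f"{n_hypo} hypo promoter DMCs",
                    stacklevel=2,
                )
                continue
            direction = "hyper" if n_hyper > n_hypo else "hypo"
            result_rows.append(
                {
                    "gene": gene,
                    "meth_direction": direction,
                    "n_promoter_dmcs": n_hyper + n_hypo,
                    "best_dmc_q": float(grp["q"].min()),
                    "mean_delta_m": float(grp["delta_m"].mean()),
                }
            )
    out = pd.DataFrame(
        result_rows,
        columns=["gene", "meth_direction", "n_promoter_dmcs", "best_dmc_q",
                 "mean_delta_m"],
    ).set_index("gene")
    out.attrs["n_dmcs"] = int(len(called))
    out.attrs["n_promoter_dmcs"] = int(len(promoter_probes))
    return out


def intersect_inverse(
    meth_genes: pd.DataFrame, de_genes: pd.DataFrame
) -> tuple[pd.DataFrame, FunnelReport]:
    """Intersect the two gene sets and keep inverse-direction candidates.

    A candidate is inverse-consistent when (hyper, down) or (hypo, up).
    Returns the candidate table (gene-indexed, with methylation and
    expression evidence plus ``rank_score``) and the funnel stage counts.
    """
    de_called = de_genes[de_genes["direction"].isin(["up", "down"])]
    common = meth_genes.index.intersection(de_called.index)
    merged = meth_genes.loc[common].join(
        de_called.loc[common, ["log2fc", "q", "direction"]].rename(
            columns={"q": "expr_q", "direction": "expr_direction"}
        )
    )
    inv = (
        ((merged["meth_direction"] == "hyper") & (merged["expr_direction"] == "down"))
        | ((merged["meth_direction"] == "hypo") & (merged["expr_direction"] == "up"))
    )
    merged["inverse_consistent"] = inv
    candidates = merged[inv].copy()
    candidates["rank_score"] = (
        candidates["mean_delta_m"].abs() * candidates["log2fc"].abs()
    )
    report = FunnelReport(
        n_dmcs=int(meth_genes.attrs.get("n_dmcs", 0)),
        n_promoter_dmcs=int(meth_genes.attrs.get("n_promoter_dmcs", 0)),
        n_meth_genes=int(len(meth_genes)),
        n_expr_probes=int(de_genes.attrs.get("n_expr_probes", len(de_genes))),
        n_expr_genes=int(len(de_called)),
        n_common=int(len(common)),
        n_inverse=int(inv.sum()),
    )
    report.validate()
    return candidates, report


def rank_candidates(candidates: pd.DataFrame, top_k: int) -> pd.DataFrame:
    """Order candidates by rank_score (|mean promoter delta-M| x |log2FC|).

    Descending score; ties broken by smaller best_dmc_q, then gene symbol.
    Asking for more than available returns the full ranked list with a
    warning.
    """
    if candidates.empty:
        raise DataValidationError("no candidates to rank")
    if top_k > len(candidates):
        warnings.warn(
            f"top_k={top_k} exceeds {len(candidates)} candidates; returning all",
            stacklevel=2,
        )
        top_k = len(candidates)
    ordered = candidates.reset_index().sort_values(
        ["rank_score", "best_dmc_q", "gene"], ascending=[False, True, True]
    ).set_index("gene")
    return ordered.head(top_k)


def integration_pipeline(
    dmcs: pd.DataFrame,
    manifest: pd.DataFrame,
    expr: ExpressionDataset,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
    top_k: int = 3,
    promoter_regions: tuple[str, ...] = PROMOTER_REGIONS,
) -> tuple[pd.DataFrame, pd.DataFrame, FunnelReport]:
    """Run the full funnel; returns (candidates, top-ranked, report)."""
    meth_genes = map_promoter_dmcs_to_genes(dmcs, manifest, promoter_regions)
    de_genes = call_de_genes(expr, alpha=alpha, fc_threshold=fc_threshold)
    candidates, report = intersect_inverse(meth_genes, de_genes)
    top = rank_candidates(candidates, top_k) if len(candidates) else candidates
    return candidates, top, report
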
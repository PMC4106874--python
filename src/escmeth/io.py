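"""Plain-text table formats used by the pipeline.

Canonical interchange is TSV for value matrices and CSV for annotation and
call tables; no binary formats.  All readers validate on load and raise
:class:`~escmeth.exceptions.DataValidationError` with offending identifiers.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MethylationDataset
from .exceptions import DataValidationError
from .simulate import ExpressionDataset, GroundTruth

logger = logging.getLogger(__name__)

__all__ = [
    "read_methylation_tsv",
    "write_methylation_tsv",
    "read_manifest_csv",
    "write_manifest_csv",
    "read_sample_sheet_csv",
    "write_sample_sheet_csv",
    "read_expression",
    "write_expression",
    "read_calls_csv",
    "write_calls_csv",
    "read_clinical_csv",
    "write_clinical_csv",
    "write_ground_truth",
    "read_ground_truth",
    "write_json",
]

_FLOAT_FMT = "%.10g"


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "probe_id":
        raise DataValidationError(
            f"{path}: first column must be 'probe_id', got {df.columns[0]!r}"
        )
    df = df.set_index("probe_id")
    dups = df.index[df.index.duplicated()].unique()
    if len(dups):
        raise DataValidationError(f"{path}: duplicate probe_id {list(dups[:5])}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise DataValidationError(f"{path}: non-numeric cell ({exc})") from exc
    return df


def read_methylation_tsv(
    path,
    manifest_path,
    samples_path,
    scale: str | None = None,
) -> MethylationDataset:
    """Load a methylation matrix with its manifest and sample sheet.

    The value scale is auto-detected (all values in [0, 1] -> beta, else M)
    unless forced via ``scale``.
    """
    values = _read_matrix(path)
    manifest = read_manifest_csv(manifest_path)
    samples = read_sample_sheet_csv(samples_path)
    missing = values.columns.difference(samples.index)
    if len(missing):
        raise DataValidationError(
            f"{path}: samples missing from sheet: {list(missing)}"
        )
    if scale is None:
        arr = values.to_numpy()
        scale = "beta" if (np.nanmin(arr) >= 0 and np.nanmax(arr) <= 1) else "M"
    logger.info("read %d probes x %d samples (%s scale) from %s",
                *values.shape, scale, path)
    return MethylationDataset(values=values, manifest=manifest,
                              samples=samples, scale=scale)


def write_methylation_tsv(dataset: MethylationDataset, path) -> None:
    dataset.values.to_csv(path, sep="\t", float_format=_FLOAT_FMT,
                          index_label="probe_id")


def read_manifest_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    required = {"probe_id", "chromosome", "position", "gene", "gene_region",
                "cgi_context"}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"{path}: manifest missing {sorted(missing)}")
    df = df.set_index("probe_id")
    df["position"] = df["position"].astype(int)
    df[["gene", "gene_region", "cgi_context"]] = (
        df[["gene", "gene_region", "cgi_context"]].fillna("")
    )
    return df


def write_manifest_csv(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index_label="probe_id")


def read_sample_sheet_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise DataValidationError(f"{path}: need sample_id and group columns")
    df = df.set_index("sample_id")
    if df.index.duplicated().any():
        raise DataValidationError(f"{path}: duplicate sample_id")
    if "patient_id" not in df.columns:
        df["patient_id"] = ""
    df["patient_id"] = df["patient_id"].fillna("")
    return df


def write_sample_sheet_csv(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index_label="sample_id")


def read_expression(matrix_path, map_path, samples_path) -> ExpressionDataset:
    """Load a log2 expression matrix, probe->gene map and sample groups."""
    values = _read_matrix(matrix_path)
    mapping = pd.read_csv(map_path, dtype=str)
    if "probe_id" not in mapping.columns or "gene" not in mapping.columns:
        raise DataValidationError(f"{map_path}: need probe_id and gene columns")
    mapping = mapping.set_index("probe_id")["gene"]
    mapping = mapping.reindex(values.index)
    sheet = pd.read_csv(samples_path, dtype=str)
    if "sample_id" not in sheet.columns or "group" not in sheet.columns:
        raise DataValidationError(f"{samples_path}: need sample_id and group")
    groups = sheet.set_index("sample_id")["group"]
    bad = set(groups) - {"tumor", "normal"}
    if bad:
        raise DataValidationError(
            f"{samples_path}: expression groups must be tumor/normal, got {bad}"
        )
    missing = values.columns.difference(groups.index)
    if len(missing):
        raise DataValidationError(
            f"{matrix_path}: samples missing from sheet: {list(missing)}"
        )
    return ExpressionDataset(values=values, probe_to_gene=mapping,
                             groups=groups.loc[values.columns])


def write_expression(expr: ExpressionDataset, matrix_path, map_path,
                     samples_path) -> None:
    expr.values.to_csv(matrix_path, sep="\t", float_format=_FLOAT_FMT,
                       index_label="probe_id")
    expr.probe_to_gene.rename("gene").to_csv(map_path, index_label="probe_id")
    expr.groups.rename("group").to_csv(samples_path, index_label="sample_id")


def read_calls_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "cohort": str,
                                  "compartment": str, "gene": str})
    required = {"subject_id", "cohort", "compartment", "gene", "call"}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"{path}: call table missing {sorted(missing)}")
    df["call"] = df["call"].astype(int)
    return df


def write_calls_csv(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, index=False)


def read_clinical_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    if "subject_id" not in df.columns:
        raise DataValidationError(f"{path}: need subject_id column")
    return df.set_index("subject_id")


def write_clinical_csv(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index_label="subject_id")


def write_ground_truth(truth: GroundTruth, probe_path, gene_path) -> None:
    truth.probe_status.rename("status").to_csv(
        probe_path, sep="\t", index_label="probe_id"
    )
    genes = pd.DataFrame(
        {
            "direction": truth.gene_expr_direction,
            "inverse": truth.inverse_consistent.astype(int),
            "meth_direction": truth.gene_meth_direction,
        }
    )
    genes.to_csv(gene_path, sep="\t", index_label="gene")


def read_ground_truth(probe_path, gene_path) -> GroundTruth:
    # keep_default_na=False: the literal status "null" must survive the trip
    probes = pd.read_csv(probe_path, sep="\t", dtype=str,
                         keep_default_na=False).set_index("probe_id")
    genes = pd.read_csv(gene_path, sep="\t", dtype=str,
                        keep_default_na=False).set_index("gene")
    return GroundTruth(
        probe_status=probes["status"],
        gene_meth_direction=genes["meth_direction"],
        gene_expr_direction=genes["direction"],
        inverse_consistent=genes["inverse"].astype(int).astype(bool),
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
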
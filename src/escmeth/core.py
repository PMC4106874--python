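"""Methylation value transforms, normalization and unsupervised structure.

The Infinium 450K array reports, per CpG probe, a methylated and an
unmethylated fluorescence intensity.  Two derived scales are in common use:

* beta value  ``beta = M_int / (M_int + U_int + offset)`` in [0, 1] —
  interpretable as the fraction of methylated alleles;
* M-value  ``M = log2(M_int / U_int)`` — approximately homoscedastic across
  the methylation range and therefore preferred for differential testing.

This module provides the intensity -> M transform, the beta <-> M
conversion, cross-sample quantile normalization, per-sample distribution
summaries (the numbers behind a normalization boxplot), and agglomerative
hierarchical clustering of samples or probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .exceptions import DataValidationError

__all__ = [
    "MethylationDataset",
    "ClusterResult",
    "m_from_intensities",
    "beta_to_m",
    "m_to_beta",
    "quantile_normalize",
    "sample_distribution_summary",
    "hierarchical_cluster",
]

BETA_EPS = 1e-6

GENE_REGIONS = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")
CGI_CONTEXTS = ("island", "n_shore", "s_shore", "n_shelf", "s_shelf", "open_sea")
SAMPLE_GROUPS = ("tumor", "adjacent", "normal")


@dataclass
class MethylationDataset:
    """Probe x sample methylation matrix with its annotations.

    Parameters
    ----------
    values
        DataFrame, rows indexed by probe_id, columns by sample_id.
    manifest
        Per-probe annotation indexed by probe_id with columns
        ``chromosome``, ``position`` (1-based), ``gene`` (semicolon list),
        ``gene_region`` (semicolon list, paired with ``gene``) and
        ``cgi_context``.
    samples
        Per-sample sheet indexed by sample_id with columns ``group``
        (tumor / adjacent / normal) and optional ``patient_id``.
    scale
        ``"M"`` (log2 ratio) or ``"beta"`` (fraction in [0, 1]).
    """

    values: pd.DataFrame
    manifest: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "M"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise DataValidationError(f"duplicate probe_ids: {list(dups[:5])}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise DataValidationError(f"duplicate sample_ids: {list(dups[:5])}")
        missing = self.values.index.difference(self.manifest.index)
        if len(missing):
            raise DataValidationError(
                f"{len(missing)} probes missing from manifest, e.g. {list(missing[:5])}"
            )
        missing_s = self.values.columns.difference(self.samples.index)
        if len(missing_s):
            raise DataValidationError(
                f"samples missing from sample sheet: {list(missing_s)}"
            )
        bad_groups = set(self.samples["group"]) - set(SAMPLE_GROUPS)
        if bad_groups:
            raise DataValidationError(f"unknown sample groups: {sorted(bad_groups)}")
        if self.scale not in ("M", "beta"):
            raise DataValidationError(f"unknown scale {self.scale!r}")
        if self.scale == "beta":
            vals = self.values.to_numpy()
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                raise DataValidationError("beta-scale values outside [0, 1]")

    @property
    def groups(self) -> pd.Series:
        """Sample group membership aligned to the value columns."""
        return self.samples.loc[self.values.columns, "group"]

    def sample_ids(self, group: str) -> list[str]:
        g = self.groups
        return list(g.index[g == group])

    def to_m(self) -> "MethylationDataset":
        """Return an M-scale copy (no-op if already on the M scale)."""
        if self.scale == "M":
            return self
        return MethylationDataset(
            values=beta_to_m(self.values),
            manifest=self.manifest,
            samples=self.samples,
            scale="M",
        )


@dataclass
class ClusterResult:
    """Agglomerative clustering output for one axis of the dataset."""

    linkage_matrix: np.ndarray
    item_ids: list[str]
    leaf_order: list[str]
    labels: pd.Series  # item_id -> cluster label in 1..k
    axis: str = "samples"
    k: int = 2

    def cluster_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for item, lab in self.labels.items():
            out.setdefault(int(lab), []).append(item)
        return out


def m_from_intensities(meth_intensity, unmeth_intensity, offset: float = 1.0):
    """M-value from a methylated/unmethylated intensity pair.

    ``M = log2((meth + offset) / (unmeth + offset))``.  The offset (default 1)
    keeps the ratio finite for dark probes.  Accepts scalars or arrays.
    """
    meth = np.asarray(meth_intensity, dtype=float)
    unmeth = np.asarray(unmeth_intensity, dtype=float)
    if np.any(meth < 0) or np.any(unmeth < 0):
        raise DataValidationError("intensities must be non-negative")
    if offset < 0:
        raise DataValidationError("offset must be non-negative")
    num = meth + offset
    den = unmeth + offset
    if np.any(num == 0) or np.any(den == 0):
        raise DataValidationError(
            "both intensity and offset are zero; M-value undefined"
        )
    out = np.log2(num / den)
    return out.item() if np.isscalar(meth_intensity) else out


def beta_to_m(beta):
    """Logit2 transform ``M = log2(beta / (1 - beta))``.

    Beta values at exactly 0 or 1 are clipped to ``[1e-6, 1 - 1e-6]`` with a
    warning, so the transform stays finite.
    """
    arr = np.asarray(beta, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise DataValidationError("beta values must lie in [0, 1]")
    if np.any(arr <= 0) or np.any(arr >= 1):
        warnings.warn(
            "beta values at 0 or 1 clipped to [1e-6, 1 - 1e-6] before logit",
            stacklevel=2,
        )
        arr = np.clip(arr, BETA_EPS, 1 - BETA_EPS)
    out = np.log2(arr / (1 - arr))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(out, index=beta.index)
    return out.item() if np.isscalar(beta) else out


def m_to_beta(m):
    """Inverse logit2: ``beta = 2**M / (1 + 2**M)``."""
    arr = np.asarray(m, dtype=float)
    # expit formulation avoids overflow for large |M|
    out = 1.0 / (1.0 + np.power(2.0, -arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(out, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(out, index=m.index)
    return out.item() if np.isscalar(m) else out


def _quantile_normalize_frame(values: pd.DataFrame) -> pd.DataFrame:
    arr = values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise DataValidationError("missing values are not supported; filter first")
    # reference distribution: mean of per-sample sorted vectors
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty(n)
        mapped[order] = ref
        # ties take the mean reference value over their rank span
        mapped = pd.Series(mapped).groupby(col, sort=False).transform("mean").to_numpy()
        out[:, j] = mapped
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_normalize(dataset: MethylationDataset) -> MethylationDataset:
    """Force every sample onto the common rank-mean reference distribution.

    After normalization every sample's sorted value vector equals the mean of
    the per-sample sorted vectors; within-sample ranks are preserved and tied
    values receive the mean of the reference values over the tied span.
    A single-sample dataset is returned unchanged with a warning.
    """
    if dataset.values.shape[1] < 2:
        warnings.warn("quantile normalization needs >= 2 samples; no-op", stacklevel=2)
        return dataset
    return MethylationDataset(
        values=_quantile_normalize_frame(dataset.values),
        manifest=dataset.manifest,
        samples=dataset.samples,
        scale=dataset.scale,
    )


def sample_distribution_summary(dataset: MethylationDataset) -> pd.DataFrame:
    """Five-number summary per sample (min, Q1, median, Q3, max).

    Quartiles use linear interpolation, the convention drawn by standard
    boxplots of array signal distributions.
    """
    if dataset.values.size == 0:
        raise DataValidationError("empty dataset")
    arr = dataset.values.to_numpy(dtype=float)
    qs = np.percentile(arr, [0, 25, 50, 75, 100], axis=0)
    return pd.DataFrame(
        qs.T,
        index=dataset.values.columns,
        columns=["min", "q1", "median", "q3", "max"],
    )


def _correlation_distance(profiles: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson distance; zero-variance items correlate as 0."""
    sd = profiles.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance items; their correlations "
            "are defined as 0",
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(profiles)
    corr = np.atleast_2d(corr)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, None)


def hierarchical_cluster(
    dataset: MethylationDataset,
    axis: str = "samples",
    k: int = 2,
    metric: str = "correlation",
    method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of samples or probes.

    Default distance is 1 - Pearson correlation between item profiles with
    average linkage, the usual choice for array heatmaps.  ``metric`` may be
    ``"euclidean"`` and ``method`` any of ``average | complete | ward``
    (ward requires euclidean).  Deterministic for a fixed input ordering.
    """
    if axis not in ("samples", "probes"):
        raise DataValidationError(f"axis must be samples or probes, got {axis!r}")
    if method == "ward" and metric != "euclidean":
        raise DataValidationError("ward linkage requires the euclidean metric")
    mat = dataset.values.to_numpy(dtype=float)
    if axis == "samples":
        profiles = mat.T
        ids = list(dataset.values.columns)
    else:
        profiles = mat
        ids = list(dataset.values.index)
    n = len(ids)
    if not 1 <= k <= n:
        raise DataValidationError(f"k={k} outside [1, {n}]")
    if metric == "correlation":
        dist = squareform(_correlation_distance(profiles), checks=False)
    elif metric == "euclidean":
        dist = pdist(profiles, metric="euclidean")
    else:
        raise DataValidationError(f"unsupported metric {metric!r}")
    z = linkage(dist, method=method)
    labels = fcluster(z, t=k, criterion="maxclust")
    order = leaves_list(z)
    return ClusterResult(
        linkage_matrix=z,
        item_ids=ids,
        leaf_order=[ids[i] for i in order],
        labels=pd.Series(labels, index=ids),
        axis=axis,
        k=k,
    )
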
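"""Differentially methylated CpG (DMC) calling on M-values.

Tumor samples are compared against a pooled reference of adjacent and
normal samples.  Per probe, a two-sided Welch two-sample t-test is run on
M-values; p-values are adjusted by the Benjamini-Hochberg step-up (FDR);
a probe is a DMC when ``q < alpha`` and the effect-size criterion holds.

A "two-fold methylation change" is ambiguous on the M scale; the default
reading here is a two-fold change of the methylated/unmethylated intensity
ratio, i.e. ``|delta_M| >= log2(2) = 1`` (``mode="delta"``).
A literal M-ratio mode (``|M_tumor / M_ref| >= fold`` or its reciprocal) is
also available as ``mode="ratio"``; neither reading is canonical and both
are documented in the methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CGI_CONTEXTS, MethylationDataset
from .exceptions import DataValidationError

__all__ = [
    "group_ttest",
    "bh_fdr",
    "call_dmcs",
    "summarize_context",
    "ContextSummary",
    "dmc_pipeline",
]

#: annotation classes counted as CpG-island-associated (island + shores + shelves)
CGI_ASSOCIATED = ("island", "n_shore", "s_shore", "n_shelf", "s_shelf")


def group_ttest(
    dataset: MethylationDataset,
    group_a: list[str],
    group_b: list[str],
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-probe two-sample t-test of group A versus group B on M-values.

    Returns a DataFrame indexed by probe_id with columns ``mean_a``,
    ``mean_b``, ``delta`` (mean_a - mean_b), ``t`` and ``p``.  The default is
    the Welch (unequal-variance) test with Welch-Satterthwaite degrees of
    freedom; ``equal_var=True`` selects the pooled-variance test.

    Probes with zero variance in both groups are degenerate for the t-test:
    equal means give ``p = 1``; unequal means give ``p = 0`` with an infinite
    statistic, and the probe is flagged in the ``degenerate`` column.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise DataValidationError("each group needs >= 2 samples")
    if set(group_a) & set(group_b):
        raise DataValidationError("groups must be disjoint")
    values = dataset.to_m().values
    a = values[list(group_a)].to_numpy(dtype=float)
    b = values[list(group_b)].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # zero-variance probes are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    delta = mean_a - mean_b
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    if degenerate.any():
        eq = degenerate & (delta == 0)
        ne = degenerate & (delta != 0)
        with np.errstate(invalid="ignore"):
            t = np.where(eq, 0.0, t)
            p = np.where(eq, 1.0, p)
            t = np.where(ne, np.sign(delta) * np.inf, t)
            p = np.where(ne, 0.0, p)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "delta": delta,
            "t": t,
            "p": p,
            "degenerate": degenerate,
        },
        index=values.index,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} m * p_(j) / j`` capped at 1, returned in the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DataValidationError("p_values must be one-dimensional")
    if p.size == 0:
        return np.array([])
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise DataValidationError("p-values must lie in [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(q, index=p_values.index)
    return q


def call_dmcs(
    stats_df: pd.DataFrame,
    alpha: float = 0.05,
    delta_m_threshold: float = 1.0,
    mode: str = "delta",
) -> pd.DataFrame:
    """Classify each probe as hyper, hypo or ns from test results + q-values.

    ``stats_df`` must carry ``delta`` (tumor minus reference mean M) and
    ``q``; run :func:`bh_fdr` on the ``p`` column first.  In the default
    ``delta`` mode the effect criterion is ``|delta| >= delta_m_threshold``
    M-units.  ``ratio`` mode applies the literal reading: the ratio of group
    mean M-values (either way round) must reach ``2**delta_m_threshold``.
    """
    if "q" not in stats_df.columns:
        raise DataValidationError("q-values missing: run bh_fdr before call_dmcs")
    delta = stats_df["delta"].to_numpy(dtype=float)
    q = stats_df["q"].to_numpy(dtype=float)
    if mode == "delta":
        effect = np.abs(delta) >= delta_m_threshold
    elif mode == "ratio":
        fold = 2.0 ** delta_m_threshold
        ma = stats_df["mean_a"].to_numpy(dtype=float)
        mb = stats_df["mean_b"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.abs(ma) / np.abs(mb)
        ratio = np.where(np.isnan(ratio), 1.0, ratio)
        effect = (ratio >= fold) | (ratio <= 1.0 / fold)
    else:
        raise DataValidationError(f"unknown mode {mode!r}")
    sig = q < alpha
    status = np.where(
        sig & effect & (delta > 0),
        "hyper",
        np.where(sig & effect & (delta < 0), "hypo", "ns"),
    )
    out = stats_df.copy()
    out["status"] = status
    return out


@dataclass
class ContextSummary:
    """CpG-island-context composition of DMCs, split by direction.

    ``counts``/``fractions`` map direction -> per-context Series; a direction
    with no DMCs is absent from the mappings rather than reported as 0/0.
    ``cgi_associated_fraction`` is the island + shore + shelf aggregate.
    """

    counts: dict[str, pd.Series]
    fractions: dict[str, pd.Series]
    cgi_associated_fraction: dict[str, float]


def summarize_context(dmcs: pd.DataFrame, manifest: pd.DataFrame) -> ContextSummary:
    """Count hyper/hypo DMCs per CpG-island context class.

    ``dmcs`` is the output of :func:`call_dmcs`; probes with status ``ns``
    are ignored.  Raises if any DMC probe carries an unknown context label.
    """
    called = dmcs[dmcs["status"].isin(["hyper", "hypo"])]
    missing = called.index.difference(manifest.index)
    if len(missing):
        raise DataValidationError(f"DMC probes missing from manifest: {list(missing[:5])}")
    ctx = manifest.loc[called.index, "cgi_context"]
    bad = set(ctx) - set(CGI_CONTEXTS)
    if bad:
        offenders = list(ctx.index[ctx.isin(bad)][:5])
        raise DataValidationError(
            f"unknown cgi_context labels {sorted(bad)} on probes {offenders}"
        )
    counts: dict[str, pd.Series] = {}
    fractions: dict[str, pd.Series] = {}
    aggregate: dict[str, float] = {}
    for direction in ("hyper", "hypo"):
        sub = ctx[called["status"] == direction]
        if len(sub) == 0:
            continue
        c = sub.value_counts().reindex(CGI_CONTEXTS, fill_value=0)
        counts[direction] = c
        fractions[direction] = c / c.sum()
        aggregate[direction] = float(fractions[direction][list(CGI_ASSOCIATED)].sum())
    return ContextSummary(counts=counts, fractions=fractions,
                          cgi_associated_fraction=aggregate)


def dmc_pipeline(
    dataset: MethylationDataset,
    alpha: float = 0.05,
    delta_m_threshold: float = 1.0,
    mode: str = "delta",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Tumor vs pooled (adjacent + normal) DMC calling, end to end.

    Convenience wrapper reproducing the standard comparison design: test,
    adjust, threshold.  Returns the per-probe table with columns
    ``mean_m_tumor``, ``mean_m_ref``, ``delta_m``, ``t``, ``p``, ``q``,
    ``status``.

    The pipeline defaults to the pooled-variance t: with four samples per
    group, per-probe variance estimates are too unstable for the Welch
    test's reduced degrees of freedom, and pooling matches how array
    class-comparison tools test at this scale.  Pass ``equal_var=False``
    for Welch.
    """
    tumor = dataset.sample_ids("tumor")
    ref = dataset.sample_ids("adjacent") + dataset.sample_ids("normal")
    res = group_ttest(dataset, tumor, ref, equal_var=equal_var)
    res["q"] = bh_fdr(res["p"].to_numpy())
    res = call_dmcs(res, alpha=alpha, delta_m_threshold=delta_m_threshold, mode=mode)
    res = res.rename(
        columns={"mean_a": "mean_m_tumor", "mean_b": "mean_m_ref", "delta": "delta_m"}
    )
    return res
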
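"""Association and diagnostic statistics for binary methylation calls.

MSP yields one binary methylated/unmethylated call per subject, gene and
compartment.  This module computes per-stratum methylation frequencies,
case-vs-control and clinicopathological contingency-table tests (Pearson
chi-square without continuity correction, or Fisher's exact test when
expected counts are small), the Bonferroni family-wise threshold, the
any-positive panel rule over a gene set, and diagnostic performance
(sensitivity, specificity, tie-corrected Mann-Whitney AUC with a
Hanley-McNeil 95% CI) for binary markers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataValidationError

__all__ = [
    "AssociationResult",
    "DiagnosticResult",
    "Frequency",
    "methylation_frequency",
    "pearson_chi2",
    "fisher_exact",
    "choose_test",
    "bonferroni_threshold",
    "panel_call",
    "binary_marker_auc",
    "diagnostics_from_calls",
    "clinico_association_report",
]

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, matching how clinical tables print percents."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class Frequency:
    """A positivity proportion with its counts and printed-style percent."""

    positives: int
    total: int

    @property
    def proportion(self) -> float:
        return self.positives / self.total

    @property
    def percent(self) -> float:
        return round_half_up(100.0 * self.positives / self.total, 1)


@dataclass
class AssociationResult:
    """A contingency-table test result."""

    table: np.ndarray
    test: str  # "pearson_chi2" | "fisher_exact"
    statistic: float
    p_value: float
    df: int | None = None
    alt_p_value: float | None = None  # the other test's p, when both computed


@dataclass
class DiagnosticResult:
    """Binary-marker diagnostic performance on a case/control cohort."""

    n_cases: int
    n_controls: int
    case_positives: int
    control_positives: int
    sensitivity: float  # proportion
    specificity: float  # proportion
    auc: float
    auc_ci_low: float
    auc_ci_high: float

    @property
    def sensitivity_percent(self) -> float:
        return round_half_up(100 * self.sensitivity, 1)

    @property
    def specificity_percent(self) -> float:
        return round_half_up(100 * self.specificity, 1)

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "case_positives": self.case_positives,
            "control_positives": self.control_positives,
            "sensitivity_percent": self.sensitivity_percent,
            "specificity_percent": self.specificity_percent,
            "auc": round(self.auc, 3),
            "auc_ci": [round(self.auc_ci_low, 3), round(self.auc_ci_high, 3)],
        }


def _validate_calls(calls: pd.DataFrame) -> None:
    required = {"subject_id", "cohort", "compartment", "gene", "call"}
    missing = required - set(calls.columns)
    if missing:
        raise DataValidationError(f"call table missing columns: {sorted(missing)}")
    if not calls["call"].isin([0, 1]).all():
        raise DataValidationError("calls must be binary 0/1")
    dup = calls.duplicated(["subject_id", "compartment", "gene"])
    if dup.any():
        raise DataValidationError(
            f"duplicate (subject, compartment, gene) rows: {int(dup.sum())}"
        )


def methylation_frequency(
    calls: pd.DataFrame, gene: str, compartment: str, cohort: str
) -> Frequency:
    """Positivity frequency of one gene in one compartment of one cohort."""
    _validate_calls(calls)
    sub = calls[
        (calls["gene"] == gene)
        & (calls["compartment"] == compartment)
        & (calls["cohort"] == cohort)
    ]
    if sub.empty:
        raise DataValidationError(
            f"empty stratum: gene={gene!r}, compartment={compartment!r}, "
            f"cohort={cohort!r}"
        )
    return Frequency(positives=int(sub["call"].sum()), total=int(len(sub)))


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise DataValidationError("contingency table must be 2-dimensional")
    if np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise DataValidationError("counts must be non-negative integers")
    return arr


def pearson_chi2(table) -> AssociationResult:
    """Pearson chi-square test of independence, no continuity correction."""
    arr = _as_table(table)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise DataValidationError("contingency table has a zero margin")
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return AssociationResult(
        table=arr.astype(int), test="pearson_chi2",
        statistic=float(chi2), p_value=float(p), df=int(df),
    )


def fisher_exact(table) -> AssociationResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The two-sided p is the total hypergeometric probability (margins fixed)
    of all tables at most as probable as the observed one.
    """
    arr = _as_table(table)
    if arr.shape != (2, 2):
        raise DataValidationError("fisher_exact supports 2x2 tables only")
    odds, p = stats.fisher_exact(arr.astype(int), alternative="two-sided")
    return AssociationResult(
        table=arr.astype(int), test="fisher_exact",
        statistic=float(odds), p_value=float(p), df=None,
    )


def expected_counts(table) -> np.ndarray:
    """Expected cell counts under independence, ``row_i * col_j / n``."""
    arr = _as_table(table)
    n = arr.sum()
    if n == 0:
        raise DataValidationError("empty contingency table")
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / n


def choose_test(table) -> AssociationResult:
    """Dispatch 2x2 tables: Fisher when any expected count < 5, else Pearson.

    Both p-values are computed and logged; the unchosen one is attached as
    ``alt_p_value``.
    """
    arr = _as_table(table)
    if arr.shape != (2, 2):
        raise DataValidationError("choose_test supports 2x2 tables only")
    exp_min = expected_counts(arr).min()
    fisher = fisher_exact(arr)
    if exp_min < 5:
        chosen, alt = fisher, None
        try:
            alt = pearson_chi2(arr)
        except DataValidationError:
            pass  # zero margin: chi-square undefined, Fisher still valid
        if alt is not None:
            chosen.alt_p_value = alt.p_value
    else:
        chosen = pearson_chi2(arr)
        chosen.alt_p_value = fisher.p_value
    logger.info(
        "choose_test: min expected=%.2f -> %s (p=%.4g, alt p=%s)",
        exp_min, chosen.test, chosen.p_value, chosen.alt_p_value,
    )
    return chosen


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Family-wise significance threshold ``alpha / n_tests``."""
    if n_tests < 1:
        raise DataValidationError("n_tests must be >= 1")
    return alpha / n_tests


def panel_call(
    calls: pd.DataFrame, genes: list[str], compartment: str = "plasma"
) -> pd.Series:
    """Any-positive panel rule: subject positive iff any listed gene is.

    Evaluated per subject over the given compartment; returns a 0/1 Series
    indexed by subject_id covering every subject with calls there.
    """
    _validate_calls(calls)
    sub = calls[calls["compartment"] == compartment]
    missing = set(genes) - set(sub["gene"].unique())
    if missing:
        raise DataValidationError(
            f"genes absent from {compartment} calls: {sorted(missing)}"
        )
    sub = sub[sub["gene"].isin(genes)]
    return sub.groupby("subject_id")["call"].max().astype(int)


def binary_marker_auc(
    case_positives: int,
    n_cases: int,
    control_positives: int,
    n_controls: int,
) -> DiagnosticResult:
    """Diagnostic performance of a binary marker from its 2x2 counts.

    AUC uses the Mann-Whitney formulation with midrank tie handling:
    ``AUC = P(case > control) + 0.5 * P(case == control)`` over all
    case-control pairs, which for a binary marker equals
    ``(sensitivity + specificity) / 2`` exactly.  The 95% CI uses the
    Hanley-McNeil standard error, clipped to [0, 1].
    """
    if n_cases <= 0 or n_controls <= 0:
        raise DataValidationError("n_cases and n_controls must be positive")
    if not 0 <= case_positives <= n_cases:
        raise DataValidationError("case_positives outside [0, n_cases]")
    if not 0 <= control_positives <= n_controls:
        raise DataValidationError("control_positives outside [0, n_controls]")
    cp, cn = case_positives, n_cases - case_positives
    up, un = control_positives, n_controls - control_positives
    pairs = n_cases * n_controls
    greater = cp * un            # case scores 1, control 0
    ties = cp * up + cn * un
    auc = (greater + 0.5 * ties) / pairs
    sens = cp / n_cases
    spec = un / n_controls
    q1 = auc / (2 - auc)
    q2 = 2 * auc * auc / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_cases - 1) * (q1 - auc * auc)
        + (n_controls - 1) * (q2 - auc * auc)
    ) / pairs
    se = float(np.sqrt(max(var, 0.0)))
    lo = max(0.0, auc - 1.959963984540054 * se)
    hi = min(1.0, auc + 1.959963984540054 * se)
    return DiagnosticResult(
        n_cases=n_cases, n_controls=n_controls,
        case_positives=case_positives, control_positives=control_positives,
        sensitivity=sens, specificity=spec,
        auc=auc, auc_ci_low=lo, auc_ci_high=hi,
    )


def diagnostics_from_calls(
    calls: pd.DataFrame,
    genes: list[str],
    compartment: str = "plasma",
) -> dict[str, DiagnosticResult]:
    """Per-gene and any-positive-panel diagnostics from a call table.

    Cases and controls are read from the ``cohort`` column; the panel entry
    is keyed ``"panel"``.
    """
    _validate_calls(calls)
    out: dict[str, DiagnosticResult] = {}
    sub = calls[calls["compartment"] == compartment]
    case_ids = sub.loc[sub["cohort"] == "case", "subject_id"].unique()
    control_ids = sub.loc[sub["cohort"] == "control", "subject_id"].unique()
    if len(case_ids) == 0 or len(control_ids) == 0:
        raise DataValidationError("need both cases and controls with plasma calls")
    for gene in genes:
        fc = methylation_frequency(calls, gene, compartment, "case")
        fu = methylation_frequency(calls, gene, compartment, "control")
        out[gene] = binary_marker_auc(fc.positives, fc.total, fu.positives, fu.total)
    panel = panel_call(calls, genes, compartment)
    cp = int(panel.loc[panel.index.isin(case_ids)].sum())
    up = int(panel.loc[panel.index.isin(control_ids)].sum())
    out["panel"] = binary_marker_auc(cp, len(case_ids), up, len(control_ids))
    return out


def clinico_association_report(
    calls: pd.DataFrame,
    clinical: pd.DataFrame,
    genes: list[str],
    compartment: str = "tumor_tissue",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Gene x covariate association tests on case subjects.

    For each gene and categorical covariate, the subjects' binary calls in
    the chosen compartment are cross-tabulated against the covariate
    levels.  Two-level covariates go through :func:`choose_test`; covariates
    with three or more levels use Pearson chi-square.  Missing covariate
    values are excluded pairwise (the n used is reported); single-level
    covariates are skipped with a warning.  The Bonferroni-adjusted
    threshold ``alpha / n_genes`` flags significance.
    """
    _validate_calls(calls)
    sub = calls[(calls["compartment"] == compartment) & (calls["cohort"] == "case")]
    threshold = bonferroni_threshold(alpha, len(genes))
    rows = []
    for gene in genes:
        g = sub[sub["gene"] == gene].set_index("subject_id")["call"]
        for cov in clinical.columns:
            values = clinical[cov].reindex(g.index)
            mask = values.notna() & (values != "")
            if mask.sum() == 0:
                warnings.warn(f"covariate {cov}: no data; skipped", stacklevel=2)
                continue
            levels = values[mask].unique()
            if len(levels) < 2:
                warnings.warn(
                    f"covariate {cov} has a single level; skipped", stacklevel=2
                )
                continue
            ct = pd.crosstab(values[mask], g[mask]).reindex(
                columns=[0, 1], fill_value=0
            )
            table = ct.to_numpy()
            try:
                if len(levels) == 2:
                    res = choose_test(table)
                else:
                    res = pearson_chi2(table)
            except DataValidationError as exc:
                warnings.warn(f"{gene} x {cov}: {exc}; skipped", stacklevel=2)
                continue
            rows.append(
                {
                    "gene": gene,
                    "covariate": cov,
                    "n": int(mask.sum()),
                    "test": res.test,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "significant_bonferroni": res.p_value < threshold,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "covariate", "n", "test", "statistic", "p_value",
                 "significant_bonferroni"],
    )
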
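import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from escmeth import (
    DataValidationError,
    binary_marker_auc,
    bonferroni_threshold,
    choose_test,
    clinico_association_report,
    diagnostics_from_calls,
    fisher_exact,
    methylation_frequency,
    panel_call,
    pearson_chi2,
)
from escmeth.biomarkers import expected_counts, round_half_up


def make_calls(assignments, cohort="case", compartment="plasma", n=None,
               prefix="X"):
    """assignments: gene -> set of positive subject indices."""
    if n is None:
        n = max(max((max(s, default=-1) for s in assignments.values()),
                    default=-1) + 1, 1)
    rows = []
    for gene, pos in assignments.items():
        for i in range(n):
            rows.append((f"{prefix}{i:03d}", cohort, compartment, gene,
                         int(i in pos)))
    return pd.DataFrame(
        rows, columns=["subject_id", "cohort", "compartment", "gene", "call"]
    )


def enum_fisher_p(a, b, c, d):
    """Exhaustive hypergeometric enumeration oracle for the two-sided p."""
    from math import comb
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = comb(n, c1)
    probs = [comb(r1, x) * comb(r2, c1 - x) / denom for x in range(lo, hi + 1)]
    pa = probs[a - lo]
    return sum(p for p in probs if p <= pa * (1 + 1e-9))


class TestFrequency:
    @pytest.mark.parametrize(
        "positives, total, percent",
        [(25, 42, 59.5), (23, 42, 54.8), (19, 42, 45.2), (2, 42, 4.8),
         (0, 50, 0.0), (42, 42, 100.0)],
    )
    def test_percent_reporting(self, positives, total, percent):
        calls = make_calls({"G": set(range(positives))}, n=total)
        freq = methylation_frequency(calls, "G", "plasma", "case")
        assert freq.total == total
        assert freq.percent == percent

    def test_empty_stratum_named(self):
        calls = make_calls({"G": {0}})
        with pytest.raises(DataValidationError, match="tumor_tissue"):
            methylation_frequency(calls, "G", "tumor_tissue", "case")

    def test_half_up_rounding(self):
        assert round_half_up(0.05, 1) == 0.1
        assert round_half_up(59.5238 * 2, 1) == 119.0


class TestPearsonChi2:
    def test_closed_form_2x2(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 40, 4)
            res = pearson_chi2([[a, b], [c, d]])
            n = a + b + c + d
            closed = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d)
            )
            assert res.statistic == pytest.approx(closed, rel=1e-12)

    def test_tissue_vs_surrounding_tables(self):
        res = pearson_chi2([[25, 17], [2, 40]])
        assert res.statistic == pytest.approx(28.9, abs=0.1)
        assert res.p_value < 0.001

    def test_tumor_size_table(self):
        res = pearson_chi2([[13, 14], [12, 3]])
        assert res.statistic == pytest.approx(4.06, abs=0.01)
        assert round(res.p_value, 3) == 0.044

    def test_independence(self):
        res = pearson_chi2([[10, 10], [10, 10]])
        assert res.statistic == 0 and res.p_value == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(DataValidationError, match="zero margin"):
            pearson_chi2([[0, 0], [5, 5]])


class TestFisherExact:
    def test_enumeration_examples(self):
        assert fisher_exact([[2, 0], [0, 2]]).p_value == pytest.approx(1 / 3)
        assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_matches_enumeration_sample(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 15, 4)
            if a + b == 0 or c + d == 0:
                continue
            p = fisher_exact([[a, b], [c, d]]).p_value
            assert p == pytest.approx(enum_fisher_p(a, b, c, d), abs=1e-9)

    def test_non_2x2_rejected(self):
        with pytest.raises(DataValidationError):
            fisher_exact([[1, 2, 3], [4, 5, 6]])


class TestChooseTest:
    def test_expected_count_formula(self):
        exp = expected_counts([[25, 17], [2, 40]])
        assert exp.min() == pytest.approx(42 * 27 / 84)

    @pytest.mark.parametrize(
        "table, expected_test",
        [([[25, 17], [2, 40]], "pearson_chi2"),
         ([[1, 9], [9, 1]], "pearson_chi2"),  # min expected exactly 5
         ([[1, 1], [1, 20]], "fisher_exact")],
    )
    def test_dispatch_rule(self, table, expected_test):
        res = choose_test(table)
        assert res.test == expected_test
        assert res.alt_p_value is not None


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha, n, expected", [(0.05, 3, 0.05 / 3), (0.05, 1, 0.05),
                               (0.01, 5, 0.002)]
    )
    def test_threshold(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected)

    def test_three_gene_threshold_prints_as_017(self):
        assert round(bonferroni_threshold(0.05, 3), 3) == 0.017


class TestPanelCall:
    def test_any_positive_rule(self):
        calls = make_calls({"A": {0}, "B": set(), "C": set()})
        panel = panel_call(calls, ["A", "B", "C"])
        assert panel["X000"] == 1
        assert (panel.drop("X000") == 0).all()

    def test_missing_gene_rejected(self):
        calls = make_calls({"A": {0}})
        with pytest.raises(DataValidationError, match="absent"):
            panel_call(calls, ["A", "Z"])

    def test_union_bounds_and_set_oracle(self):
        rng = np.random.default_rng(9)
        n = 40
        for _ in range(20):
            assignments = {
                g: set(rng.choice(n, rng.integers(0, n), replace=False))
                for g in ["A", "B", "C"]
            }
            calls = make_calls(assignments)
            panel = panel_call(calls, ["A", "B", "C"])
            union = set.union(*assignments.values())
            assert panel.sum() == len(union)
            singles = [len(s) for s in assignments.values()]
            assert max(singles) <= panel.sum() <= sum(singles)


class TestBinaryMarkerAuc:
    @pytest.mark.parametrize(
        "cp, nc, up, nu, sens, auc",
        [(13, 42, 0, 50, 31.0, 0.655),
         (17, 42, 0, 50, 40.5, 0.702),
         (27, 42, 0, 50, 64.3, 0.821),
         (0, 42, 0, 50, 0.0, 0.5)],
    )
    def test_reported_diagnostics(self, cp, nc, up, nu, sens, auc):
        res = binary_marker_auc(cp, nc, up, nu)
        assert res.sensitivity_percent == sens
        assert res.specificity_percent == 100.0
        assert round(res.auc, 3) == auc

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(data=st.data())
    def test_auc_identity(self, data):
        nc = data.draw(st.integers(1, 200))
        nu = data.draw(st.integers(1, 200))
        cp = data.draw(st.integers(0, nc))
        up = data.draw(st.integers(0, nu))
        res = binary_marker_auc(cp, nc, up, nu)
        assert res.auc == pytest.approx(
            (res.sensitivity + res.specificity) / 2, abs=1e-12
        )
        assert 0 <= res.auc_ci_low <= res.auc <= res.auc_ci_high <= 1

    def test_invalid_counts_rejected(self):
        with pytest.raises(DataValidationError):
            binary_marker_auc(5, 4, 0, 10)
        with pytest.raises(DataValidationError):
            binary_marker_auc(0, 0, 0, 10)


class TestDiagnosticsFromCalls:
    def test_per_gene_and_panel(self):
        cases = make_calls(
            {"A": set(range(13)), "B": set(range(5, 22)),
             "C": set(range(14, 27))}, n=42,
        )
        controls = make_calls({"A": set(), "B": set(), "C": set()},
                              cohort="control", n=50, prefix="c")
        calls = pd.concat([cases, controls], ignore_index=True)
        res = diagnostics_from_calls(calls, ["A", "B", "C"])
        assert res["A"].case_positives == 13
        assert res["panel"].case_positives == 27
        assert round(res["panel"].auc, 3) == 0.821


class TestClinicoAssociation:
    def _fixture(self):
        # EPB41L3 x tumor size reproducing [[13, 14], [12, 3]]
        rows = []
        idx = 0
        for size, pos, neg in [("<5cm", 13, 14), (">=5cm", 12, 3)]:
            for _ in range(pos):
                rows.append((f"X{idx:03d}", size, 1)); idx += 1
            for _ in range(neg):
                rows.append((f"X{idx:03d}", size, 0)); idx += 1
        calls = pd.DataFrame(
            [(sid, "case", "tumor_tissue", "EPB41L3", call)
             for sid, _, call in rows],
            columns=["subject_id", "cohort", "compartment", "gene", "call"],
        )
        clinical = pd.DataFrame(
            {"tumor_size": [size for _, size, _ in rows]},
            index=pd.Index([sid for sid, _, _ in rows], name="subject_id"),
        )
        return calls, clinical

    def test_reproduces_tumor_size_association(self):
        calls, clinical = self._fixture()
        report = clinico_association_report(calls, clinical, ["EPB41L3"],
                                            compartment="tumor_tissue")
        row = report.iloc[0]
        assert row["test"] == "pearson_chi2"
        assert round(row["p_value"], 3) == 0.044

    def test_three_level_covariate_uses_pearson(self, cohort):
        _, calls, clinical = cohort
        report = clinico_association_report(
            calls, clinical, ["GPX3"], compartment="tumor_tissue"
        )
        row = report[report["covariate"] == "differentiation"].iloc[0]
        assert row["test"] == "pearson_chi2"

    def test_single_level_covariate_skipped(self):
        calls, clinical = self._fixture()
        clinical["constant"] = "x"
        with pytest.warns(UserWarning, match="single level"):
            report = clinico_association_report(
                calls, clinical, ["EPB41L3"], compartment="tumor_tissue"
            )
        assert "constant" not in set(report["covariate"])

    def test_full_report_structure(self, cohort):
        _, calls, clinical = cohort
        genes = ["EPB41L3", "GPX3", "COL14A1"]
        report = clinico_association_report(calls, clinical, genes,
                                            compartment="tumor_tissue")
        assert set(report["gene"]) == set(genes)
        assert ((report["p_value"] >= 0) & (report["p_value"] <= 1)).all()
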
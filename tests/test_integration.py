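import numpy as np
import pandas as pd
import pytest

from escmeth import (
    DataValidationError,
    ExpressionDataset,
    FunnelReport,
    SimulationConfig,
    call_de_genes,
    dmc_pipeline,
    generate_expression_dataset,
    generate_methylation_dataset,
    integration_pipeline,
    intersect_inverse,
    map_promoter_dmcs_to_genes,
    rank_candidates,
)


def make_expression(gene_means_tumor, gene_means_normal, n_per_group=5,
                    noise=0.05, seed=0, unmapped=0):
    """Expression fixture: one probe per gene, tight noise."""
    rng = np.random.default_rng(seed)
    genes = sorted(gene_means_tumor)
    probes = [f"p{i}" for i in range(len(genes) + unmapped)]
    rows = []
    for g in genes:
        rows.append(
            np.concatenate([
                rng.normal(gene_means_tumor[g], noise, n_per_group),
                rng.normal(gene_means_normal[g], noise, n_per_group),
            ])
        )
    for _ in range(unmapped):
        rows.append(rng.normal(5.0, noise, 2 * n_per_group))
    samples = [f"T{i}" for i in range(n_per_group)] + \
        [f"N{i}" for i in range(n_per_group)]
    values = pd.DataFrame(rows, index=pd.Index(probes, name="probe_id"),
                          columns=samples)
    mapping = pd.Series(genes + [np.nan] * unmapped, index=values.index)
    groups = pd.Series(["tumor"] * n_per_group + ["normal"] * n_per_group,
                       index=values.columns)
    return ExpressionDataset(values=values, probe_to_gene=mapping,
                             groups=groups)


def make_dmcs(records):
    """records: list of (probe, status, q, delta_m)."""
    return pd.DataFrame(
        [{"status": s, "q": q, "delta_m": d} for _, s, q, d in records],
        index=[r[0] for r in records],
    )


def make_manifest(records):
    """records: list of (probe, gene_field, region_field)."""
    return pd.DataFrame(
        [{"chromosome": "chr1", "position": i + 1, "gene": g,
          "gene_region": r, "cgi_context": "island"}
         for i, (_, g, r) in enumerate(records)],
        index=[r[0] for r in records],
    )


class TestCallDeGenes:
    def test_down_regulated_gene(self):
        expr = make_expression({"A": 8.0, "B": 9.0}, {"A": 10.0, "B": 9.0})
        out = call_de_genes(expr)
        assert out.loc["A", "direction"] == "down"
        assert out.loc["A", "log2fc"] == pytest.approx(-2.0, abs=0.1)
        assert out.loc["B", "direction"] == "ns"

    def test_insignificant_q_blocks_call(self):
        # huge noise: big fold change but no significance
        expr = make_expression({"A": 8.0}, {"A": 10.0}, noise=8.0, seed=1)
        out = call_de_genes(expr)
        assert out.loc["A", "direction"] == "ns"

    def test_unmapped_probes_dropped(self):
        expr = make_expression({"A": 8.0}, {"A": 10.0}, unmapped=3)
        out = call_de_genes(expr)
        assert list(out.index) == ["A"]
        assert out.attrs["n_expr_probes"] == 1

    def test_collapse_keeps_brightest_probe(self):
        values = pd.DataFrame(
            [[10.0, 10.0, 8.0, 8.0],   # bright probe of A, fc -? tumor-normal
             [2.0, 2.0, 4.0, 4.0]],    # dim probe of A
            index=pd.Index(["p0", "p1"], name="probe_id"),
            columns=["T0", "T1", "N0", "N1"],
        )
        values += np.random.default_rng(0).normal(0, 0.01, values.shape)
        expr = ExpressionDataset(
            values=values,
            probe_to_gene=pd.Series(["A", "A"], index=values.index),
            groups=pd.Series(["tumor", "tumor", "normal", "normal"],
                             index=values.columns),
        )
        out = call_de_genes(expr)
        assert out.loc["A", "probe_id"] == "p0"
        assert out.loc["A", "log2fc"] == pytest.approx(2.0, abs=0.1)

    def test_recovers_planted_genes(self):
        cfg = SimulationConfig(n_probes=2000, seed=3, inverse_link_prob=1.0)
        _, truth = generate_methylation_dataset(cfg)
        expr = generate_expression_dataset(truth, cfg)
        out = call_de_genes(expr)
        planted = set(truth.planted_inverse_genes)
        called = set(out.index[out["de"]])
        assert len(planted & called) >= 0.95 * len(planted)


class TestMapPromoterDmcs:
    def test_majority_direction(self):
        dmcs = make_dmcs([("cg0", "hyper", 0.01, 2.0),
                          ("cg1", "hyper", 0.02, 1.5),
                          ("cg2", "hyper", 0.03, 1.0)])
        manifest = make_manifest([("cg0", "A", "TSS200"),
                                  ("cg1", "A", "TSS1500"),
                                  ("cg2", "A", "5UTR")])
        out = map_promoter_dmcs_to_genes(dmcs, manifest)
        assert out.loc["A", "meth_direction"] == "hyper"
        assert out.loc["A", "n_promoter_dmcs"] == 3
        assert out.loc["A", "best_dmc_q"] == pytest.approx(0.01)

    def test_tie_drops_gene_with_warning(self):
        dmcs = make_dmcs([("cg0", "hyper", 0.01, 2.0),
                          ("cg1", "hypo", 0.02, -1.5)])
        manifest = make_manifest([("cg0", "A", "TSS200"),
                                  ("cg1", "A", "TSS200")])
        with pytest.warns(UserWarning, match="tie"):
            out = map_promoter_dmcs_to_genes(dmcs, manifest)
        assert "A" not in out.index

    def test_semicolon_lists_paired_positionally(self):
        dmcs = make_dmcs([("cg0", "hyper", 0.01, 2.0)])
        manifest = make_manifest([("cg0", "GENE_A;GENE_B", "TSS200;Body")])
        out = map_promoter_dmcs_to_genes(dmcs, manifest)
        assert list(out.index) == ["GENE_A"]

    def test_body_only_probes_excluded(self):
        dmcs = make_dmcs([("cg0", "hyper", 0.01, 2.0)])
        manifest = make_manifest([("cg0", "A", "Body")])
        out = map_promoter_dmcs_to_genes(dmcs, manifest)
        assert out.empty
        assert out.attrs["n_promoter_dmcs"] == 0
        assert out.attrs["n_dmcs"] == 1


class TestIntersectInverse:
    def _meth(self, directions):
        df = pd.DataFrame(
            {"meth_direction": list(directions.values()),
             "n_promoter_dmcs": 1, "best_dmc_q": 0.01, "mean_delta_m": 2.0},
            index=pd.Index(directions.keys(), name="gene"),
        )
        df.attrs.update(n_dmcs=len(df), n_promoter_dmcs=len(df))
        return df

    def _de(self, directions):
        return pd.DataFrame(
            {"log2fc": [(-2.0 if d == "down" else 2.0) for d in
                        directions.values()],
             "q": 0.01, "de": True, "direction": list(directions.values())},
            index=pd.Index(directions.keys(), name="gene"),
        )

    def test_set_logic(self):
        cands, report = intersect_inverse(
            self._meth({"A": "hyper", "B": "hyper", "C": "hypo"}),
            self._de({"B": "down", "C": "up", "D": "down"}),
        )
        assert set(cands.index) == {"B", "C"}
        assert report.n_common == 2 and report.n_inverse == 2

    def test_direction_conflict_excluded(self):
        cands, report = intersect_inverse(
            self._meth({"A": "hyper"}), self._de({"A": "up"})
        )
        assert report.n_common == 1 and report.n_inverse == 0
        assert cands.empty

    def test_matches_brute_force_pairing(self):
        rng = np.random.default_rng(8)
        genes_m = [f"G{i}" for i in rng.choice(500, 200, replace=False)]
        genes_e = [f"G{i}" for i in rng.choice(500, 200, replace=False)]
        mdir = {g: rng.choice(["hyper", "hypo"]) for g in genes_m}
        edir = {g: rng.choice(["up", "down"]) for g in genes_e}
        cands, report = intersect_inverse(self._meth(mdir), self._de(edir))
        expected = set()
        for gm, dm in mdir.items():
            for ge, de in edir.items():
                if gm == ge and ((dm == "hyper" and de == "down")
                                 or (dm == "hypo" and de == "up")):
                    expected.add(gm)
        assert set(cands.index) == expected
        assert report.n_common == len(set(genes_m) & set(genes_e))

    def test_funnel_inequalities_random_instances(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            nm, ne = rng.integers(1, 50, 2)
            mdir = {f"G{i}": rng.choice(["hyper", "hypo"])
                    for i in rng.choice(100, nm, replace=False)}
            edir = {f"G{i}": rng.choice(["up", "down"])
                    for i in rng.choice(100, ne, replace=False)}
            _, report = intersect_inverse(self._meth(mdir), self._de(edir))
            assert report.n_inverse <= report.n_common
            assert report.n_common <= min(report.n_meth_genes,
                                          report.n_expr_genes)
            assert report.n_promoter_dmcs <= report.n_dmcs


class TestRankCandidates:
    def _cands(self, rows):
        return pd.DataFrame(
            rows,
            index=pd.Index([r["gene"] for r in rows], name="gene"),
        ).drop(columns="gene")

    def test_score_order(self):
        cands = self._cands([
            {"gene": "A", "mean_delta_m": 2.0, "log2fc": -3.0,
             "best_dmc_q": 0.01, "rank_score": 6.0},
            {"gene": "B", "mean_delta_m": 1.0, "log2fc": -1.0,
             "best_dmc_q": 0.01, "rank_score": 1.0},
        ])
        out = rank_candidates(cands, 2)
        assert list(out.index) == ["A", "B"]

    def test_tie_broken_by_q_then_symbol(self):
        cands = self._cands([
            {"gene": "B", "mean_delta_m": 1.0, "log2fc": -1.0,
             "best_dmc_q": 0.01, "rank_score": 1.0},
            {"gene": "A", "mean_delta_m": 1.0, "log2fc": -1.0,
             "best_dmc_q": 0.001, "rank_score": 1.0},
            {"gene": "C", "mean_delta_m": 1.0, "log2fc": -1.0,
             "best_dmc_q": 0.01, "rank_score": 1.0},
        ])
        out = rank_candidates(cands, 3)
        assert list(out.index) == ["A", "B", "C"]

    def test_overlong_topk_warns(self):
        cands = self._cands([
            {"gene": "A", "mean_delta_m": 1.0, "log2fc": -1.0,
             "best_dmc_q": 0.01, "rank_score": 1.0},
        ])
        with pytest.warns(UserWarning, match="top_k"):
            out = rank_candidates(cands, 5)
        assert len(out) == 1

    def test_empty_rejected(self):
        with pytest.raises(DataValidationError):
            rank_candidates(pd.DataFrame(), 3)


class TestFunnelEndToEnd:
    def test_strong_effects_recover_planted_set_exactly(self):
        cfg = SimulationConfig(n_probes=2000, seed=5, inverse_link_prob=1.0)
        ds, truth = generate_methylation_dataset(cfg)
        expr = generate_expression_dataset(truth, cfg)
        dmcs = dmc_pipeline(ds)
        cands, top, report = integration_pipeline(dmcs, ds.manifest, expr)
        assert set(cands.index) == set(truth.planted_inverse_genes)
        assert len(top) == 3
        assert top["inverse_consistent"].all()

    def test_no_links_empty_funnel(self):
        cfg = SimulationConfig(n_probes=1000, seed=6, inverse_link_prob=0.0)
        ds, truth = generate_methylation_dataset(cfg)
        expr = generate_expression_dataset(truth, cfg)
        dmcs = dmc_pipeline(ds)
        meth = map_promoter_dmcs_to_genes(dmcs, ds.manifest)
        de = call_de_genes(expr)
        cands, report = intersect_inverse(meth, de)
        assert report.n_inverse == 0
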
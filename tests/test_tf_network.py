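"""Quantile footprint calling, bound-gene counting, key-TF ranking and
cascade network construction."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from triomics import tf_network as tfn


def footprints(scores, neglog_p=None):
    n = len(scores)
    return pd.DataFrame({
        "tf_id": [f"tf{i}" for i in range(n)],
        "diff_binding_score": scores,
        "neglog10_p": neglog_p if neglog_p is not None else [0.1] * n,
    })


def gene_table(lfc_by_gene, labels=None):
    return pd.DataFrame({
        "feature_id": list(lfc_by_gene),
        "base_mean": 10.0,
        "log2fc": list(lfc_by_gene.values()),
        "pvalue": 1e-5,
        "padj": 1e-4,
        "label": [labels.get(g, "ns") if labels else "ns" for g in lfc_by_gene],
    })


class TestQuantileCalling:
    def test_top_and_bottom_five_percent_flagged(self):
        stats = footprints(list(range(1, 101)))
        calls = tfn.call_differential_tfs(stats).set_index("tf_id")["footprint_call"]
        scores = dict(zip(stats["tf_id"], stats["diff_binding_score"]))
        # brute-force sort-and-slice oracle
        ranked = sorted(scores, key=scores.get)
        assert {t for t in calls.index if calls[t] == "decreased"} == set(ranked[:5])
        assert {t for t in calls.index if calls[t] == "increased"} == set(ranked[-5:])

    def test_matches_brute_force_on_random_scores(self):
        rng = np.random.default_rng(30)
        scores = rng.normal(0, 2, size=60)
        stats = footprints(scores, neglog_p=np.abs(rng.normal(0, 1, size=60)))
        calls = tfn.call_differential_tfs(stats).set_index("tf_id")["footprint_call"]
        q_lo, q_hi = np.quantile(scores, [0.05, 0.95])
        p_hi = np.quantile(stats["neglog10_p"], 0.95)
        for row in stats.itertuples(index=False):
            s, p = row.diff_binding_score, row.neglog10_p
            if s > q_hi:
                expected = "increased"
            elif s < q_lo:
                expected = "decreased"
            elif p > p_hi:
                expected = "increased" if s > 0 else ("decreased" if s < 0 else "ns")
            else:
                expected = "ns"
            assert calls[row.tf_id] == expected

    def test_identical_scores_pass_no_score_criterion(self):
        calls = tfn.call_differential_tfs(footprints([1.0] * 30))
        assert (calls["footprint_call"] == "ns").all()

    def test_extreme_pvalue_flags_regardless_of_score_size(self):
        neglog_p = [0.1] * 29 + [15.0]
        scores = list(np.linspace(-1, 1, 29)) + [0.05]
        calls = tfn.call_differential_tfs(footprints(scores, neglog_p)).set_index("tf_id")
        assert calls.at["tf29", "footprint_call"] == "increased"  # tiny but positive score

    def test_fewer_than_twenty_tfs_raises(self):
        with pytest.raises(ValueError, match=">= 20"):
            tfn.call_differential_tfs(footprints([1.0] * 19))

    def test_score_tails_bounded_at_five_percent(self, dataset):
        calls = tfn.call_differential_tfs(dataset.footprint_stats)
        n = len(calls)
        by_score_inc = (
            calls["diff_binding_score"]
            > np.quantile(calls["diff_binding_score"], 0.95)
        ).sum()
        assert by_score_inc <= math.ceil(0.05 * n)


class TestBoundGenes:
    PEAKS = pd.DataFrame({
        "peak_id": ["pkA", "pkB", "pkC"],
        "chrom": ["chr1", "chr1", "chr1"],
        "start": [1000, 5000, 9000],
        "end": [1600, 5600, 9600],
    })
    ASSIGNMENTS = pd.DataFrame({
        "gene_id": ["gA", "gB", "gC"],
        "peak_ids": [["pkA"], ["pkB"], ["pkC"]],
        "n_peak": [1, 1, 1],
    })

    def sites(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])

    def test_sign_counting(self):
        sites = self.sites([
            ("chr1", 1100, 1115, "tfX", 0, "."),
            ("chr1", 5100, 5115, "tfX", 0, "."),
            ("chr1", 9100, 9115, "tfX", 0, "."),
        ])
        bound = tfn.bound_genes(sites, self.PEAKS, self.ASSIGNMENTS)
        genes = gene_table({"gA": 0.4, "gB": 2.0, "gC": -1.0})
        assert tfn.bound_gene_direction_counts("tfX", bound, genes) == (2, 1)

    def test_site_outside_any_peak_is_not_bound(self):
        sites = self.sites([("chr1", 3000, 3015, "tfX", 0, ".")])  # between peaks
        bound = tfn.bound_genes(sites, self.PEAKS, self.ASSIGNMENTS)
        assert bound.empty

    def test_matches_brute_force_triple_join(self):
        rng = np.random.default_rng(31)
        sites = self.sites([
            ("chr1", int(s), int(s) + 15, f"tf{rng.integers(3)}", 0, ".")
            for s in rng.integers(0, 11000, size=60)
        ])
        bound = tfn.bound_genes(sites, self.PEAKS, self.ASSIGNMENTS)
        got = set(map(tuple, bound[["tf_id", "gene_id"]].drop_duplicates().to_numpy()))
        expected = set()
        for site in sites.itertuples(index=False):
            for pk in self.PEAKS.itertuples(index=False):
                if site.start < pk.end and pk.start < site.end:
                    for a in self.ASSIGNMENTS.itertuples(index=False):
                        if pk.peak_id in a.peak_ids:
                            expected.add((site.name, a.gene_id))
        assert got == expected


class TestRanking:
    def evidence(self, rows):
        return pd.DataFrame(rows, columns=[
            "tf_id", "expression_lfc", "expression_padj", "expression_label",
            "diff_binding_score", "neglog10_p", "footprint_call",
            "n_bound_up", "n_bound_down", "relative_expression",
        ])

    def test_single_concordant_candidate_ranks_first(self):
        ev = self.evidence([
            ("tfA", 2.0, 1e-4, "up", 5.0, 8.0, "increased", 3, 0, 100.0),
            ("tfB", 2.0, 1e-4, "up", 0.1, 0.1, "ns", 5, 0, 500.0),
        ])
        ranked = tfn.rank_key_tfs(ev)
        assert ranked["tf_id"].tolist() == ["tfA"]  # tfB excluded: footprint ns

    def test_ratio_then_expression_ordering(self):
        ev = self.evidence([
            ("tfA", 2.0, 1e-4, "up", 5.0, 8.0, "increased", 2, 2, 900.0),
            ("tfB", 2.0, 1e-4, "up", 5.0, 8.0, "increased", 4, 1, 100.0),
            ("tfC", 2.0, 1e-4, "up", 5.0, 8.0, "increased", 3, 0, 500.0),
        ])
        # bound-gene ratio dominates (1.0 > 0.8 > 0.5) despite tfA's expression
        assert tfn.rank_key_tfs(ev)["tf_id"].tolist() == ["tfC", "tfB", "tfA"]

    def test_planted_seed_recovered_at_rank_one(self, dataset, result):
        assert result.key_tfs["tf_id"].iloc[0] == dataset.truth.seed_tf


class TestCascade:
    def toy(self):
        """seed binds TF_A (lfc 0.44); TF_A binds TF_B (lfc 1.92)."""
        genes = gene_table({"SEED": 1.5, "TF_A": 0.44, "TF_B": 1.92, "TF_C": -0.2})
        bound = pd.DataFrame({
            "tf_id": ["SEED", "TF_A", "SEED"],
            "gene_id": ["TF_A", "TF_B", "TF_C"],
            "site_chrom": ["chr1"] * 3,
            "site_start": [100, 200, 300],
            "site_end": [115, 215, 315],
            "peak_id": ["pk1", "pk2", "pk3"],
        })
        return genes, bound

    def test_two_layer_toy_network(self):
        genes, bound = self.toy()
        net = tfn.build_cascade_network("SEED", bound, genes, {"SEED", "TF_A", "TF_B", "TF_C"})
        assert set(net.graph.nodes) == {"SEED", "TF_A", "TF_B"}
        assert set(net.graph.edges) == {("SEED", "TF_A"), ("TF_A", "TF_B")}
        assert (net.layer("SEED"), net.layer("TF_A"), net.layer("TF_B")) == (0, 1, 2)

    def test_downregulated_bound_tf_excluded(self):
        genes, bound = self.toy()
        net = tfn.build_cascade_network("SEED", bound, genes, {"SEED", "TF_A", "TF_B", "TF_C"})
        assert "TF_C" not in net.graph  # lfc -0.2 fails the > 0 rule

    def test_no_binding_sites_gives_seed_only_network(self):
        genes, _ = self.toy()
        bound = pd.DataFrame(columns=["tf_id", "gene_id", "site_chrom", "site_start", "site_end", "peak_id"])
        net = tfn.build_cascade_network("SEED", bound, genes, {"SEED"})
        assert list(net.graph.nodes) == ["SEED"]

    def test_gene_reachable_at_both_layers_stays_shallow(self):
        genes = gene_table({"SEED": 1.0, "TF_A": 1.0, "TF_B": 1.0})
        bound = pd.DataFrame({
            "tf_id": ["SEED", "SEED", "TF_A"],
            "gene_id": ["TF_A", "TF_B", "TF_B"],
            "site_chrom": ["chr1"] * 3,
            "site_start": [1, 2, 3],
            "site_end": [16, 17, 18],
            "peak_id": ["p1", "p2", "p3"],
        })
        net = tfn.build_cascade_network("SEED", bound, genes, {"SEED", "TF_A", "TF_B"})
        assert net.layer("TF_B") == 1
        assert ("TF_A", "TF_B") not in net.graph.edges

    def test_network_is_layered_dag(self, result):
        net = result.network
        assert nx.is_directed_acyclic_graph(net.graph)
        for u, v in net.graph.edges:
            lu, lv = net.layer(u), net.layer(v)
            if lv is not None:
                assert lu == lv - 1
            assert net.graph.nodes[v]["log2fc"] > 0

    def test_removing_a_binding_site_never_adds_nodes_or_edges(self, dataset, result):
        genes = result.gene_results
        full = tfn.build_cascade_network(
            dataset.truth.seed_tf, result.bound_table, genes, set(dataset.annotation.tf_ids())
        )
        reduced_table = result.bound_table.iloc[1:]
        reduced = tfn.build_cascade_network(
            dataset.truth.seed_tf, reduced_table, genes, set(dataset.annotation.tf_ids())
        )
        assert set(reduced.graph.nodes) <= set(full.graph.nodes)
        assert set(reduced.graph.edges) <= set(full.graph.edges)

    def test_planted_cascade_recovered_exactly(self, dataset, result):
        planted = set(map(tuple, dataset.truth.cascade_edges))
        recovered = set(result.network.graph.edges)
        assert recovered == planted

    def test_graphml_and_sif_export(self, result, tmp_path):
        result.network.write_graphml(str(tmp_path / "net.graphml"))
        back = nx.read_graphml(tmp_path / "net.graphml")
        assert back.number_of_edges() == result.network.graph.number_of_edges()
        result.network.write_sif(str(tmp_path / "net.sif"))
        lines = (tmp_path / "net.sif").read_text().strip().splitlines()
        assert len(lines) == result.network.graph.number_of_edges()


class TestOverlay:
    def test_down_mirna_targeting_two_nodes(self):
        genes = gene_table({"SEED": 1.0, "TF_A": 1.0, "TF_B": 1.0})
        bound = pd.DataFrame({
            "tf_id": ["SEED", "SEED"], "gene_id": ["TF_A", "TF_B"],
            "site_chrom": ["chr1"] * 2, "site_start": [1, 2], "site_end": [16, 17],
            "peak_id": ["p1", "p2"],
        })
        net = tfn.build_cascade_network("SEED", bound, genes, {"SEED", "TF_A", "TF_B"})
        targets = pd.DataFrame({
            "mirna_id": ["m1", "m1", "m2"],
            "gene_id": ["TF_A", "TF_B", "OUTSIDE"],
        })
        mirnas = pd.DataFrame({"feature_id": ["m1", "m2"], "label": ["down", "down"]})
        overlay = tfn.mirna_network_overlay(net, targets, mirnas)
        assert len(overlay) == 1
        row = overlay.iloc[0]
        assert row["mirna_id"] == "m1" and row["n_target_nodes"] == 2
        assert bool(row["candidate_derepressor"])

    def test_matches_brute_force_intersection(self, dataset, result):
        overlay = result.mirna_overlay
        labels = result.mirna_results.set_index("feature_id")["label"]
        nodes = set(result.network.node_genes())
        expected = {}
        for r in result.target_map.itertuples(index=False):
            if labels.get(r.mirna_id) in ("up", "down") and r.gene_id in nodes:
                expected.setdefault(r.mirna_id, set()).add(r.gene_id)
        got = {r.mirna_id: set(r.target_nodes.split(",")) for r in overlay.itertuples(index=False)}
        assert got == expected
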
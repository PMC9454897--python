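"""Differential-footprint TF calling, evidence integration, and seed-TF
cascade network construction.

A TF "binds" a gene when one of its footprint binding sites overlaps an ATAC
peak assigned to that gene's promoter window — binding evidence outside open
chromatin is ignored. Differential-binding TFs are called by empirical
quantiles over the analyzed TF set: a TF is flagged when its differential
binding score falls outside the 5%/95% quantiles (top 5% per direction) or
its -log10 p exceeds the 95% quantile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

MIN_TFS_FOR_QUANTILES = 20


def call_differential_tfs(
    stats: pd.DataFrame, score_quantiles: tuple[float, float] = (0.05, 0.95), p_quantile: float = 0.95
) -> pd.DataFrame:
    """Quantile rule for differential-binding TFs.

    Flags score < q5 (decreased) or score > q95 (increased); TFs passing the
    -log10 p criterion instead take their direction from the score sign.
    Quantiles are empirical over the input set, which must hold at least 20
    TFs for the tails to be meaningful.
    """
    if len(stats) < MIN_TFS_FOR_QUANTILES:
        raise ValueError(f"need >= {MIN_TFS_FOR_QUANTILES} TFs for quantile calling, got {len(stats)}")
    scores = stats["diff_binding_score"].to_numpy(dtype=float)
    neglog_p = stats["neglog10_p"].to_numpy(dtype=float)
    q_lo, q_hi = np.quantile(scores, score_quantiles)
    p_hi = np.quantile(neglog_p, p_quantile)

    call = np.full(len(stats), "ns", dtype=object)
    call[scores > q_hi] = "increased"
    call[scores < q_lo] = "decreased"
    p_flag = (neglog_p > p_hi) & (call == "ns")
    call[p_flag & (scores > 0)] = "increased"
    call[p_flag & (scores < 0)] = "decreased"
    out = stats.copy()
    out["footprint_call"] = call
    return out


def bound_genes(
    binding_sites: pd.DataFrame,
    peak_intervals: pd.DataFrame,
    assignments: pd.DataFrame,
) -> pd.DataFrame:
    """TF -> gene binding-evidence table.

    A (tf, gene) pair is evidenced by a binding site (BED6 row with the TF id
    in the name field) overlapping a peak assigned to the gene's promoter
    window. One row per (tf, gene, site, peak) tuple.
    """
    trees: dict[str, IntervalTree] = {}
    for row in peak_intervals.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.peak_id)
    peak_to_genes: dict[str, list[str]] = {}
    for row in assignments.itertuples(index=False):
        for pid in row.peak_ids:
            peak_to_genes.setdefault(pid, []).append(row.gene_id)

    rows = []
    for site in binding_sites.itertuples(index=False):
        tree = trees.get(site.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(site.start, site.end)):
            for gene_id in peak_to_genes.get(iv.data, []):
                rows.append((site.name, gene_id, site.chrom, site.start, site.end, iv.data))
    return pd.DataFrame(
        rows, columns=["tf_id", "gene_id", "site_chrom", "site_start", "site_end", "peak_id"]
    ).drop_duplicates(ignore_index=True)


def bound_gene_direction_counts(
    tf_id: str, bound_table: pd.DataFrame, gene_results: pd.DataFrame
) -> tuple[int, int]:
    """(n_up, n_down) bound genes of a TF, by the SIGN of the expression
    log2FC (not the DEG thresholds); genes at exactly 0 count in neither."""
    lfc = gene_results.set_index("feature_id")["log2fc"]
    genes = bound_table.loc[bound_table["tf_id"] == tf_id, "gene_id"].unique()
    vals = lfc.reindex(genes).dropna()
    return int((vals > 0).sum()), int((vals < 0).sum())


def integrate_tf_evidence(
    footprint_calls: pd.DataFrame,
    gene_results: pd.DataFrame,
    bound_table: pd.DataFrame,
    tpm: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join the three evidence layers per TF: expression change, footprint
    change, and the direction balance of its bound genes."""
    genes = gene_results.set_index("feature_id")
    tpm_mean = tpm.mean(axis=1) if tpm is not None else pd.Series(dtype=float)
    rows = []
    for row in footprint_calls.itertuples(index=False):
        n_up, n_down = bound_gene_direction_counts(row.tf_id, bound_table, gene_results)
        in_expr = row.tf_id in genes.index
        rows.append(
            {
                "tf_id": row.tf_id,
                "expression_lfc": genes.at[row.tf_id, "log2fc"] if in_expr else np.nan,
                "expression_padj": genes.at[row.tf_id, "padj"] if in_expr else np.nan,
                "expression_label": genes.at[row.tf_id, "label"] if in_expr else "unexpressed",
                "diff_binding_score": row.diff_binding_score,
                "neglog10_p": row.neglog10_p,
                "footprint_call": row.footprint_call,
                "n_bound_up": n_up,
                "n_bound_down": n_down,
                "relative_expression": tpm_mean.get(row.tf_id, np.nan),
            }
        )
    return pd.DataFrame(rows)


def rank_key_tfs(evidence: pd.DataFrame) -> pd.DataFrame:
    """Rank candidate key TFs: DEG and differential-footprint in the same
    direction, ordered by the ratio of concordant bound genes then by
    relative expression (upregulated candidates first)."""
    ev = evidence.copy()
    total = (ev["n_bound_up"] + ev["n_bound_down"]).replace(0, np.nan)
    ev["up_ratio"] = (ev["n_bound_up"] / total).fillna(0.0)
    ev["down_ratio"] = (ev["n_bound_down"] / total).fillna(0.0)
    up = ev[(ev["expression_label"] == "up") & (ev["footprint_call"] == "increased")].copy()
    down = ev[(ev["expression_label"] == "down") & (ev["footprint_call"] == "decreased")].copy()
    up = up.sort_values(["up_ratio", "relative_expression", "tf_id"], ascending=[False, False, True])
    down = down.sort_values(["down_ratio", "relative_expression", "tf_id"], ascending=[False, False, True])
    ranked = pd.concat([up, down], ignore_index=True)
    if ranked.empty:
        logger.info("no TF passes both the expression and footprint criteria")
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    return ranked


@dataclass
class CascadeNetwork:
    """Layered DAG from a seed TF through primary to secondary target-TFs.

    Nodes carry ``layer`` (0 = seed, 1 = primary, 2 = secondary), the
    expression log2FC and relative expression; non-TF bound genes are
    attached as leaves (``is_leaf=True``) for enrichment but never expanded.
    Every edge points one layer down and every edge target is upregulated.
    """

    seed: str
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def tf_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d.get("is_leaf", False)]

    @property
    def leaf_genes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("is_leaf", False)]

    def layer(self, node: str) -> int | None:
        return self.graph.nodes[node].get("layer")

    def node_genes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "site_chrom": d["site_chrom"],
                "site_start": d["site_start"],
                "site_end": d["site_end"],
                "peak_id": d["peak_id"],
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "site_chrom", "site_start", "site_end", "peak_id"])

    def write_graphml(self, path: str) -> None:
        g = self.graph.copy()
        for _, d in g.nodes(data=True):
            for k, v in list(d.items()):
                if v is None:
                    d[k] = ""
        nx.write_graphml(g, path)

    def write_sif(self, path: str) -> None:
        with open(path, "w") as fh:
            for u, v in self.graph.edges:
                fh.write(f"{u}\tbinds\t{v}\n")


def build_cascade_network(
    seed_tf: str,
    bound_table: pd.DataFrame,
    gene_results: pd.DataFrame,
    tf_universe: set[str] | list[str],
    tpm: pd.DataFrame | None = None,
    layers: int = 2,
) -> CascadeNetwork:
    """Expand the seed TF into its two-layer cascade of upregulated targets.

    Layer 1 holds TF genes bound by the seed with expression log2FC > 0;
    layer 2 holds TF genes bound by any layer-1 TF with log2FC > 0, excluding
    the seed and anything already placed (shallowest layer wins, which keeps
    the graph a DAG). Upregulated non-TF bound genes attach as leaves.
    """
    tf_universe = set(tf_universe)
    if seed_tf not in tf_universe:
        raise ValueError(f"seed TF {seed_tf!r} not in the TF universe")
    genes = gene_results.set_index("feature_id")
    lfc = genes["log2fc"]
    tpm_mean = tpm.mean(axis=1) if tpm is not None else pd.Series(dtype=float)
    if seed_tf not in lfc.index:
        logger.warning("seed TF %s absent from expression results; network built from binding only", seed_tf)

    net = CascadeNetwork(seed=seed_tf)

    def add_node(node: str, layer: int | None, is_leaf: bool = False) -> None:
        net.graph.add_node(
            node,
            layer=layer,
            log2fc=float(lfc.get(node, np.nan)),
            relative_expression=float(tpm_mean.get(node, np.nan)),
            is_leaf=is_leaf,
        )

    def evidence_for(tf: str, gene: str) -> pd.Series:
        ev = bound_table[(bound_table["tf_id"] == tf) & (bound_table["gene_id"] == gene)]
        return ev.sort_values(["site_chrom", "site_start", "peak_id"]).iloc[0]

    def add_edge(tf: str, gene: str) -> None:
        ev = evidence_for(tf, gene)
        net.graph.add_edge(
            tf,
            gene,
            site_chrom=ev["site_chrom"],
            site_start=int(ev["site_start"]),
            site_end=int(ev["site_end"]),
            peak_id=ev["peak_id"],
        )

    add_node(seed_tf, layer=0)
    frontier = [seed_tf]
    placed = {seed_tf}
    for depth in range(1, layers + 1):
        next_frontier = []
        for tf in frontier:
            targets = sorted(bound_table.loc[bound_table["tf_id"] == tf, "gene_id"].unique())
            for gene in targets:
                if gene == seed_tf or lfc.get(gene, 0.0) <= 0 or not np.isfinite(lfc.get(gene, np.nan)):
                    continue
                if gene in tf_universe:
                    if gene in placed:
                        # shallowest-layer placement: no edge into an
                        # equal-or-shallower layer, keeps the DAG layered
                        if net.layer(gene) == depth:
                            add_edge(tf, gene)
                        continue
                    add_node(gene, layer=depth)
                    add_edge(tf, gene)
                    placed.add(gene)
                    next_frontier.append(gene)
                else:
                    if gene not in placed:
                        add_node(gene, layer=None, is_leaf=True)
                        placed.add(gene)
                        add_edge(tf, gene)
        frontier = next_frontier
    return net


def mirna_network_overlay(
    network: CascadeNetwork, target_map: pd.DataFrame, mirna_results: pd.DataFrame
) -> pd.DataFrame:
    """Differentially expressed miRNAs whose filtered targets hit network
    node genes; downregulated miRNAs are candidate de-repressors of the
    upregulated cascade."""
    labels = mirna_results.set_index("feature_id")["label"]
    node_set = set(network.node_genes())
    rows = []
    for mirna_id, sub in target_map.groupby("mirna_id", sort=True):
        label = labels.get(mirna_id, "ns")
        if label not in ("up", "down"):
            continue
        hit = sorted(set(sub["gene_id"]) & node_set)
        if not hit:
            continue
        rows.append(
            {
                "mirna_id": mirna_id,
                "mirna_label": label,
                "target_nodes": ",".join(hit),
                "n_target_nodes": len(hit),
                "candidate_derepressor": label == "down",
            }
        )
    return pd.DataFrame(
        rows, columns=["mirna_id", "mirna_label", "target_nodes", "n_target_nodes", "candidate_derepressor"]
    )
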
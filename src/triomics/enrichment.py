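"""Hypergeometric over-representation of gene lists against GMT collections.

For a universe of M genes, a term with K members in the universe and a query
of N genes overlapping the term in k, the raw p-value is the upper tail
P(X >= k) of Hypergeometric(M, K, N). Raw p < 0.05 marks significance;
Benjamini-Hochberg adjusted values are reported alongside.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SIGNIFICANCE_P = 0.05


def hypergeometric_enrichment(
    query: set[str] | list[str],
    universe: set[str] | list[str],
    gmt: dict[str, set[str]],
    significance_p: float = SIGNIFICANCE_P,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per GMT term.

    Term membership is intersected with the universe before testing; the
    query must be a subset of the universe.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")

    rows = []
    for term, members in gmt.items():
        in_universe = members & universe
        overlap = sorted(in_universe & query)
        k, big_m, big_k, n = len(overlap), len(universe), len(in_universe), len(query)
        p = float(stats.hypergeom.sf(k - 1, big_m, big_k, n)) if big_k > 0 else 1.0
        rows.append(
            {
                "term_id": term,
                "term_size": big_k,
                "overlap_size": k,
                "pvalue": min(p, 1.0),
                "gene_ids": ",".join(overlap),
            }
        )
    out = pd.DataFrame(rows, columns=["term_id", "term_size", "overlap_size", "pvalue", "gene_ids"])
    if len(out):
        out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
        out["significant"] = out["pvalue"] < significance_p
        out = out.sort_values(["pvalue", "term_id"], ignore_index=True)
    else:
        out["padj"] = []
        out["significant"] = []
    return out[["term_id", "term_size", "overlap_size", "pvalue", "padj", "significant", "gene_ids"]]
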
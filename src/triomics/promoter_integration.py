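"""Proximal regulation: element-wise peak/expression correlation, major-peak
selection, and the cross-classification of gene DE labels against promoter
peak directions."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _group_means(table: pd.DataFrame, group_labels: pd.Series | dict[str, str]) -> pd.DataFrame:
    if isinstance(group_labels, dict):
        group_labels = pd.Series(group_labels)
    group_labels = group_labels.reindex(table.columns)
    if group_labels.isna().any():
        raise ValueError("every sample column needs a group label")
    return table.T.groupby(group_labels).mean().T


def element_correlation(
    annotated_peaks: pd.DataFrame,
    peak_cpm: pd.DataFrame,
    gene_tpm: pd.DataFrame,
    peak_groups: pd.Series | dict[str, str],
    gene_groups: pd.Series | dict[str, str],
    min_pairs: int = 3,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Pearson correlation between peak accessibility and nearby-gene
    expression, per element class.

    Each peak pairs with its nearest gene. Group means of log2(CPM + 1) and
    log2(TPM + 1) are averaged across the two groups to give one point per
    pair, so unequal replicate numbers between conditions do not bias the
    estimate (and a global between-condition shift cannot masquerade as a
    peak/gene correlation). Classes with fewer than ``min_pairs`` pairs, or
    with zero variance on either axis, report r as NaN (not computable,
    never 0).
    """
    peak_val = np.log2(_group_means(peak_cpm, peak_groups) + pseudocount).mean(axis=1)
    gene_val = np.log2(_group_means(gene_tpm, gene_groups) + pseudocount).mean(axis=1)
    rows = []
    for element, sub in annotated_peaks.groupby("element_class", sort=True):
        sub = sub.dropna(subset=["nearest_gene"])
        pairs = [
            (p, g)
            for p, g in zip(sub["peak_id"], sub["nearest_gene"])
            if p in peak_val.index and g in gene_val.index
        ]
        n_pairs = len(pairs)
        if n_pairs < min_pairs:
            rows.append((element, np.nan, np.nan, n_pairs))
            continue
        x = np.array([peak_val[p] for p, _ in pairs])
        y = np.array([gene_val[g] for _, g in pairs])
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((element, np.nan, np.nan, n_pairs))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((element, r, p, n_pairs))
    return pd.DataFrame(rows, columns=["element_class", "r", "pvalue", "n_pairs"])


def select_major_peak(
    peak_ids: list[str], peak_results: pd.DataFrame, peak_starts: pd.Series
) -> str | None:
    """The major promoter peak: maximum |log2FC|, ties broken by smaller
    adjusted p, then leftmost start. None when the gene has no promoter peak."""
    if not peak_ids:
        return None
    res = peak_results.set_index("feature_id") if "feature_id" in peak_results.columns else peak_results

    def key(pid: str):
        return (-abs(res.at[pid, "log2fc"]), res.at[pid, "padj"], peak_starts[pid], pid)

    return min(peak_ids, key=key)


def classify_promoter_genes(
    assignments: pd.DataFrame,
    gene_results: pd.DataFrame,
    peak_results: pd.DataFrame,
    peak_starts: pd.Series,
) -> pd.DataFrame:
    """Per-gene promoter summary: DE label x promoter-peak direction.

    Direction summary over a gene's promoter peaks (using the differential
    peak labels; non-significant peaks are neutral):

    * ``none`` — no promoter peak;
    * ``single_increased`` / ``single_decreased`` / ``single_ns`` — one peak;
    * ``all_increased`` / ``all_decreased`` — multiple peaks, at least one
      significant, all significant ones in the same direction;
    * ``mixed`` — both directions present (the major peak resolves these);
    * ``ns_only`` — multiple peaks, none significant.

    Every gene in ``gene_results`` must appear in ``assignments``; a missing
    gene is a universe mismatch and raises.
    """
    peak_res = peak_results.set_index("feature_id")
    gene_labels = gene_results.set_index("feature_id")["label"]
    assigned = assignments.set_index("gene_id")
    missing = gene_labels.index.difference(assigned.index)
    if len(missing) > 0:
        raise ValueError(f"genes absent from promoter assignments: {list(missing[:5])}")

    rows = []
    for gene_id, de_label in gene_labels.items():
        peak_ids = list(assigned.at[gene_id, "peak_ids"])
        n_peak = len(peak_ids)
        major = select_major_peak(peak_ids, peak_results, peak_starts)
        major_dir = peak_res.at[major, "label"] if major is not None else None
        labels = [peak_res.at[p, "label"] for p in peak_ids]
        n_inc = labels.count("increased")
        n_dec = labels.count("decreased")
        if n_peak == 0:
            summary = "none"
        elif n_peak == 1:
            summary = {"increased": "single_increased", "decreased": "single_decreased"}.get(
                labels[0], "single_ns"
            )
        elif n_inc > 0 and n_dec > 0:
            summary = "mixed"
        elif n_inc > 0:
            summary = "all_increased"
        elif n_dec > 0:
            summary = "all_decreased"
        else:
            summary = "ns_only"
        if summary == "none":
            category = f"no_peak:{de_label}"
        elif n_peak == 1:
            category = f"single:{de_label}:{labels[0]}"
        elif summary == "mixed":
            category = f"multi:{de_label}:mixed_major_{major_dir}"
        else:
            category = f"multi:{de_label}:{summary}"
        rows.append((gene_id, de_label, n_peak, summary, major, major_dir, category))
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "de_label",
            "n_peak",
            "peak_direction_summary",
            "major_peak_id",
            "major_peak_direction",
            "category",
        ],
    )


def cross_classify(gene_classes: pd.DataFrame) -> pd.Series:
    """Contingency of cross-classification categories over genes with at
    least one promoter peak. Cells are disjoint and exhaustive: counts sum to
    the number of genes with n_peak >= 1."""
    with_peak = gene_classes[gene_classes["n_peak"] >= 1]
    return with_peak["category"].value_counts().sort_index()


def n_peak_histogram(gene_classes: pd.DataFrame, max_bin: int = 5) -> pd.Series:
    """How many genes carry 0, 1, 2, ... promoter peaks (last bin pooled)."""
    binned = gene_classes["n_peak"].clip(upper=max_bin)
    hist = binned.value_counts().sort_index()
    hist.index = [f"{i}+" if i == max_bin else str(i) for i in hist.index]
    return hist
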
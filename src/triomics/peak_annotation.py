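"""Genomic-element classification of ATAC peaks and promoter-peak linking.

A peak belongs to exactly one element class, decided by the membership of its
midpoint with the precedence

    promoter > 5'UTR > 3'UTR > exon > intron > downstream > distal_intergenic

where the promoter window is TSS +/- ``promoter_bp`` (3 kb default) and the
downstream window extends ``downstream_bp`` past the gene 3' end. Midpoint
membership (rather than any-overlap) makes the class a total function of the
peak, so the per-class percentages partition the peak set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import GeneAnnotationSet, PeakSet

logger = logging.getLogger(__name__)

ELEMENT_CLASSES = [
    "promoter",
    "five_prime_utr",
    "three_prime_utr",
    "exon",
    "intron",
    "downstream",
    "distal_intergenic",
]

#: midpoint-membership precedence, highest first
_PRECEDENCE = ["promoter", "five_prime_utr", "three_prime_utr", "exon", "intron", "downstream"]


def promoter_window(tss: int, promoter_bp: int = 3000) -> tuple[int, int]:
    """The promoter interval [tss - promoter_bp, tss + promoter_bp), clipped at 0."""
    return max(0, tss - promoter_bp), tss + promoter_bp


class FeatureIndex:
    """Interval indices over promoters, UTRs, exons, gene bodies and
    downstream windows, plus sorted TSS arrays for nearest-gene queries."""

    def __init__(
        self,
        annotation: GeneAnnotationSet,
        promoter_bp: int = 3000,
        downstream_bp: int = 3000,
    ):
        if len(annotation) == 0:
            raise ValueError("cannot index an empty annotation")
        self.annotation = annotation
        self.promoter_bp = promoter_bp
        self.downstream_bp = downstream_bp
        self._trees: dict[str, dict[str, IntervalTree]] = {
            cls: {} for cls in ("promoter", "five_prime_utr", "three_prime_utr", "exon", "intron", "downstream")
        }
        tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
        for g in annotation:
            lo, hi = promoter_window(g.tss, promoter_bp)
            self._add("promoter", g.chrom, lo, hi, g.gene_id)
            for s, e in g.five_prime_utrs:
                self._add("five_prime_utr", g.chrom, s, e, g.gene_id)
            for s, e in g.three_prime_utrs:
                self._add("three_prime_utr", g.chrom, s, e, g.gene_id)
            for s, e in g.exons:
                self._add("exon", g.chrom, s, e, g.gene_id)
            # the gene body stands in for introns; exon precedence peels them off
            self._add("intron", g.chrom, g.start, g.end, g.gene_id)
            if g.strand == "+":
                self._add("downstream", g.chrom, g.end, g.end + downstream_bp, g.gene_id)
            else:
                self._add("downstream", g.chrom, max(0, g.start - downstream_bp), g.start, g.gene_id)
            tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
        self._tss: dict[str, tuple[np.ndarray, list[str]]] = {}
        for chrom, pairs in tss_by_chrom.items():
            pairs.sort()
            self._tss[chrom] = (np.array([p for p, _ in pairs]), [g for _, g in pairs])

    def _add(self, cls: str, chrom: str, start: int, end: int, gene_id: str) -> None:
        if end <= start:
            return
        self._trees[cls].setdefault(chrom, IntervalTree()).addi(start, end, gene_id)

    def classes_at(self, chrom: str, pos: int) -> dict[str, list[str]]:
        """All element classes whose intervals contain ``pos``, with member genes."""
        hits: dict[str, list[str]] = {}
        for cls, by_chrom in self._trees.items():
            tree = by_chrom.get(chrom)
            if tree is None:
                continue
            genes = sorted(iv.data for iv in tree.at(pos))
            if genes:
                hits[cls] = genes
        return hits

    def nearest_gene(self, chrom: str, pos: int) -> str | None:
        """Gene with minimum |pos - TSS| on the chromosome (ties: smaller gene id)."""
        if chrom not in self._tss:
            return None
        positions, gene_ids = self._tss[chrom]
        i = int(np.searchsorted(positions, pos))
        candidates = []
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(positions):
                candidates.append((abs(pos - int(positions[j])), gene_ids[j]))
        return min(candidates)[1]

    def promoter_genes_at(self, chrom: str, pos: int) -> list[str]:
        tree = self._trees["promoter"].get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(pos))


def build_feature_index(
    annotation: GeneAnnotationSet, promoter_bp: int = 3000, downstream_bp: int = 3000
) -> FeatureIndex:
    return FeatureIndex(annotation, promoter_bp=promoter_bp, downstream_bp=downstream_bp)


def _signed_tss_distance(midpoint: int, gene) -> int:
    """Signed distance in gene orientation: negative = upstream of the TSS."""
    d = midpoint - gene.tss
    return d if gene.strand == "+" else -d


def annotate_peaks(peaks: PeakSet, index: FeatureIndex) -> pd.DataFrame:
    """Assign each peak its element class and nearest gene.

    Returns a table with peak_id, chrom, midpoint, element_class,
    nearest_gene and the signed distance from the peak midpoint to the
    nearest gene's TSS (negative = upstream in that gene's orientation).
    Peaks on chromosomes absent from the annotation become
    distal_intergenic with no nearest gene.
    """
    rows = []
    mids = peaks.midpoints()
    for row in peaks.intervals.itertuples(index=False):
        mid = int(mids[row.peak_id])
        nearest = index.nearest_gene(row.chrom, mid)
        if nearest is None:
            logger.warning("peak %s on chromosome %r absent from annotation", row.peak_id, row.chrom)
            rows.append((row.peak_id, row.chrom, mid, "distal_intergenic", None, np.nan))
            continue
        hits = index.classes_at(row.chrom, mid)
        element = next((cls for cls in _PRECEDENCE if cls in hits), "distal_intergenic")
        dist = _signed_tss_distance(mid, index.annotation[nearest])
        rows.append((row.peak_id, row.chrom, mid, element, nearest, dist))
    return pd.DataFrame(
        rows, columns=["peak_id", "chrom", "midpoint", "element_class", "nearest_gene", "distance_to_tss"]
    )


def annotation_summary(annotated_peaks: pd.DataFrame, pool_utrs: bool = False) -> pd.Series:
    """Percentage of peaks per element class (sums to 100).

    ``pool_utrs`` merges the 5'/3' UTR classes into a single 'utr' figure for
    reporting; the underlying classes stay split.
    """
    if len(annotated_peaks) == 0:
        raise ValueError("cannot summarize an empty peak set")
    counts = annotated_peaks["element_class"].value_counts()
    pct = counts / counts.sum() * 100.0
    if pool_utrs:
        utr = pct.get("five_prime_utr", 0.0) + pct.get("three_prime_utr", 0.0)
        pct = pct.drop(index=[c for c in ("five_prime_utr", "three_prime_utr") if c in pct.index])
        pct["utr"] = utr
    return pct.reindex([c for c in ELEMENT_CLASSES + ["utr"] if c in pct.index])


def assign_promoter_peaks(
    annotated_peaks: pd.DataFrame, index: FeatureIndex
) -> pd.DataFrame:
    """Per-gene promoter-peak assignment covering ALL genes (n_peak may be 0).

    A peak belongs to a gene's promoter iff its midpoint lies in the gene's
    TSS +/- promoter_bp window; a peak inside overlapping windows is assigned
    to every such gene. Returns gene_id, peak_ids (list) and n_peak.
    """
    per_gene: dict[str, list[str]] = {gid: [] for gid in index.annotation.gene_ids}
    for row in annotated_peaks.itertuples(index=False):
        for gid in index.promoter_genes_at(row.chrom, int(row.midpoint)):
            per_gene[gid].append(row.peak_id)
    return pd.DataFrame(
        {
            "gene_id": list(per_gene),
            "peak_ids": [per_gene[g] for g in per_gene],
            "n_peak": [len(per_gene[g]) for g in per_gene],
        }
    )
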
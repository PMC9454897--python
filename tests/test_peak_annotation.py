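"""Element classification, promoter windows and peak-to-gene assignment,
checked against brute-force interval scans."""

import numpy as np
import pandas as pd
import pytest

from triomics import peak_annotation as pa
from triomics.models import PeakSet

PRECEDENCE = ["promoter", "five_prime_utr", "three_prime_utr", "exon", "intron", "downstream"]


def brute_force_class(chrom, mid, genes, promoter_bp=3000, downstream_bp=3000):
    hits = set()
    for g in genes:
        if g.chrom != chrom:
            continue
        lo, hi = max(0, g.tss - promoter_bp), g.tss + promoter_bp
        if lo <= mid < hi:
            hits.add("promoter")
        for s, e in g.five_prime_utrs:
            if s <= mid < e:
                hits.add("five_prime_utr")
        for s, e in g.three_prime_utrs:
            if s <= mid < e:
                hits.add("three_prime_utr")
        for s, e in g.exons:
            if s <= mid < e:
                hits.add("exon")
        if g.start <= mid < g.end:
            hits.add("intron")  # gene body; exon precedence peels exons off
        if g.strand == "+":
            if g.end <= mid < g.end + downstream_bp:
                hits.add("downstream")
        elif max(0, g.start - downstream_bp) <= mid < g.start:
            hits.add("downstream")
    for cls in PRECEDENCE:
        if cls in hits:
            return cls
    return "distal_intergenic"


def peakset_from_midpoints(pairs):
    rows, counts = [], {}
    for i, (chrom, mid) in enumerate(pairs):
        pid = f"pk{i}"
        rows.append({"peak_id": pid, "chrom": chrom, "start": mid - 50, "end": mid + 50})
        counts[pid] = [1, 1]
    return PeakSet(
        intervals=pd.DataFrame(rows),
        counts=pd.DataFrame.from_dict(counts, orient="index", columns=["s1", "s2"]),
    )


class TestPromoterWindow:
    def test_plus_strand_clipped_at_zero(self):
        assert pa.promoter_window(1000) == (0, 4000)

    def test_minus_strand_window(self):
        # gene [1000, 2000) on '-': tss = 1999, window clipped at 0
        assert pa.promoter_window(1999) == (0, 4999)

    def test_interior_window(self):
        assert pa.promoter_window(10_000) == (7000, 13_000)


class TestAnnotatePeaks:
    def test_midpoint_upstream_of_tss_is_promoter(self, toy_annotation):
        index = pa.build_feature_index(toy_annotation)
        peaks = peakset_from_midpoints([("chr1", 9_500)])  # 500 bp upstream of gA TSS
        out = pa.annotate_peaks(peaks, index)
        assert out.at[0, "element_class"] == "promoter"
        assert out.at[0, "nearest_gene"] == "gA"
        assert out.at[0, "distance_to_tss"] == -500

    def test_promoter_takes_precedence_over_neighbor_intron(self, conftest_genes=None):
        from conftest import make_gene
        from triomics.models import GeneAnnotationSet

        # gB's promoter window [27000, 33000) reaches into gA's intron
        ann = GeneAnnotationSet(
            [
                make_gene("gA", "chr1", "+", 20_000, 29_000,
                          exons=[(20_000, 20_500), (28_500, 29_000)]),
                make_gene("gB", "chr1", "+", 30_000, 33_000),
            ]
        )
        index = pa.build_feature_index(ann)
        out = pa.annotate_peaks(peakset_from_midpoints([("chr1", 28_000)]), index)
        assert out.at[0, "element_class"] == "promoter"

    def test_unknown_chromosome_is_distal_with_no_gene(self, toy_annotation):
        index = pa.build_feature_index(toy_annotation)
        out = pa.annotate_peaks(peakset_from_midpoints([("chrUn", 1000)]), index)
        assert out.at[0, "element_class"] == "distal_intergenic"
        assert out.at[0, "nearest_gene"] is None

    def test_classes_match_brute_force_on_random_peaks(self, dataset):
        genes = list(dataset.annotation)
        index = pa.build_feature_index(dataset.annotation)
        rng = np.random.default_rng(13)
        pairs = [
            (f"chr{rng.integers(1, 3)}", int(rng.integers(0, 2_000_000)))
            for _ in range(300)
        ]
        out = pa.annotate_peaks(peakset_from_midpoints(pairs), index)
        for (chrom, mid), row in zip(pairs, out.itertuples(index=False)):
            assert row.element_class == brute_force_class(chrom, mid, genes)

    def test_nearest_gene_matches_brute_force(self, dataset):
        genes = list(dataset.annotation)
        index = pa.build_feature_index(dataset.annotation)
        rng = np.random.default_rng(14)
        for _ in range(100):
            chrom = f"chr{rng.integers(1, 3)}"
            pos = int(rng.integers(0, 2_000_000))
            best = min(
                ((abs(pos - g.tss), g.gene_id) for g in genes if g.chrom == chrom)
            )[1]
            assert index.nearest_gene(chrom, pos) == best

    def test_every_peak_gets_exactly_one_class(self, result):
        assert result.annotated_peaks["element_class"].notna().all()
        assert set(result.annotated_peaks["element_class"]) <= set(pa.ELEMENT_CLASSES)


class TestSummary:
    def test_single_class_is_hundred_percent(self):
        df = pd.DataFrame({"element_class": ["promoter"] * 7})
        summary = pa.annotation_summary(df)
        assert summary["promoter"] == pytest.approx(100.0)

    def test_empty_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            pa.annotation_summary(pd.DataFrame({"element_class": []}))

    def test_percentages_sum_to_hundred(self, result):
        assert result.annotation_summary.sum() == pytest.approx(100.0, abs=1e-9)
        pooled = pa.annotation_summary(result.annotated_peaks, pool_utrs=True)
        assert pooled.sum() == pytest.approx(100.0, abs=1e-9)

    def test_planted_promoter_distal_split_recovered(self, dataset, result):
        """The generator concentrates peaks at promoters; the annotation
        stage sees that concentration."""
        summary = result.annotation_summary
        assert summary["promoter"] > summary.get("distal_intergenic", 0.0)


class TestPromoterAssignment:
    def test_counts_match_brute_force_double_loop(self, dataset, result):
        genes = list(dataset.annotation)
        mids = dataset.peaks.midpoints()
        chroms = dataset.peaks.intervals.set_index("peak_id")["chrom"]
        expected = {}
        for g in genes:
            lo, hi = pa.promoter_window(g.tss)
            expected[g.gene_id] = sorted(
                pid for pid in mids.index
                if chroms[pid] == g.chrom and lo <= int(mids[pid]) < hi
            )
        table = result.assignments.set_index("gene_id")
        assert set(table.index) == set(expected)
        for gid, peaks in expected.items():
            assert sorted(table.at[gid, "peak_ids"]) == peaks
            assert table.at[gid, "n_peak"] == len(peaks)

    def test_peak_in_overlapping_windows_assigned_to_both(self):
        from conftest import make_gene
        from triomics.models import GeneAnnotationSet

        ann = GeneAnnotationSet(
            [
                make_gene("gA", "chr1", "+", 10_000, 12_000),
                make_gene("gB", "chr1", "+", 13_000, 15_000),
            ]
        )
        index = pa.build_feature_index(ann)
        peaks = peakset_from_midpoints([("chr1", 11_500)])  # inside both windows
        out = pa.annotate_peaks(peaks, index)
        assigned = pa.assign_promoter_peaks(out, index)
        assert assigned.set_index("gene_id")["n_peak"].to_dict() == {"gA": 1, "gB": 1}

    def test_widening_promoter_never_decreases_n_peak(self, dataset):
        narrow = pa.build_feature_index(dataset.annotation, promoter_bp=3000)
        wide = pa.build_feature_index(dataset.annotation, promoter_bp=5000)
        a_narrow = pa.assign_promoter_peaks(
            pa.annotate_peaks(dataset.peaks, narrow), narrow
        ).set_index("gene_id")["n_peak"]
        a_wide = pa.assign_promoter_peaks(
            pa.annotate_peaks(dataset.peaks, wide), wide
        ).set_index("gene_id")["n_peak"]
        assert (a_wide >= a_narrow).all()

    def test_empty_annotation_rejected(self):
        from triomics.models import GeneAnnotationSet

        with pytest.raises(ValueError, match="empty"):
            pa.build_feature_index(GeneAnnotationSet())
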
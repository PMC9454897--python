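#!/usr/bin/env python
"""Differential analysis of the three omics layers at their published
thresholds: genes (|log2FC| > 1, Padj < 0.01), miRNAs (|log2FC| > 1, raw
p < 0.05), peaks (|log2FC| > 1.5, Padj < 0.05)."""

from triomics import differential as de
from triomics import genome_io

from common import OUT_DIR, load_inputs


def main() -> None:
    inputs = load_inputs()
    groups = inputs["sample_groups"]

    genes = de.classify_genes(
        de.test_differential(inputs["gene_counts"], groups),
        expressed=de.is_expressed(inputs["gene_counts"]),
    )
    mirnas = de.classify_mirnas(
        de.test_differential(inputs["mirna_counts"], groups),
        expressed=de.is_expressed(inputs["mirna_counts"]),
    )
    peaks = de.classify_peaks(de.test_differential(inputs["peaks"].counts, groups))

    genome_io.write_differential(genes, OUT_DIR / "gene_differential.tsv")
    genome_io.write_differential(mirnas, OUT_DIR / "mirna_differential.tsv")
    genome_io.write_differential(peaks, OUT_DIR / "peak_differential.tsv")

    for name, table in [("genes", genes), ("miRNAs", mirnas), ("peaks", peaks)]:
        print(f"{name}: {table['label'].value_counts().to_dict()}")
    cpm = de.normalize_cpm(inputs["peaks"].counts)
    high = de.flag_highly_accessible(cpm, groups)
    print(f"highly accessible peaks (log2 group-mean CPM > 5): {int(high.sum())} of {len(high)}")


if __name__ == "__main__":
    main()
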
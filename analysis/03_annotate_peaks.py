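#!/usr/bin/env python
"""Genomic-element annotation of the ATAC peaks (midpoint membership with
promoter > UTR > exon > intron > downstream precedence; promoter = TSS
+/- 3 kb) and the per-gene promoter-peak census."""

from triomics import peak_annotation as pa

from common import OUT_DIR, load_inputs


def main() -> None:
    inputs = load_inputs()
    index = pa.build_feature_index(inputs["annotation"])
    annotated = pa.annotate_peaks(inputs["peaks"], index)
    annotated.to_csv(OUT_DIR / "peak_annotation.tsv", sep="\t", index=False)

    summary = pa.annotation_summary(annotated, pool_utrs=True)
    summary.rename("percent").to_csv(OUT_DIR / "annotation_summary.tsv", sep="\t",
                                     index_label="element_class")
    print("peak distribution across genomic elements (%):")
    print(summary.round(2).to_string())

    assigned = pa.assign_promoter_peaks(annotated, index)
    assigned.assign(peak_ids=assigned["peak_ids"].map(",".join)).to_csv(
        OUT_DIR / "promoter_assignments.tsv", sep="\t", index=False
    )
    census = assigned["n_peak"].clip(upper=2).value_counts().sort_index()
    print(f"promoter-peak census: {census.get(0, 0)} genes with no peak, "
          f"{census.get(1, 0)} with a single peak, {census.get(2, 0)} with multiple peaks")


if __name__ == "__main__":
    main()
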
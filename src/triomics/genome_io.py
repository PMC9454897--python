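"""Readers and writers for the standard formats the pipeline touches.

Conventions
-----------
* Internal coordinates are 0-based half-open everywhere.
* GTF is 1-based inclusive and is converted at this boundary; BED, narrowPeak
  and all interval TSVs pass through unchanged.
* Count matrices are feature x sample TSVs with the feature id in the first
  column; duplicate ids and missing values are errors, never silently fixed.
"""

from __future__ import annotations

import logging

import pandas as pd
from gffutils.feature import feature_from_line

from .models import (
    DIFFERENTIAL_COLUMNS,
    FOOTPRINT_COLUMNS,
    TARGET_RECORD_COLUMNS,
    GeneAnnotationSet,
    GeneModel,
    PeakSet,
)

logger = logging.getLogger(__name__)

_NARROWPEAK_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "signalValue",
    "pValue",
    "qValue",
    "peak",
]

_BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

# DESeq2 result tables are accepted as-is on read.
_DESEQ2_ALIASES = {
    "baseMean": "base_mean",
    "log2FoldChange": "log2fc",
    "pvalue": "pvalue",
    "padj": "padj",
}


def read_gtf(path: str, tf_list: list[str] | set[str] | None = None) -> GeneAnnotationSet:
    """Parse a GTF into a :class:`GeneAnnotationSet`.

    1-based inclusive GTF coordinates become 0-based half-open. Genes whose
    record carries strand ``.`` are skipped with a warning; any malformed
    line raises with its line number. ``tf_list`` marks genes as
    transcription factors (the analysis is agnostic to where the list comes
    from; a motif-database gene list is typical).
    """
    tf_set = set(tf_list or [])
    genes: dict[str, GeneModel] = {}
    sub_features: list[tuple[str, str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises several types
                raise ValueError(f"{path}: malformed GTF line {lineno}: {exc}") from exc
            try:
                gene_id = feat.attributes["gene_id"][0]
            except KeyError as exc:
                raise ValueError(f"{path}: line {lineno} lacks a gene_id attribute") from exc
            start, end = feat.start - 1, feat.end  # to 0-based half-open
            if feat.featuretype == "gene":
                if feat.strand not in ("+", "-"):
                    logger.warning("skipping gene %s with strand %r (line %d)", gene_id, feat.strand, lineno)
                    continue
                if gene_id in genes:
                    raise ValueError(f"{path}: duplicate gene record for {gene_id!r} at line {lineno}")
                genes[gene_id] = GeneModel(
                    gene_id=gene_id,
                    chrom=feat.seqid,
                    strand=feat.strand,
                    start=start,
                    end=end,
                    is_tf=gene_id in tf_set,
                )
            elif feat.featuretype in ("exon", "five_prime_utr", "three_prime_utr"):
                sub_features.append((gene_id, feat.featuretype, start, end))
    for gene_id, kind, start, end in sub_features:
        if gene_id not in genes:
            raise ValueError(f"{path}: {kind} refers to unknown gene {gene_id!r}")
        gene = genes[gene_id]
        if kind == "exon":
            gene.exons.append((start, end))
        elif kind == "five_prime_utr":
            gene.five_prime_utrs.append((start, end))
        else:
            gene.three_prime_utrs.append((start, end))
    return GeneAnnotationSet(list(genes.values()))


def write_gtf(annotation: GeneAnnotationSet, path: str, source: str = "triomics") -> None:
    """Write gene/exon/UTR records as GTF (converting back to 1-based inclusive)."""

    def line(g: GeneModel, kind: str, start: int, end: int) -> str:
        attrs = f'gene_id "{g.gene_id}";'
        return "\t".join(
            [g.chrom, source, kind, str(start + 1), str(end), ".", g.strand, ".", attrs]
        )

    with open(path, "w") as fh:
        for g in annotation:
            fh.write(line(g, "gene", g.start, g.end) + "\n")
            for lo, hi in g.exons:
                fh.write(line(g, "exon", lo, hi) + "\n")
            for lo, hi in g.five_prime_utrs:
                fh.write(line(g, "five_prime_utr", lo, hi) + "\n")
            for lo, hi in g.three_prime_utrs:
                fh.write(line(g, "three_prime_utr", lo, hi) + "\n")


def read_counts(path: str) -> pd.DataFrame:
    """Read a feature x sample raw count matrix from TSV."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    if table.isna().any().any():
        raise ValueError(f"{path}: missing values in count matrix")
    if table.shape[1] == 0:
        raise ValueError(f"{path}: count matrix has no sample columns")
    return table


def write_counts(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index_label="feature_id")


def read_narrowpeak(path: str, counts_path: str) -> PeakSet:
    """Read a 10-column narrowPeak plus its per-sample raw count TSV.

    Peak ids come from the narrowPeak ``name`` field and must match the
    count-matrix index exactly; a dimension mismatch is an error.
    """
    intervals = pd.read_csv(path, sep="\t", header=None, names=_NARROWPEAK_COLUMNS)
    intervals = intervals.rename(columns={"name": "peak_id"})
    counts = read_counts(counts_path)
    return PeakSet(intervals=intervals[["peak_id", "chrom", "start", "end"]].copy(), counts=counts)


def write_narrowpeak(peaks: PeakSet, path: str, counts_path: str | None = None) -> None:
    df = peaks.intervals
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            mid_offset = (row.end - row.start) // 2
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.peak_id}\t0\t.\t0\t-1\t-1\t{mid_offset}\n"
            )
    if counts_path is not None:
        peaks.counts.to_csv(counts_path, sep="\t", index_label="peak_id")


def read_bed6(path: str) -> pd.DataFrame:
    """Read BED6 intervals (e.g. TF binding sites with the TF id in the name field)."""
    df = pd.read_csv(path, sep="\t", header=None, names=_BED6_COLUMNS)
    if df[["chrom", "start", "end", "name"]].isna().any().any():
        raise ValueError(f"{path}: missing values in BED6 file")
    return df


def write_bed6(df: pd.DataFrame, path: str) -> None:
    out = df.copy()
    if "score" not in out.columns:
        out["score"] = 0
    if "strand" not in out.columns:
        out["strand"] = "."
    out[_BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_target_map(path: str) -> pd.DataFrame:
    """Read miRNA->gene target-prediction records from TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = set(TARGET_RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: target map missing columns {sorted(missing)}")
    if df["hybrid_pvalue"].between(0, 1).pipe(lambda s: ~s).any():
        raise ValueError(f"{path}: hybrid_pvalue outside [0, 1]")
    return df[TARGET_RECORD_COLUMNS].copy()


def write_target_map(df: pd.DataFrame, path: str) -> None:
    df[TARGET_RECORD_COLUMNS].to_csv(path, sep="\t", index=False)


def read_footprint_stats(path: str) -> pd.DataFrame:
    """Read the per-TF differential footprint statistics table.

    The schema mirrors the output of differential footprinting tools: one row
    per TF with a differential binding score and a -log10 p-value.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(FOOTPRINT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: footprint table missing columns {sorted(missing)}")
    if df["tf_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate tf_id in footprint table")
    if (df["neglog10_p"] < 0).any():
        raise ValueError(f"{path}: neglog10_p must be non-negative")
    return df[FOOTPRINT_COLUMNS].copy()


def read_gmt(path: str) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: term name, description, member genes.

    Members absent from a given analysis universe are kept here; the
    enrichment stage intersects terms with its universe at test time.
    """
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: GMT line {lineno} has fewer than 3 fields")
            name, genes = parts[0], {g for g in parts[2:] if g}
            if name in terms:
                raise ValueError(f"{path}: duplicate GMT term {name!r}")
            terms[name] = genes
    return terms


def read_differential(path: str) -> pd.DataFrame:
    """Read a differential-result table, accepting DESeq2 column names.

    Externally computed tables (e.g. from a negative-binomial GLM) can be
    dropped in here in place of the built-in stand-in test.
    """
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns=_DESEQ2_ALIASES)
    if "feature_id" not in df.columns:
        df = df.rename(columns={df.columns[0]: "feature_id"})
    missing = {"feature_id", "log2fc", "pvalue", "padj"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: differential table missing columns {sorted(missing)}")
    if "base_mean" not in df.columns:
        df["base_mean"] = float("nan")
    if "label" not in df.columns:
        df["label"] = "ns"
    return df[DIFFERENTIAL_COLUMNS].copy()


def write_differential(df: pd.DataFrame, path: str) -> None:
    df[DIFFERENTIAL_COLUMNS].to_csv(path, sep="\t", index=False)
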
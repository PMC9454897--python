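"""Core domain containers shared across the pipeline stages.

Coordinates are 0-based half-open everywhere inside the package; format
conversions happen at the I/O boundary (see :mod:`triomics.genome_io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

Interval = tuple[int, int]


@dataclass
class GeneModel:
    """A gene record with its exon/UTR structure.

    The transcription start site (TSS) is the 5' end of the gene record:
    ``start`` on the '+' strand, ``end - 1`` on the '-' strand.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[Interval] = field(default_factory=list)
    five_prime_utrs: list[Interval] = field(default_factory=list)
    three_prime_utrs: list[Interval] = field(default_factory=list)
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        for lo, hi in self.exons:
            if lo < self.start or hi > self.end:
                raise ValueError(f"gene {self.gene_id}: exon [{lo},{hi}) outside gene body")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        """Transcript length proxy: total exonic bases, or gene span if exon-less."""
        if self.exons:
            return sum(hi - lo for lo, hi in self.exons)
        return self.end - self.start


class GeneAnnotationSet:
    """An ordered collection of :class:`GeneModel` keyed by gene id."""

    def __init__(self, genes: list[GeneModel] | None = None):
        self._genes: dict[str, GeneModel] = {}
        for g in genes or []:
            self.add(g)

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self._genes:
            raise ValueError(f"duplicate gene_id {gene.gene_id!r}")
        self._genes[gene.gene_id] = gene

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self):
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    @property
    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self:
            seen.setdefault(g.chrom, None)
        return list(seen)

    def tf_ids(self) -> list[str]:
        return [g.gene_id for g in self if g.is_tf]

    def lengths(self) -> pd.Series:
        return pd.Series({g.gene_id: g.length for g in self}, name="length")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "start": g.start,
                "end": g.end,
                "tss": g.tss,
                "is_tf": g.is_tf,
            }
            for g in self
        ]
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end", "tss", "is_tf"])


@dataclass
class PeakSet:
    """ATAC peaks: interval table plus a per-sample raw count matrix.

    ``intervals`` has columns peak_id, chrom, start, end (0-based half-open);
    ``counts`` is indexed by peak_id with one column per sample.
    """

    intervals: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"peak_id", "chrom", "start", "end"}
        missing = required - set(self.intervals.columns)
        if missing:
            raise ValueError(f"peak intervals missing columns: {sorted(missing)}")
        if self.intervals["peak_id"].duplicated().any():
            dup = self.intervals.loc[self.intervals["peak_id"].duplicated(), "peak_id"].iloc[0]
            raise ValueError(f"duplicate peak_id {dup!r}")
        ids = set(self.intervals["peak_id"])
        if ids != set(self.counts.index):
            raise ValueError(
                "dimension mismatch between peak intervals "
                f"({len(ids)}) and counts ({len(self.counts)})"
            )
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("peak counts must be non-negative")

    def __len__(self) -> int:
        return len(self.intervals)

    def midpoints(self) -> pd.Series:
        mid = (self.intervals["start"] + self.intervals["end"]) // 2
        return pd.Series(mid.to_numpy(), index=self.intervals["peak_id"], name="midpoint")


# Column contracts for the tabular records that flow between stages.
TARGET_RECORD_COLUMNS = [
    "mirna_id",
    "gene_id",
    "miranda_score",
    "hybrid_energy",
    "hybrid_pvalue",
    "source",
]
FOOTPRINT_COLUMNS = ["tf_id", "diff_binding_score", "neglog10_p"]
DIFFERENTIAL_COLUMNS = ["feature_id", "base_mean", "log2fc", "pvalue", "padj", "label"]
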
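"""Shared I/O for the numbered analysis scripts: locate the simulated cohort
written by 01_simulate_cohort.py and load it through the package readers."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from triomics import genome_io

ROOT = Path(__file__).resolve().parents[1]
INPUT_DIR = ROOT / "results" / "analysis" / "inputs"
OUT_DIR = ROOT / "results" / "analysis"


def load_inputs():
    if not INPUT_DIR.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    annotation = genome_io.read_gtf(INPUT_DIR / "genes.gtf")
    for g in annotation:  # simulator convention: TF genes carry a TF prefix
        if g.gene_id.startswith("TF"):
            g.is_tf = True
    return {
        "annotation": annotation,
        "gene_counts": genome_io.read_counts(INPUT_DIR / "gene_counts.tsv"),
        "mirna_counts": genome_io.read_counts(INPUT_DIR / "mirna_counts.tsv"),
        "peaks": genome_io.read_narrowpeak(INPUT_DIR / "peaks.narrowPeak", INPUT_DIR / "peak_counts.tsv"),
        "binding_sites": genome_io.read_bed6(INPUT_DIR / "binding_sites.bed"),
        "footprint_stats": genome_io.read_footprint_stats(INPUT_DIR / "footprint_stats.tsv"),
        "target_records": genome_io.read_target_map(INPUT_DIR / "target_records.tsv"),
        "sample_groups": pd.read_csv(INPUT_DIR / "sample_groups.tsv", sep="\t", index_col=0)["group"],
    }
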
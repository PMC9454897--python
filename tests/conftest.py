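import numpy as np
import pandas as pd
import pytest

from triomics import SimulationConfig, run_stages, simulate_dataset
from triomics.models import GeneAnnotationSet, GeneModel


@pytest.fixture(scope="session")
def dataset():
    """One synthetic tri-omics dataset with planted truth (4v4 replicates)."""
    return simulate_dataset(SimulationConfig(seed=11, reps_per_group=(4, 4)))


@pytest.fixture(scope="session")
def result(dataset):
    """The full pipeline run on the shared dataset."""
    d = dataset
    return run_stages(
        d.annotation,
        d.gene_counts,
        d.mirna_counts,
        d.peaks,
        d.binding_sites,
        d.footprint_stats,
        d.target_records,
        d.sample_groups,
    )


def make_gene(gene_id, chrom, strand, start, end, exons=None, **kw):
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, start=start, end=end,
        exons=exons or [(start, end)], **kw,
    )


@pytest.fixture()
def toy_annotation():
    """Two genes on opposite strands plus one on a second chromosome."""
    return GeneAnnotationSet(
        [
            make_gene("gA", "chr1", "+", 10_000, 14_000,
                      exons=[(10_000, 10_500), (12_000, 14_000)],
                      five_prime_utrs=[(10_000, 10_150)],
                      three_prime_utrs=[(13_800, 14_000)]),
            make_gene("gB", "chr1", "-", 30_000, 33_000),
            make_gene("gC", "chr2", "+", 5_000, 7_000, is_tf=True),
        ]
    )


def random_counts(rng, n_features=50, n_samples=6, prefix="f"):
    table = pd.DataFrame(
        rng.integers(0, 500, size=(n_features, n_samples)),
        index=[f"{prefix}{i}" for i in range(n_features)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    table.iloc[0] += 1  # keep every column total positive
    return table
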
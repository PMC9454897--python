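"""Planted-truth recovery benchmarks.

These functions simulate datasets under the study-shaped conditions
(negative-binomial dispersion 0.05, planted |log2FC| = 2, 4v4 replicates for
the recovery benchmarks) and score how well each pipeline stage recovers
what was planted. They back the acceptance checks and the analysis scripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pipeline import PipelineParams, run_stages
from .synthetic_data import SimulationConfig, simulate_dataset
from . import differential as de


@dataclass
class ReplicateMetrics:
    seed: int
    de_recall: float
    de_false_positives: int
    promoter_r: float
    promoter_r_is_greatest: bool
    edge_precision: float
    edge_recall: float
    seed_tf_top_ranked: bool
    tension_recall: float
    promoter_peak_pct: float


def score_replicate(seed: int, reps_per_group: tuple[int, int] = (4, 4)) -> ReplicateMetrics:
    """Simulate one dataset and score every stage against its planted truth."""
    data = simulate_dataset(SimulationConfig(seed=seed, reps_per_group=reps_per_group))
    truth = data.truth
    result = run_stages(
        data.annotation,
        data.gene_counts,
        data.mirna_counts,
        data.peaks,
        data.binding_sites,
        data.footprint_stats,
        data.target_records,
        data.sample_groups,
        params=PipelineParams(),
    )

    gene_labels = result.gene_results.set_index("feature_id")["label"]
    planted_de = [g for g in data.annotation.gene_ids if truth.planted_lfc[g] != 0]
    null_expressed = [
        g for g in data.annotation.gene_ids
        if truth.planted_lfc[g] == 0 and g not in truth.unexpressed_genes
    ]
    de_recall = float(np.mean([gene_labels[g] in ("up", "down") for g in planted_de]))
    de_fp = int(sum(gene_labels[g] in ("up", "down") for g in null_expressed))

    ec = result.element_correlations.set_index("element_class")["r"]
    others = ec.drop(index="promoter").dropna()
    promoter_best = bool((ec["promoter"] > others).all()) if len(others) else True

    planted_edges = set(map(tuple, truth.cascade_edges))
    recovered = set(result.network.graph.edges) if result.network is not None else set()
    tp = len(planted_edges & recovered)
    precision = tp / len(recovered) if recovered else 0.0
    recall = tp / len(planted_edges) if planted_edges else 1.0

    seed_top = bool(len(result.key_tfs)) and result.key_tfs["tf_id"].iloc[0] == truth.seed_tf

    calls = result.tension_calls.set_index("gene_id")["call"]
    tension_recall = float(
        np.mean([calls.get(g) == "mirna_dominant" for g in truth.tension_genes])
    ) if truth.tension_genes else 1.0

    return ReplicateMetrics(
        seed=seed,
        de_recall=de_recall,
        de_false_positives=de_fp,
        promoter_r=float(ec["promoter"]),
        promoter_r_is_greatest=promoter_best,
        edge_precision=precision,
        edge_recall=recall,
        seed_tf_top_ranked=seed_top,
        tension_recall=tension_recall,
        promoter_peak_pct=float(result.annotation_summary.get("promoter", 0.0)),
    )


def recovery_replicates(n_reps: int, base_seed: int = 0) -> pd.DataFrame:
    """Score ``n_reps`` independent simulations (seeds base_seed+1 ...)."""
    rows = [score_replicate(base_seed + i + 1).__dict__ for i in range(n_reps)]
    return pd.DataFrame(rows)


def null_type_i_error(
    seed: int,
    n_features: int = 2000,
    reps_per_group: int = 4,
    dispersion: float = 0.05,
    alpha: float = 0.05,
) -> float:
    """Fraction of null NB features with p < alpha under the stand-in test.

    Features draw log-normal base means (median 100) and identical means in
    both groups; a calibrated test reports close to ``alpha``.
    """
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(np.log(100), 1.0, size=n_features))
    size = 1.0 / dispersion
    mu = np.tile(base[:, None], (1, 2 * reps_per_group))
    counts = pd.DataFrame(
        rng.negative_binomial(size, size / (size + mu)),
        index=[f"f{i}" for i in range(n_features)],
        columns=[f"A_{j}" for j in range(reps_per_group)] + [f"B_{j}" for j in range(reps_per_group)],
    )
    groups = pd.Series(
        ["A"] * reps_per_group + ["B"] * reps_per_group, index=counts.columns
    )
    res = de.test_differential(counts, groups)
    return float((res["pvalue"] < alpha).mean())
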
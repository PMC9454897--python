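"""Config-driven orchestration of the full integration pipeline.

`run_stages` is the in-memory engine (used by tests, the analysis scripts
and the acceptance checks); `run_pipeline` wraps it with file I/O, a YAML
config, stage logging and a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import differential as de
from . import enrichment as enr
from . import genome_io
from . import mirna_integration as mi
from . import peak_annotation as pa
from . import promoter_integration as pi
from . import tf_network as tfn
from .models import GeneAnnotationSet, PeakSet

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Every analysis threshold in one auditable place (defaults as
    published for each omics layer)."""

    gene_lfc_cut: float = 1.0
    gene_padj_cut: float = 0.01
    mirna_lfc_cut: float = 1.0
    mirna_p_cut: float = 0.05
    peak_lfc_cut: float = 1.5
    peak_padj_cut: float = 0.05
    promoter_bp: int = 3000
    downstream_bp: int = 3000
    log_cpm_cut: float = 5.0
    log_base: float = 2.0
    score_quantiles: tuple[float, float] = (0.05, 0.95)
    p_quantile: float = 0.95
    target_filter_mode: str = "intersection"
    seed_tf: str | None = None
    cascade_layers: int = 2


@dataclass
class PipelineConfig:
    """Paths, sample groups, thresholds, seed and output directory."""

    gtf: str
    gene_counts: str
    mirna_counts: str
    peaks: str
    peak_counts: str
    binding_sites: str
    footprint_stats: str
    target_records: str
    sample_groups: str
    outdir: str = "results"
    gmt: str | None = None
    tf_list: str | None = None
    seed: int = 0
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        params = PipelineParams(**raw.pop("params", {}))
        if isinstance(params.score_quantiles, list):
            params.score_quantiles = tuple(params.score_quantiles)
        return cls(params=params, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["params"]["score_quantiles"] = list(self.params.score_quantiles)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass
class PipelineResult:
    """Every stage's tables, in memory."""

    gene_results: pd.DataFrame
    mirna_results: pd.DataFrame
    peak_results: pd.DataFrame
    peak_cpm: pd.DataFrame
    gene_tpm: pd.DataFrame
    highly_accessible: pd.Series
    annotated_peaks: pd.DataFrame
    annotation_summary: pd.Series
    assignments: pd.DataFrame
    element_correlations: pd.DataFrame
    gene_classes: pd.DataFrame
    cross_classification: pd.Series
    n_peak_histogram: pd.Series
    target_map: pd.DataFrame
    gene_regulation: pd.DataFrame
    tension_calls: pd.DataFrame
    footprint_calls: pd.DataFrame
    bound_table: pd.DataFrame
    tf_evidence: pd.DataFrame
    key_tfs: pd.DataFrame
    network: tfn.CascadeNetwork | None
    mirna_overlay: pd.DataFrame
    enrichment: pd.DataFrame | None


def run_stages(
    annotation: GeneAnnotationSet,
    gene_counts: pd.DataFrame,
    mirna_counts: pd.DataFrame,
    peaks: PeakSet,
    binding_sites: pd.DataFrame,
    footprint_stats: pd.DataFrame,
    target_records: pd.DataFrame,
    sample_groups: pd.Series,
    gene_lengths: pd.Series | None = None,
    gmt: dict[str, set[str]] | None = None,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run every analysis stage on in-memory inputs and return all tables."""
    p = params or PipelineParams()
    if gene_lengths is None:
        gene_lengths = annotation.lengths()

    # differential layer by layer
    gene_groups = sample_groups.reindex(gene_counts.columns)
    gene_expressed = de.is_expressed(gene_counts)
    gene_results = de.classify_genes(
        de.test_differential(gene_counts, gene_groups),
        lfc_cut=p.gene_lfc_cut,
        padj_cut=p.gene_padj_cut,
        expressed=gene_expressed,
    )
    mirna_groups = sample_groups.reindex(mirna_counts.columns)
    mirna_results = de.classify_mirnas(
        de.test_differential(mirna_counts, mirna_groups),
        lfc_cut=p.mirna_lfc_cut,
        p_cut=p.mirna_p_cut,
        expressed=de.is_expressed(mirna_counts),
    )
    peak_groups = sample_groups.reindex(peaks.counts.columns)
    peak_results = de.classify_peaks(
        de.test_differential(peaks.counts, peak_groups),
        lfc_cut=p.peak_lfc_cut,
        padj_cut=p.peak_padj_cut,
    )
    peak_cpm = de.normalize_cpm(peaks.counts)
    gene_tpm = de.normalize_tpm(gene_counts, gene_lengths)
    highly_accessible = de.flag_highly_accessible(
        peak_cpm, peak_groups, log_cpm_cut=p.log_cpm_cut, log_base=p.log_base
    )

    # peak annotation and promoter linking
    index = pa.build_feature_index(annotation, promoter_bp=p.promoter_bp, downstream_bp=p.downstream_bp)
    annotated = pa.annotate_peaks(peaks, index)
    summary = pa.annotation_summary(annotated)
    assignments = pa.assign_promoter_peaks(annotated, index)

    # promoter-centric integration
    correlations = pi.element_correlation(annotated, peak_cpm, gene_tpm, peak_groups, gene_groups)
    peak_starts = pd.Series(
        peaks.intervals["start"].to_numpy(), index=peaks.intervals["peak_id"]
    )
    gene_classes = pi.classify_promoter_genes(assignments, gene_results, peak_results, peak_starts)
    cross = pi.cross_classify(gene_classes)
    histogram = pi.n_peak_histogram(gene_classes)

    # miRNA dominance calls
    target_map = mi.filter_targets(target_records, mode=p.target_filter_mode)
    regulation = mi.overlap_regulation(gene_classes, target_map, mirna_results)
    tension = mi.call_tension(regulation)

    # TF footprints and the cascade network
    footprint_calls = tfn.call_differential_tfs(
        footprint_stats, score_quantiles=p.score_quantiles, p_quantile=p.p_quantile
    )
    bound = tfn.bound_genes(binding_sites, peaks.intervals, assignments)
    evidence = tfn.integrate_tf_evidence(footprint_calls, gene_results, bound, tpm=gene_tpm)
    key_tfs = tfn.rank_key_tfs(evidence)
    seed_tf = p.seed_tf or (key_tfs["tf_id"].iloc[0] if len(key_tfs) else None)
    network = None
    overlay = pd.DataFrame(
        columns=["mirna_id", "mirna_label", "target_nodes", "n_target_nodes", "candidate_derepressor"]
    )
    if seed_tf is not None:
        network = tfn.build_cascade_network(
            seed_tf,
            bound,
            gene_results,
            tf_universe=set(annotation.tf_ids()),
            tpm=gene_tpm,
            layers=p.cascade_layers,
        )
        overlay = tfn.mirna_network_overlay(network, target_map, mirna_results)

    # optional enrichment of the network genes against a GMT collection
    enrichment = None
    if gmt is not None and network is not None:
        universe = set(gene_results.loc[gene_results["label"] != "unexpressed", "feature_id"])
        query = set(network.node_genes()) & universe
        if query:
            enrichment = enr.hypergeometric_enrichment(query, universe, gmt)

    return PipelineResult(
        gene_results=gene_results,
        mirna_results=mirna_results,
        peak_results=peak_results,
        peak_cpm=peak_cpm,
        gene_tpm=gene_tpm,
        highly_accessible=highly_accessible,
        annotated_peaks=annotated,
        annotation_summary=summary,
        assignments=assignments,
        element_correlations=correlations,
        gene_classes=gene_classes,
        cross_classification=cross,
        n_peak_histogram=histogram,
        target_map=target_map,
        gene_regulation=regulation,
        tension_calls=tension,
        footprint_calls=footprint_calls,
        bound_table=bound,
        tf_evidence=evidence,
        key_tfs=key_tfs,
        network=network,
        mirna_overlay=overlay,
        enrichment=enrichment,
    )


def _write_outputs(result: PipelineResult, outdir: Path) -> dict[str, int]:
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def table(df: pd.DataFrame, name: str, **kwargs) -> None:
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False, **kwargs)
        counts[name] = len(df)

    table(result.gene_results, "gene_differential")
    table(result.mirna_results, "mirna_differential")
    table(result.peak_results, "peak_differential")
    table(result.annotated_peaks, "peak_annotation")
    result.annotation_summary.rename("percent").to_csv(
        outdir / "annotation_summary.tsv", sep="\t", index_label="element_class"
    )
    assignments = result.assignments.copy()
    assignments["peak_ids"] = assignments["peak_ids"].map(",".join)
    table(assignments, "promoter_assignments")
    table(result.element_correlations, "element_correlations")
    table(result.gene_classes, "gene_promoter_classes")
    result.cross_classification.rename("n_genes").to_csv(
        outdir / "cross_classification.tsv", sep="\t", index_label="category"
    )
    table(result.target_map, "filtered_targets")
    table(result.tension_calls, "tension_calls")
    table(result.footprint_calls, "footprint_calls")
    table(result.tf_evidence, "tf_evidence")
    table(result.key_tfs, "key_tfs")
    table(result.mirna_overlay, "mirna_network_overlay")
    if result.network is not None:
        result.network.write_graphml(str(outdir / "cascade_network.graphml"))
        result.network.write_sif(str(outdir / "cascade_network.sif"))
        table(result.network.edges_frame(), "cascade_edges")
        counts["network_nodes"] = result.network.graph.number_of_nodes()
    if result.enrichment is not None:
        table(result.enrichment, "enrichment")
    return counts


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Read the configured inputs, run every stage, write all outputs plus a
    JSON run manifest. Deterministic given config + inputs; any stage
    failure aborts with the stage name."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("triomics")
    root.addHandler(handler)
    try:
        stage = "read_inputs"
        try:
            tf_list = None
            if config.tf_list:
                tf_list = [t.strip() for t in Path(config.tf_list).read_text().split() if t.strip()]
            annotation = genome_io.read_gtf(config.gtf, tf_list=tf_list)
            if tf_list is None:  # fall back to id convention from the simulator
                for g in annotation:
                    if g.gene_id.startswith("TF"):
                        g.is_tf = True
            gene_counts = genome_io.read_counts(config.gene_counts)
            mirna_counts = genome_io.read_counts(config.mirna_counts)
            peaks = genome_io.read_narrowpeak(config.peaks, config.peak_counts)
            binding_sites = genome_io.read_bed6(config.binding_sites)
            footprints = genome_io.read_footprint_stats(config.footprint_stats)
            targets = genome_io.read_target_map(config.target_records)
            groups = pd.read_csv(config.sample_groups, sep="\t", index_col=0)["group"]
            gmt = genome_io.read_gmt(config.gmt) if config.gmt else None
            stage = "analysis"
            result = run_stages(
                annotation,
                gene_counts,
                mirna_counts,
                peaks,
                binding_sites,
                footprints,
                targets,
                groups,
                gmt=gmt,
                params=config.params,
            )
            stage = "write_outputs"
            counts = _write_outputs(result, outdir)
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest = {
            "seed": config.seed,
            "params": {**asdict(config.params), "score_quantiles": list(config.params.score_quantiles)},
            "stage_counts": counts,
            "n_samples": int(len(groups)),
            "n_genes": len(annotation),
            "n_peaks": len(peaks),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        logger.info("pipeline complete: %s", counts)
        return result
    finally:
        root.removeHandler(handler)
        handler.close()
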
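"""Synthetic tri-omics datasets with planted regulatory ground truth.

The generator emulates the data shape of a two-condition developmental
contrast profiled with RNA-seq, miRNA-seq and ATAC-seq: a toy genome of
non-overlapping genes, negative-binomial count tables with planted log2
fold-changes, promoter-concentrated peaks whose intensity and direction are
coupled to expression for a known gene subset, a miRNA target map with
planted repression effects, per-TF differential footprint statistics with
planted extremes, and a two-layer TF cascade (seed -> primary target-TFs ->
secondary target-TFs) wired through binding sites inside promoter peaks.

Everything is deterministic given the seed, and the planted truth is
returned alongside the tables so every downstream stage can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import genome_io
from .models import (
    FOOTPRINT_COLUMNS,
    TARGET_RECORD_COLUMNS,
    GeneAnnotationSet,
    GeneModel,
    PeakSet,
)

_GAP_RANGE = (8000, 15000)  # intergenic gaps keep promoter windows apart
_EDGE_MARGIN = 4000


@dataclass
class SimulationConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the profiled cohort: two groups with 3 vs 4 replicates,
    negative-binomial dispersion 0.05, planted |log2FC| of 2 on differential
    features, 10% unexpressed genes, and a cascade of one seed TF with three
    primary and five secondary target-TFs.
    """

    n_chrom: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 150
    n_tfs: int = 30
    n_mirnas: int = 40
    reps_per_group: tuple[int, int] = (3, 4)
    nb_dispersion: float = 0.05
    lfc_magnitude: float = 2.0
    lfc_sd: float = 0.0
    frac_de: float = 0.2
    frac_unexpressed: float = 0.10
    frac_promoter_peak: float = 0.6
    frac_multi_peak: float = 0.15
    n_primary: int = 3
    n_secondary: int = 5
    n_leaf_targets: int = 2
    n_tension_genes: int = 6
    mirnas_per_tension_gene: int = 3
    n_intron_peaks: int = 30
    n_distal_peaks: int = 40
    group_names: tuple[str, str] = ("G21", "G24")
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.reps_per_group, int):
            self.reps_per_group = (self.reps_per_group, self.reps_per_group)
        if self.n_genes < 0 or self.n_tfs < 0 or self.n_genes < self.n_tfs:
            raise ValueError("need 0 <= n_tfs <= n_genes")
        if min(self.reps_per_group) < 2:
            raise ValueError("each group needs >= 2 replicates")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 <= self.frac_de <= 1:
            raise ValueError("frac_de must be in [0, 1]")
        if self.n_secondary > 0 and self.n_primary == 0:
            raise ValueError("secondary targets require at least one primary target")

    @property
    def sample_names(self) -> list[str]:
        g1, g2 = self.group_names
        r1, r2 = self.reps_per_group
        return [f"{g1}_{i + 1}" for i in range(r1)] + [f"{g2}_{i + 1}" for i in range(r2)]

    @property
    def sample_groups(self) -> pd.Series:
        g1, g2 = self.group_names
        r1, r2 = self.reps_per_group
        return pd.Series([g1] * r1 + [g2] * r2, index=self.sample_names, name="group")


@dataclass
class RegulatoryTruth:
    """Planted ground truth: who regulates whom, and by how much."""

    seed_tf: str
    primary_targets: list[str]
    secondary_targets: list[str]
    leaf_targets: list[str]
    cascade_edges: list[tuple[str, str]]
    competitor_tf: str | None
    binding_sites: pd.DataFrame  # BED6-shaped, name = tf_id
    site_target_genes: list[str]  # genes whose promoter hosts a planted site
    promoter_coupled_genes: set[str]
    promoter_peak_genes: set[str]
    tension_genes: list[str]
    unexpressed_genes: set[str]
    mirna_effects: list[tuple[str, str, str]]  # (mirna, gene, direction)
    planted_lfc: dict[str, float]
    planted_footprint_increased: list[str] = field(default_factory=list)
    planted_footprint_decreased: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["binding_sites"] = self.binding_sites.to_dict(orient="records")
        payload["promoter_coupled_genes"] = sorted(self.promoter_coupled_genes)
        payload["promoter_peak_genes"] = sorted(self.promoter_peak_genes)
        payload["unexpressed_genes"] = sorted(self.unexpressed_genes)
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


def simulate_genome(config: SimulationConfig) -> GeneAnnotationSet:
    """A toy genome: non-overlapping multi-exon genes on both strands.

    Genes are packed left to right with intergenic gaps of 8-15 kb so that
    promoter windows of neighbours stay disjoint; an explicit error is
    raised when the requested genes cannot fit on the chromosomes.
    """
    rng = np.random.default_rng([config.seed, 0])
    annotation = GeneAnnotationSet()
    if config.n_genes == 0:
        return annotation
    tf_indices = set(rng.choice(config.n_genes, size=config.n_tfs, replace=False).tolist())
    per_chrom = [config.n_genes // config.n_chrom] * config.n_chrom
    for i in range(config.n_genes % config.n_chrom):
        per_chrom[i] += 1

    gene_idx = 0
    tf_counter = 0
    gene_counter = 0
    for c, n_on_chrom in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        pos = _EDGE_MARGIN
        for _ in range(n_on_chrom):
            n_exons = int(rng.integers(2, 5))
            exon_lengths = rng.integers(200, 601, size=n_exons)
            intron_lengths = rng.integers(500, 2001, size=n_exons - 1)
            start = pos
            exons = []
            cur = start
            for k in range(n_exons):
                exons.append((cur, cur + int(exon_lengths[k])))
                cur = exons[-1][1]
                if k < n_exons - 1:
                    cur += int(intron_lengths[k])
            end = exons[-1][1]
            if end > config.chrom_length - _EDGE_MARGIN:
                raise ValueError(
                    f"infeasible packing: {config.n_genes} genes do not fit in "
                    f"{config.n_chrom} x {config.chrom_length} bp"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            if gene_idx in tf_indices:
                gene_id = f"TF{tf_counter:03d}"
                tf_counter += 1
            else:
                gene_id = f"G{gene_counter:04d}"
                gene_counter += 1
            # 5'/3' UTRs carve the outermost stretches of the terminal exons
            if strand == "+":
                five = [(exons[0][0], exons[0][0] + min(150, exon_lengths[0] // 2))]
                three = [(exons[-1][1] - min(200, exon_lengths[-1] // 2), exons[-1][1])]
            else:
                five = [(exons[-1][1] - min(150, exon_lengths[-1] // 2), exons[-1][1])]
                three = [(exons[0][0], exons[0][0] + min(200, exon_lengths[0] // 2))]
            annotation.add(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                    five_prime_utrs=five,
                    three_prime_utrs=three,
                    is_tf=gene_idx in tf_indices,
                )
            )
            gene_idx += 1
            pos = end + int(rng.integers(*_GAP_RANGE))
    # guarantee both strands appear
    genes = list(annotation)
    if len(genes) >= 2 and len({g.strand for g in genes}) == 1:
        flip = genes[0]
        flip.strand = "+" if flip.strand == "-" else "-"
    return annotation


def _signed_magnitude(rng: np.random.Generator, config: SimulationConfig, sign: int) -> float:
    mag = config.lfc_magnitude + (rng.normal(0, config.lfc_sd) if config.lfc_sd > 0 else 0.0)
    return sign * max(abs(mag), 0.25)


def plant_truth(annotation: GeneAnnotationSet, config: SimulationConfig) -> RegulatoryTruth:
    """Plant the cascade, promoter coupling, miRNA effects and footprint
    extremes on top of a simulated genome.

    All cascade targets receive positive planted log2FCs, and every planted
    binding site midpoint falls within 3 kb of its target's TSS (inside the
    target's promoter peak, so the binding evidence survives the
    site-in-peak-in-promoter rule downstream).
    """
    rng = np.random.default_rng([config.seed, 1])
    tfs = annotation.tf_ids()
    if len(tfs) < 3:
        raise ValueError(f"need >= 3 TF-designated genes, have {len(tfs)}")
    needed = 1 + config.n_primary + config.n_secondary + 1  # + competitor
    if len(tfs) < needed:
        raise ValueError(f"need >= {needed} TF genes for the requested cascade, have {len(tfs)}")

    tf_pool = list(rng.permutation(tfs))
    seed_tf = tf_pool.pop()
    primaries = [tf_pool.pop() for _ in range(config.n_primary)]
    secondaries = [tf_pool.pop() for _ in range(config.n_secondary)]
    competitor = tf_pool.pop() if tf_pool else None

    non_tf = [g for g in annotation.gene_ids if not annotation[g].is_tf]
    non_tf_pool = list(rng.permutation(non_tf))
    leaves = [non_tf_pool.pop() for _ in range(min(config.n_leaf_targets, len(non_tf_pool)))]
    tension = [non_tf_pool.pop() for _ in range(min(config.n_tension_genes, len(non_tf_pool)))]
    competitor_down = [non_tf_pool.pop() for _ in range(min(2, len(non_tf_pool)))]
    competitor_up = [non_tf_pool.pop() for _ in range(min(2, len(non_tf_pool)))]

    n_unexpr = int(round(config.frac_unexpressed * len(non_tf_pool)))
    unexpressed = {non_tf_pool.pop() for _ in range(n_unexpr)}

    planted_lfc: dict[str, float] = {g: 0.0 for g in annotation.gene_ids}
    for g in [seed_tf, *primaries, *secondaries, *leaves, *competitor_up]:
        planted_lfc[g] = _signed_magnitude(rng, config, +1)
    if competitor is not None:
        planted_lfc[competitor] = _signed_magnitude(rng, config, +1)
    for g in [*tension, *competitor_down]:
        planted_lfc[g] = _signed_magnitude(rng, config, -1)
    # generic DE genes up to frac_de of the expressed genes
    n_expressed = len(annotation) - len(unexpressed)
    n_de_target = int(round(config.frac_de * n_expressed))
    already_de = [g for g, v in planted_lfc.items() if v != 0]
    extra = max(0, n_de_target - len(already_de))
    for g in non_tf_pool[:extra]:
        planted_lfc[g] = _signed_magnitude(rng, config, 1 if rng.random() < 0.5 else -1)

    # cascade wiring: primaries split round-robin over the secondaries
    edges = [(seed_tf, p) for p in primaries]
    for i, s in enumerate(secondaries):
        edges.append((primaries[i % max(1, len(primaries))], s))
    edges += [(seed_tf, leaf) for leaf in leaves]
    competitor_edges = (
        [(competitor, g) for g in competitor_up + competitor_down] if competitor is not None else []
    )

    site_rows = []
    for src, tgt in edges + competitor_edges:
        tss = annotation[tgt].tss
        offset = int(rng.integers(-250, 236))
        site_rows.append(
            {
                "chrom": annotation[tgt].chrom,
                "start": tss + offset,
                "end": tss + offset + 15,
                "name": src,
                "score": 0,
                "strand": ".",
            }
        )
    # decoy sites outside any peak, near the chromosome start
    for tf in (seed_tf, competitor or seed_tf):
        site_rows.append({"chrom": "chr1", "start": 50, "end": 65, "name": tf, "score": 0, "strand": "."})
    binding_sites = pd.DataFrame(site_rows)

    # promoter peaks: all planted actors plus a random slice of the genome
    must_have_peak = {
        seed_tf,
        *primaries,
        *secondaries,
        *leaves,
        *tension,
        *competitor_up,
        *competitor_down,
    }
    if competitor is not None:
        must_have_peak.add(competitor)
    others = [g for g in annotation.gene_ids if g not in must_have_peak]
    n_random_peaks = int(round(config.frac_promoter_peak * len(annotation))) - len(must_have_peak)
    random_peaked = set(rng.permutation(others)[: max(0, n_random_peaks)].tolist())
    promoter_peak_genes = must_have_peak | random_peaked
    coupled = {
        g
        for g in promoter_peak_genes
        if planted_lfc.get(g, 0.0) != 0 and g not in tension and g not in unexpressed
    }

    # miRNAs: planted up pool represses the tension genes, planted down pool
    # targets cascade nodes (candidate de-repression)
    mirna_ids = [f"miR-{i:03d}" for i in range(config.n_mirnas)]
    n_de_mirna = max(4, int(round(config.frac_de * config.n_mirnas)))
    de_pool = list(rng.permutation(mirna_ids)[:n_de_mirna])
    up_mirnas = de_pool[: max(config.mirnas_per_tension_gene, n_de_mirna // 2)]
    down_mirnas = de_pool[len(up_mirnas):]
    for m in mirna_ids:
        planted_lfc[m] = 0.0
    for m in up_mirnas:
        planted_lfc[m] = _signed_magnitude(rng, config, +1)
    for m in down_mirnas:
        planted_lfc[m] = _signed_magnitude(rng, config, -1)

    effects: list[tuple[str, str, str]] = []
    for g in tension:
        chosen = rng.permutation(up_mirnas)[: config.mirnas_per_tension_gene]
        effects.extend((m, g, "repression") for m in chosen)
    overlay_targets = (primaries + secondaries)[:4]
    for i, g in enumerate(overlay_targets):
        if down_mirnas:
            effects.append((down_mirnas[i % len(down_mirnas)], g, "derepression"))

    planted_inc = [seed_tf] + ([competitor] if competitor is not None else [])
    planted_dec = tf_pool[:2]
    for tf in planted_dec:
        if planted_lfc.get(tf, 0.0) == 0:
            planted_lfc[tf] = _signed_magnitude(rng, config, -1)

    return RegulatoryTruth(
        seed_tf=seed_tf,
        primary_targets=primaries,
        secondary_targets=secondaries,
        leaf_targets=leaves,
        cascade_edges=edges,
        competitor_tf=competitor,
        binding_sites=binding_sites,
        site_target_genes=sorted({tgt for _, tgt in edges + competitor_edges}),
        promoter_coupled_genes=coupled,
        promoter_peak_genes=promoter_peak_genes,
        tension_genes=tension,
        unexpressed_genes=unexpressed,
        mirna_effects=effects,
        planted_lfc=planted_lfc,
        planted_footprint_increased=planted_inc,
        planted_footprint_decreased=planted_dec,
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB counts with Var = mu + dispersion * mu^2 (size = 1/dispersion)."""
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if pos.any():
        size = 1.0 / dispersion
        p = size / (size + mu[pos])
        out[pos] = rng.negative_binomial(size, p)
    return out


@dataclass
class SimulatedData:
    """The full simulated dataset plus its planted truth."""

    config: SimulationConfig
    annotation: GeneAnnotationSet
    truth: RegulatoryTruth
    gene_counts: pd.DataFrame
    mirna_counts: pd.DataFrame
    peaks: PeakSet
    binding_sites: pd.DataFrame
    footprint_stats: pd.DataFrame
    target_records: pd.DataFrame
    planted_peak_lfc: dict[str, float]

    @property
    def sample_groups(self) -> pd.Series:
        return self.config.sample_groups

    def gene_lengths(self) -> pd.Series:
        return self.annotation.lengths()


def simulate_counts(
    truth: RegulatoryTruth, annotation: GeneAnnotationSet, config: SimulationConfig
) -> SimulatedData:
    """Draw the count tables and assemble the peak/footprint/target inputs.

    Group-2 means are group-1 means scaled by 2^(planted log2FC); promoter
    peak base intensity tracks the host gene's base expression (that is the
    planted promoter/expression intensity coupling), while intronic and
    distal peaks draw independent intensities.
    """
    rng = np.random.default_rng([config.seed, 2])
    samples = config.sample_names
    groups = config.sample_groups
    g2 = config.group_names[1]
    depth = rng.uniform(0.8, 1.2, size=len(samples))

    def draw_counts(ids: list[str], base: np.ndarray, lfc: np.ndarray) -> pd.DataFrame:
        mu = np.empty((len(ids), len(samples)))
        for j, s in enumerate(samples):
            scale = np.where(groups[s] == g2, 2.0 ** lfc, 1.0)
            mu[:, j] = base * scale * depth[j]
        return pd.DataFrame(_nb_draw(rng, mu, config.nb_dispersion), index=ids, columns=samples)

    gene_ids = annotation.gene_ids
    gene_base = np.exp(rng.normal(np.log(100), 1.0, size=len(gene_ids)))
    base_by_gene = dict(zip(gene_ids, gene_base))
    if truth.seed_tf in base_by_gene:
        base_by_gene[truth.seed_tf] = 1500.0
    if truth.competitor_tf in base_by_gene:
        base_by_gene[truth.competitor_tf] = 300.0
    for g in truth.unexpressed_genes:
        base_by_gene[g] = 0.0
    gene_base = np.array([base_by_gene[g] for g in gene_ids])
    gene_lfc = np.array([truth.planted_lfc.get(g, 0.0) for g in gene_ids])
    gene_counts = draw_counts(gene_ids, gene_base, gene_lfc)

    mirna_ids = sorted(m for m in truth.planted_lfc if m.startswith("miR-"))
    mirna_base = np.exp(rng.normal(np.log(200), 1.0, size=len(mirna_ids)))
    mirna_lfc = np.array([truth.planted_lfc[m] for m in mirna_ids])
    mirna_counts = draw_counts(mirna_ids, mirna_base, mirna_lfc)

    # ---- peaks -------------------------------------------------------
    peak_rows: list[dict] = []
    peak_base: list[float] = []
    peak_lfc_list: list[float] = []

    def add_peak(chrom: str, start: int, end: int, base: float, lfc: float) -> None:
        pid = f"peak{len(peak_rows):05d}"
        peak_rows.append({"peak_id": pid, "chrom": chrom, "start": max(0, start), "end": end})
        peak_base.append(base)
        peak_lfc_list.append(lfc)

    # genes carrying a planted binding site need a promoter peak wide enough
    # to contain it, so the site-in-peak-in-promoter rule finds the edge
    site_target_genes = set(truth.site_target_genes)
    multi_candidates = sorted(truth.promoter_peak_genes - site_target_genes - set(truth.tension_genes))
    n_multi = int(round(config.frac_multi_peak * len(multi_candidates)))
    multi_genes = set(rng.permutation(multi_candidates)[:n_multi].tolist())

    for g in sorted(truth.promoter_peak_genes):
        gene = annotation[g]
        tss = gene.tss
        if g in site_target_genes:
            start, end = tss - 400, tss + 400  # must cover the planted binding site
        else:
            center = tss + int(rng.integers(-1000, 1001))
            width = int(rng.integers(200, 1001))
            start, end = center - width // 2, center + width // 2
        if g in truth.tension_genes:
            lfc = abs(config.lfc_magnitude)  # opened promoter on a repressed gene
        elif g in truth.promoter_coupled_genes:
            lfc = truth.planted_lfc.get(g, 0.0)
        else:
            lfc = 0.0
        base = 20.0 + 0.3 * base_by_gene[g] * float(np.exp(rng.normal(0, 0.3)))
        add_peak(gene.chrom, start, end, base, lfc)
        if g in multi_genes:
            center = tss + int(rng.integers(-2000, 2001))
            width = int(rng.integers(200, 601))
            extra_lfc = float(rng.choice([0.0, config.lfc_magnitude, -config.lfc_magnitude]))
            add_peak(
                gene.chrom,
                center - width // 2,
                center + width // 2,
                float(np.exp(rng.normal(np.log(50), 0.8))),
                extra_lfc,
            )

    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for gene in annotation:
        genes_by_chrom.setdefault(gene.chrom, []).append(gene)
    all_genes = list(annotation)
    for _ in range(config.n_intron_peaks):
        gene = all_genes[int(rng.integers(len(all_genes)))]
        introns = [(a2, b1) for (_, a2), (b1, _) in zip(gene.exons[:-1], gene.exons[1:])]
        # intron midpoints must escape the gene's own promoter window
        candidates = [
            p
            for a, b in introns
            for p in range(a + 50, b - 50, 97)
            if abs(p - gene.tss) > 3200
        ]
        if not candidates:
            continue
        mid = candidates[int(rng.integers(len(candidates)))]
        width = int(rng.integers(200, 401))
        add_peak(gene.chrom, mid - width // 2, mid + width // 2, float(np.exp(rng.normal(np.log(50), 0.8))), 0.0)

    for chrom, chrom_genes in genes_by_chrom.items():
        chrom_genes.sort(key=lambda g: g.start)
    gap_centers = []
    for chrom, chrom_genes in genes_by_chrom.items():
        for left, right in zip(chrom_genes[:-1], chrom_genes[1:]):
            center = (left.end + right.start) // 2
            if min(center - left.end, right.start - center) > 3600:
                gap_centers.append((chrom, center))
    if gap_centers:
        for _ in range(config.n_distal_peaks):
            chrom, center = gap_centers[int(rng.integers(len(gap_centers)))]
            mid = center + int(rng.integers(-300, 301))
            width = int(rng.integers(200, 601))
            add_peak(chrom, mid - width // 2, mid + width // 2, float(np.exp(rng.normal(np.log(50), 0.8))), 0.0)

    intervals = pd.DataFrame(peak_rows, columns=["peak_id", "chrom", "start", "end"])
    peak_counts = draw_counts(
        intervals["peak_id"].tolist(), np.array(peak_base), np.array(peak_lfc_list)
    )
    peaks = PeakSet(intervals=intervals, counts=peak_counts)
    planted_peak_lfc = dict(zip(intervals["peak_id"], peak_lfc_list))
    truth.planted_lfc.update(planted_peak_lfc)

    # ---- footprint statistics ---------------------------------------
    tf_ids = annotation.tf_ids()
    scores = rng.normal(0, 1, size=len(tf_ids))
    neglog_p = np.abs(rng.normal(0, 0.7, size=len(tf_ids)))
    fp = pd.DataFrame({"tf_id": tf_ids, "diff_binding_score": scores, "neglog10_p": neglog_p})
    fp = fp.set_index("tf_id")
    for tf in truth.planted_footprint_increased:
        fp.loc[tf, ["diff_binding_score", "neglog10_p"]] = (
            float(rng.uniform(5, 7)),
            float(rng.uniform(6, 9)),
        )
    for tf in truth.planted_footprint_decreased:
        fp.loc[tf, ["diff_binding_score", "neglog10_p"]] = (
            float(rng.uniform(-7, -5)),
            float(rng.uniform(5, 8)),
        )
    footprint_stats = fp.reset_index()[FOOTPRINT_COLUMNS]

    # ---- miRNA target records ---------------------------------------
    rec_rows: list[dict] = []

    def add_pair(mirna: str, gene: str, passing: bool) -> None:
        if passing:
            rec_rows.append(
                {
                    "mirna_id": mirna,
                    "gene_id": gene,
                    "miranda_score": float(rng.uniform(160, 300)),
                    "hybrid_energy": float(rng.uniform(-25, -16)),
                    "hybrid_pvalue": float(rng.uniform(0.05, 1.0)),
                    "source": "toolA",
                }
            )
            rec_rows.append(
                {
                    "mirna_id": mirna,
                    "gene_id": gene,
                    "miranda_score": 0.0,
                    "hybrid_energy": float(rng.uniform(-25, -16)),
                    "hybrid_pvalue": float(rng.uniform(0.001, 0.04)),
                    "source": "toolB",
                }
            )
        else:
            rec_rows.append(
                {
                    "mirna_id": mirna,
                    "gene_id": gene,
                    "miranda_score": float(rng.uniform(50, 150)),
                    "hybrid_energy": float(rng.uniform(-25, -16)),
                    "hybrid_pvalue": float(rng.uniform(0.05, 1.0)),
                    "source": "toolA",
                }
            )

    for mirna, gene, _direction in truth.mirna_effects:
        add_pair(mirna, gene, passing=True)
    ns_mirnas = [m for m in mirna_ids if truth.planted_lfc[m] == 0.0]
    peaked = sorted(truth.promoter_peak_genes)
    for i in range(min(10, len(ns_mirnas), len(peaked))):
        add_pair(ns_mirnas[i], peaked[int(rng.integers(len(peaked)))], passing=True)
    for _ in range(30):
        add_pair(
            mirna_ids[int(rng.integers(len(mirna_ids)))],
            gene_ids[int(rng.integers(len(gene_ids)))] if gene_ids else "G0000",
            passing=False,
        )
    target_records = pd.DataFrame(rec_rows, columns=TARGET_RECORD_COLUMNS)

    return SimulatedData(
        config=config,
        annotation=annotation,
        truth=truth,
        gene_counts=gene_counts,
        mirna_counts=mirna_counts,
        peaks=peaks,
        binding_sites=truth.binding_sites.copy(),
        footprint_stats=footprint_stats,
        target_records=target_records,
        planted_peak_lfc=planted_peak_lfc,
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedData:
    """Genome -> planted truth -> counts, in one call."""
    annotation = simulate_genome(config)
    truth = plant_truth(annotation, config)
    return simulate_counts(truth, annotation, config)


def write_dataset(data: SimulatedData, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in its on-disk formats (GTF, narrowPeak, BED6, TSV,
    ground-truth JSON). Returns the path of each artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": outdir / "genes.gtf",
        "gene_counts": outdir / "gene_counts.tsv",
        "mirna_counts": outdir / "mirna_counts.tsv",
        "peaks": outdir / "peaks.narrowPeak",
        "peak_counts": outdir / "peak_counts.tsv",
        "binding_sites": outdir / "binding_sites.bed",
        "footprints": outdir / "footprint_stats.tsv",
        "targets": outdir / "target_records.tsv",
        "groups": outdir / "sample_groups.tsv",
        "truth": outdir / "truth.json",
    }
    genome_io.write_gtf(data.annotation, paths["gtf"])
    genome_io.write_counts(data.gene_counts, paths["gene_counts"])
    genome_io.write_counts(data.mirna_counts, paths["mirna_counts"])
    genome_io.write_narrowpeak(data.peaks, paths["peaks"], paths["peak_counts"])
    genome_io.write_bed6(data.binding_sites, paths["binding_sites"])
    data.footprint_stats.to_csv(paths["footprints"], sep="\t", index=False)
    genome_io.write_target_map(data.target_records, paths["targets"])
    data.sample_groups.to_frame().to_csv(paths["groups"], sep="\t", index_label="sample")
    data.truth.to_json(paths["truth"])
    return paths
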
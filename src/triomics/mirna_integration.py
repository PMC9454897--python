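"""miRNA target filtering and accessibility-vs-miRNA dominance calls.

Sequence-based target predictors emit candidate miRNA->gene records with a
pairing score, a hybridization energy (kcal/mol) and, for one of the tools, a
hybridization p-value. The filters reproduce the published cutoffs: the
score/energy tool passes records with score > 150 and energy < -15; the
energy/p-value tool passes records with energy < -15 and p < 0.05. A pair
survives if supported by both tools (intersection, default) or either
(union).
"""

from __future__ import annotations

import pandas as pd

MIRANDA_SCORE_CUT = 150.0
HYBRID_ENERGY_CUT = -15.0
HYBRID_P_CUT = 0.05

_SOURCES = {"toolA", "toolB", "both"}


def filter_targets(
    records: pd.DataFrame,
    mode: str = "intersection",
    score_cut: float = MIRANDA_SCORE_CUT,
    energy_cut: float = HYBRID_ENERGY_CUT,
    p_cut: float = HYBRID_P_CUT,
) -> pd.DataFrame:
    """Filter raw target-prediction records into a (mirna_id, gene_id) map.

    All inequalities are strict, exactly as the cutoffs are stated: a record
    at score == 150 fails. A record tagged ``both`` counts as support from
    both tools and must satisfy both filters.
    """
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown filter mode {mode!r}")
    unknown = set(records["source"]) - _SOURCES
    if unknown:
        raise ValueError(f"unknown source tag(s): {sorted(unknown)}")

    rec = records.copy()
    pass_a = (rec["miranda_score"] > score_cut) & (rec["hybrid_energy"] < energy_cut)
    pass_b = (rec["hybrid_energy"] < energy_cut) & (rec["hybrid_pvalue"] < p_cut)
    rec["pass_toolA"] = ((rec["source"] == "toolA") & pass_a) | ((rec["source"] == "both") & pass_a)
    rec["pass_toolB"] = ((rec["source"] == "toolB") & pass_b) | ((rec["source"] == "both") & pass_b)

    support = rec.groupby(["mirna_id", "gene_id"])[["pass_toolA", "pass_toolB"]].any()
    if mode == "intersection":
        kept = support[support["pass_toolA"] & support["pass_toolB"]]
    else:
        kept = support[support["pass_toolA"] | support["pass_toolB"]]
    return kept.reset_index()[["mirna_id", "gene_id"]].sort_values(
        ["mirna_id", "gene_id"], ignore_index=True
    )


def overlap_regulation(
    gene_classes: pd.DataFrame,
    target_map: pd.DataFrame,
    mirna_results: pd.DataFrame,
) -> pd.DataFrame:
    """Count differentially expressed miRNAs targeting each promoter-peak gene.

    Only genes with at least one promoter peak are considered; only miRNAs
    labeled up or down contribute to the counts.
    """
    labels = mirna_results.set_index("feature_id")["label"]
    tmap = target_map.copy()
    tmap["mirna_label"] = tmap["mirna_id"].map(labels)
    genes = gene_classes[gene_classes["n_peak"] >= 1][
        ["gene_id", "de_label", "n_peak", "major_peak_direction"]
    ].copy()
    up = tmap[tmap["mirna_label"] == "up"].groupby("gene_id").size()
    down = tmap[tmap["mirna_label"] == "down"].groupby("gene_id").size()
    genes["n_up_mirna"] = genes["gene_id"].map(up).fillna(0).astype(int)
    genes["n_down_mirna"] = genes["gene_id"].map(down).fillna(0).astype(int)
    return genes.reset_index(drop=True)


def _tension_rule(de_label: str, peak_dir: str, n_up: int, n_down: int) -> str:
    targeted = (n_up + n_down) > 0
    if de_label == "down" and peak_dir == "increased" and n_up > n_down:
        return "mirna_dominant"
    if de_label == "up" and peak_dir == "increased":
        return "accessibility_dominant" if targeted else "concordant"
    if de_label == "down" and peak_dir == "decreased" and (n_down >= n_up or not targeted):
        return "concordant"
    return "ambiguous" if targeted else "untargeted"


def call_tension(gene_regulation: pd.DataFrame) -> pd.DataFrame:
    """Per-gene dominance call between promoter accessibility and miRNA
    targeting.

    Open promoters activate; miRNAs repress. A downregulated gene whose
    major promoter peak nonetheless opened, targeted by more upregulated than
    downregulated miRNAs, is called ``mirna_dominant``: the repression won.
    An upregulated gene with an opened promoter is
    ``accessibility_dominant`` when miRNAs target it at all (the activation
    won) and ``concordant`` when none do. A downregulated gene with a closed
    promoter and no opposing miRNA signal is ``concordant``. Anything else is
    ``ambiguous`` when DE miRNAs target the gene, ``untargeted`` otherwise.
    """
    if gene_regulation["major_peak_direction"].isna().any():
        bad = gene_regulation.loc[gene_regulation["major_peak_direction"].isna(), "gene_id"].iloc[0]
        raise ValueError(f"gene {bad!r} has no major promoter peak")
    out = gene_regulation.copy()
    out["call"] = [
        _tension_rule(r.de_label, r.major_peak_direction, r.n_up_mirna, r.n_down_mirna)
        for r in out.itertuples(index=False)
    ]
    return out
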
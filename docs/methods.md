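# Methods

This note documents the models, rules and numerical choices behind each
pipeline stage, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the analysis was genuinely
open.

## Coordinates and formats

All internal coordinates are 0-based half-open. GTF (1-based inclusive) is
converted at the I/O boundary; BED, narrowPeak and interval TSVs pass
through unchanged. A single convention avoids off-by-one drift in the
±3 kb promoter arithmetic. The TSS is the 5′ end of the *gene record*
(start on '+', end−1 on '−'); per-transcript TSS variation is out of scope.
TF status comes from a user-supplied gene list (a motif-database export is
typical); nothing is bundled.

## Differential analysis

**Normalization.** CPM divides each raw count by its column total × 10⁶;
for peaks the column total is the number of reads in all peaks. TPM divides
by feature length first and rescales columns to 10⁶. Both column sums are
exactly 10⁶ up to float rounding.

**Test.** The default test works on log2(CPM + 1) after rescaling CPM
columns by median-of-ratios size factors (median ratio to the row geometric
mean over features observed in every sample). This matters: with an
unbalanced set of strong fold-changes, total-count normalization drags
every null feature's apparent log2FC by the library-composition shift
(~0.5 under the generator's defaults), pushing true effects below the
|log2FC| > 1 cut. Per-feature variances are pooled across both groups
(df = n₁+n₂−2), shrunk toward a lowess mean–variance trend with an
empirical-Bayes prior whose df is estimated by matching the moments of log
sample variances (chi-square bias removed analytically), and the moderated
t is referred to the combined df. At 3–4 replicates per group an unmoderated
Welch t has ~5–6 residual df; its p-values bottom out near 5×10⁻⁴ and a
Benjamini–Hochberg 0.01 threshold then caps recall near 0.6 regardless of
effect size — variance moderation is what makes these designs workable.
`method="logcpm_welch"` gives the plain Welch t (with the convention that a
zero-variance, zero-difference feature has p = 1). The test is a documented
stand-in: only the labels feed downstream, and DESeq2-format result tables
can be read in directly.

**Thresholds.** Genes: |log2FC| > 1 and P_adj < 0.01. miRNAs: |log2FC| > 1
and raw p < 0.05 (the miRNA layer thresholds the unadjusted p-value).
Peaks: |log2FC| > 1.5 and P_adj < 0.05. All inequalities strict, exactly as
printed. A feature is "expressed" if its raw count is ≥ 1 in ≥ 2 samples;
failures are labeled `unexpressed` before thresholding. "Highly accessible"
peaks have log₂(group-mean CPM + 1) > 5, where the two group means are
averaged so unequal replicate numbers do not bias the pool; the base and
the cut are configurable since the original log base is ambiguous. At desk
scale (≈150 peaks) mean CPM is ~10⁴ and every peak passes; the flag only
discriminates at realistic peak-set sizes.

## Peak annotation

Class membership is decided by the peak **midpoint**, not any-overlap, so
each peak gets exactly one class and the per-class percentages partition
the peak set. Precedence: promoter > 5′UTR > 3′UTR > exon > intron >
downstream > distal intergenic (the ChIPseeker-style hierarchy). The
promoter window is [TSS−3000, TSS+3000) clipped at zero; "downstream"
extends 3 kb past the gene 3′ end (the width is this package's choice —
no standard exists). Intron membership is implemented as gene-body
membership with exons peeled off by precedence. The nearest gene is the
minimum |midpoint − TSS| on the same chromosome, ties to the
lexicographically smaller id; distances are signed in gene orientation
(negative = upstream). Promoter-peak assignment links a peak to *every*
gene whose window contains its midpoint, so overlapping windows share
peaks; all genes are reported, including n_peak = 0. Reported percentages
can pool the two UTR classes; internal classes stay split.

## Promoter integration

**Element correlation.** Each peak pairs with its nearest gene. Group means
of log2(CPM+1) and log2(TPM+1) are computed per condition and averaged
across the two conditions, giving one point per pair. Averaging rather than
pooling the two group points is deliberate: a global between-condition
shift common to both axes would otherwise read as correlation in every
class. Classes need ≥ 3 pairs; zero variance on either axis reports r as
NaN (not computable), never 0. Whether only differential peaks should
enter is ambiguous in general; all peaks is the default.

**Major peak.** Among a gene's promoter peaks: maximum |log2FC|, ties
broken by smaller P_adj, then leftmost start, then id — fully deterministic
and order-invariant.

**Cross-classification.** Genes with one promoter peak fall into
label × direction cells (direction from the differential-peak labels;
non-significant peaks count as a separate `ns` direction rather than
either tail). Multi-peak genes are `all_increased` / `all_decreased` when
at least one peak is significant and all significant peaks agree, `mixed`
when both directions occur (then reduced by the major peak's direction),
and `ns_only` when none is significant. Cells are disjoint and exhaustive
over genes with ≥ 1 promoter peak.

## miRNA integration

Raw predictor records carry a pairing score, hybridization energy
(kcal/mol) and hybridization p-value. The score/energy tool passes records
with score > 150 and energy < −15; the energy/p tool with energy < −15 and
p < 0.05 (strict; a record at exactly 150 fails). A miRNA–gene pair
survives under `intersection` (default) when both tools support it, under
`union` when either does. 3′UTR restriction is assumed already encoded in
the input records.

Dominance calls compare counts of DE miRNAs targeting each promoter-peak
gene (expression-weighted variants are out of scope):

| gene | major peak | miRNA evidence | call |
|---|---|---|---|
| down | increased | n_up > n_down | `mirna_dominant` |
| up | increased | any DE targeting | `accessibility_dominant` |
| up | increased | none | `concordant` |
| down | decreased | n_down ≥ n_up or none | `concordant` |
| other | — | any DE targeting | `ambiguous` |
| other | — | none | `untargeted` |

The count-majority rule is the stated reading of "a higher number of
upregulated miRNAs"; the verbal boundary admits no sharper numeric form.

## TF footprints and the cascade network

Differential-binding TFs: empirical quantiles over the analyzed TF set
(≥ 20 required); score > q95 → increased, < q5 → decreased; TFs passing
only the −log10 p criterion (above its 95% quantile) take their direction
from the score sign. With all-identical scores the strict inequalities
flag nothing. At most ⌈0.05·N⌉ TFs can pass per score tail.

"Bound" requires binding site ∩ peak ∩ promoter window — footprints live
inside open chromatin, so sites outside any peak are ignored. Bound-gene
direction counts use the *sign* of the expression log2FC, not the DEG
thresholds. Candidate key TFs are DEGs with a same-direction footprint
call, ranked by the fraction of same-direction bound genes, then relative
expression (mean TPM); upregulated candidates precede downregulated ones,
whose mirrored ratio is this package's extension of the stated
(upregulated-only) ordering.

The cascade expands the seed TF two layers: layer-1 = upregulated
(log2FC > 0, strictly) bound TF genes; layer-2 = upregulated TF genes
bound by any layer-1 TF, excluding the seed. A gene reachable at both
layers stays at its shallowest layer and receives no edge from deeper
layers, which keeps the graph a layered DAG. Upregulated non-TF bound
genes attach as leaves (for enrichment and the miRNA overlay) but are
never expanded. Layer-2 search uses all layer-1 TFs' sites, not only
differential-footprint ones (configurable in principle; the restriction
changes little on planted data). The overlay lists DE miRNAs whose
filtered targets intersect network nodes; downregulated miRNAs are flagged
as candidate de-repressors of the upregulated cascade.

## Enrichment

One-sided hypergeometric upper tail per GMT term, term membership
intersected with the universe at test time; significance at raw p < 0.05
with BH alongside. The default universe is the expressed genes (the
original choice is unstated); the query must be a subset of the universe.

## Synthetic data

The generator emulates the *shape* of the study data: two conditions with
3 vs 4 replicates (configurable; the recovery benchmarks use 4v4), gene
base means log-normal (µ = log 100, σ = 1), negative-binomial counts with
Var = µ + 0.05µ², planted |log2FC| = 2 on ~20% of expressed features
(`lfc_sd` jitters the magnitude; 0 keeps it exact), 10% unexpressed genes,
promoter peaks whose base intensity tracks the host gene's base expression
(the planted promoter/expression coupling) and whose planted direction
matches the gene's for coupled genes, intronic and distal peaks with
independent intensities, a planted seed→3-primary→5-secondary TF cascade
whose binding sites (midpoint within ±250 bp of the target TSS) sit inside
800 bp promoter peaks, one competitor TF with a deliberately diluted
bound-gene ratio, footprint score extremes on the planted TFs, and six
"tension" genes (expression −2, promoter peak +2, three upregulated
miRNAs targeting each). Genes pack left-to-right with 8–15 kb gaps so
neighbouring promoter windows stay disjoint; an explicit error reports
infeasible packing. Everything is deterministic given the seed.

Not emulated: sequence content (no FASTQ, motifs or Tn5 model), replicate
correlation structure from pooled litters, exon/UTR/downstream peaks
(element correlation is reported only for classes present), linked
peaks across genes, and the genome-scale peak counts that make percentage
summaries comparable to real data. Passing tests therefore demonstrate
that the *rules* recover planted structure under realistic noise — not
that the effect sizes of any real tissue will look the same.

## Benchmarks and problem sizes

The recovery benchmark scores 20 independent cohorts of 150 genes / 30
TFs / ~150 peaks / 40 miRNAs at 4v4 replicates: planted-DE recall,
promoter-correlation ordering, cascade edge precision/recall, seed-TF
ranking and miRNA-dominance recall. Null calibration draws 2000 NB null
features and checks the fraction of p < 0.05. These sizes keep the whole
suite and the acceptance script in the seconds-to-minutes range while
leaving every statistical check well-powered.

## Known limitations

- The moderated test assumes a smooth mean–variance trend; wildly
  heteroscedastic layers would need per-layer trend fits.
- Midpoint classification under-counts broad peaks spanning several
  elements by design (uniqueness was preferred over coverage).
- The cascade uses binding evidence only; no expression-based edge
  filtering beyond the log2FC > 0 rule, and no >2-layer expansion.
- Dominance calls ignore miRNA expression magnitude and target-site
  multiplicity.
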
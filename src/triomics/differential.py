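"""Count normalization, a documented stand-in differential test, and the
layer-specific classification thresholds.

The differential test is a Welch t-test on log2(CPM + 1) with
Benjamini-Hochberg adjustment. It is deliberately simple: only the labels
feed downstream, and externally computed tables (e.g. a negative-binomial
GLM fit) can be substituted via :func:`triomics.genome_io.read_differential`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import DIFFERENTIAL_COLUMNS

#: Layer-specific thresholds: strict inequalities exactly as applied upstream.
GENE_LFC_CUT = 1.0
GENE_PADJ_CUT = 0.01
MIRNA_LFC_CUT = 1.0
MIRNA_P_CUT = 0.05
PEAK_LFC_CUT = 1.5
PEAK_PADJ_CUT = 0.05


def normalize_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: each raw count divided by its column total, x 1e6.

    For ATAC peaks the column total is the number of reads mapped to all
    peaks, which is exactly the column sum of the peak count matrix.
    """
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"column {bad!r} has zero total count")
    return counts / totals * 1e6


def normalize_tpm(counts: pd.DataFrame, feature_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates rescaled to 1e6 per column."""
    lengths = feature_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"missing length for feature {missing!r}")
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"column {bad!r} has zero total rate")
    return rate / totals * 1e6


def is_expressed(counts: pd.DataFrame, min_count: int = 1, min_samples: int = 2) -> pd.Series:
    """Expression filter: raw count >= ``min_count`` in >= ``min_samples`` samples."""
    return (counts >= min_count).sum(axis=1) >= min_samples


def _split_groups(counts: pd.DataFrame, group_labels: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    labels = pd.Series(group_labels)
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(groups)}")
    g1, g2 = sorted(groups)
    cols1 = labels.index[labels == g1]
    cols2 = labels.index[labels == g2]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("each group needs >= 2 replicates (variance undefined otherwise)")
    return counts[cols1], counts[cols2]


def median_of_ratios_size_factors(table: pd.DataFrame) -> pd.Series:
    """Per-sample size factors: median ratio to the row geometric mean,
    computed over features observed in every sample. Robust to a handful of
    strongly differential features dominating the library."""
    with np.errstate(divide="ignore"):
        log_table = np.log(table.where(table > 0))
    log_table = log_table.dropna(axis=0)
    if len(log_table) == 0:
        return pd.Series(1.0, index=table.columns)
    log_ratios = log_table.sub(log_table.mean(axis=1), axis=0)
    sf = np.exp(log_ratios.median(axis=0))
    return sf / np.exp(np.log(sf).mean())  # geometric mean 1


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    from scipy.special import polygamma

    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return y


def squeeze_variances(
    s2: np.ndarray, df_resid: float, log_mean: np.ndarray
) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-feature variances toward a
    mean-variance trend.

    Per-feature sample variances are modeled as scaled chi-square draws
    around a prior variance that follows a lowess trend in the feature's
    average log abundance; the prior degrees of freedom are estimated by
    matching the moments of log sample variances. Returns the posterior
    variances and the prior df (inf when the observed spread is no larger
    than the chi-square sampling noise).
    """
    from scipy.special import polygamma, digamma
    from statsmodels.nonparametric.smoothers_lowess import lowess

    ok = s2 > 0
    floor = s2[ok].min() * 1e-3 if ok.any() else 1e-8
    z = np.log(np.maximum(s2, floor))
    if ok.sum() >= 10 and np.ptp(log_mean[ok]) > 0:
        trend = lowess(z[ok], log_mean[ok], frac=0.5, return_sorted=False)
        full_trend = np.interp(log_mean, np.sort(log_mean[ok]), trend[np.argsort(log_mean[ok])])
    else:
        full_trend = np.full_like(z, z[ok].mean() if ok.any() else 0.0)
    e = z - full_trend - float(digamma(df_resid / 2)) + np.log(df_resid / 2)
    evar = float(np.var(e[ok], ddof=1)) - float(polygamma(1, df_resid / 2)) if ok.sum() > 2 else 0.0
    # E[log s2] = log(sigma2) + digamma(d/2) - log(d/2): undo the chi-square
    # bias of the lowess fit, then add the prior's own bias term
    debias = np.log(df_resid / 2) - float(digamma(df_resid / 2))
    if evar > 0:
        df_prior = 2.0 * _trigamma_inverse(evar)
        s0 = np.exp(full_trend + debias - (np.log(df_prior / 2) - float(digamma(df_prior / 2))))
    else:
        df_prior = np.inf
        s0 = np.exp(full_trend + debias)
    if np.isinf(df_prior):
        return s0, df_prior
    post = (df_prior * s0 + df_resid * s2) / (df_prior + df_resid)
    return post, df_prior


def test_differential(
    counts: pd.DataFrame,
    group_labels: pd.Series | dict[str, str],
    method: str = "logcpm_moderated",
    pseudocount: float = 1.0,
    composition_correct: bool = True,
) -> pd.DataFrame:
    """Two-group differential test on log2(CPM + pseudocount).

    ``group_labels`` maps sample column -> group name; the log2 fold-change
    is oriented second group vs first group (groups sorted by name). CPM
    columns are first rescaled by median-of-ratios size factors
    (``composition_correct``) so an unbalanced set of strongly differential
    features cannot drag every other feature's apparent fold-change with it.

    Methods: ``logcpm_moderated`` (default) pools a per-feature variance
    across both groups and shrinks it toward a mean-variance trend with
    empirical-Bayes prior df — the moderated t that makes 3-4 replicates per
    group workable; ``logcpm_welch`` is a plain Welch t. Only the labels
    feed downstream, and externally computed tables can be dropped in via
    :func:`triomics.genome_io.read_differential`.
    """
    if method not in ("logcpm_moderated", "logcpm_welch"):
        raise ValueError(f"unknown method {method!r}")
    if isinstance(group_labels, dict):
        group_labels = pd.Series(group_labels)
    group_labels = group_labels.reindex(counts.columns)
    if group_labels.isna().any():
        missing = group_labels.index[group_labels.isna()][0]
        raise ValueError(f"sample {missing!r} has no group label")
    cpm = normalize_cpm(counts)
    if composition_correct:
        cpm = cpm / median_of_ratios_size_factors(cpm)
    log_cpm = np.log2(cpm + pseudocount)
    c1, c2 = _split_groups(log_cpm, group_labels)

    m1 = c1.mean(axis=1).to_numpy()
    m2 = c2.mean(axis=1).to_numpy()
    lfc = m2 - m1
    n1, n2 = c1.shape[1], c2.shape[1]
    if method == "logcpm_welch":
        _, p = stats.ttest_ind(c2.to_numpy(), c1.to_numpy(), axis=1, equal_var=False)
        # Welch is undefined when both groups are constant: identical means
        # is the null exactly (p = 1), a shift with zero variance is maximal
        # evidence.
        p = np.asarray(p, dtype=float)
        degenerate = ~np.isfinite(p)
        p[degenerate & (lfc == 0)] = 1.0
        p[degenerate & (lfc != 0)] = 0.0
    else:
        df_resid = n1 + n2 - 2
        rss = ((c1.to_numpy() - m1[:, None]) ** 2).sum(axis=1) + (
            (c2.to_numpy() - m2[:, None]) ** 2
        ).sum(axis=1)
        s2 = rss / df_resid
        s2_post, df_prior = squeeze_variances(s2, df_resid, log_cpm.mean(axis=1).to_numpy())
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, lfc / se, 0.0)
        df_use = df_resid + df_prior if not np.isinf(df_prior) else 1e6
        p = 2.0 * stats.t.sf(np.abs(t), df_use)
        p = np.where((se == 0) & (lfc == 0), 1.0, p)
    padj = multipletests(p, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "feature_id": counts.index,
            "base_mean": cpm.mean(axis=1).to_numpy(),
            "log2fc": lfc,
            "pvalue": p,
            "padj": padj,
            "label": "ns",
        },
        columns=DIFFERENTIAL_COLUMNS,
    ).reset_index(drop=True)


def _classify(
    results: pd.DataFrame,
    lfc_cut: float,
    sig_col: str,
    sig_cut: float,
    expressed: pd.Series | None,
    up_label: str = "up",
    down_label: str = "down",
) -> pd.DataFrame:
    out = results.copy()
    sig = out[sig_col] < sig_cut
    labels = np.where(
        (out["log2fc"] > lfc_cut) & sig,
        up_label,
        np.where((out["log2fc"] < -lfc_cut) & sig, down_label, "ns"),
    )
    if expressed is not None:
        mask = ~expressed.reindex(out["feature_id"]).fillna(False).to_numpy(dtype=bool)
        labels = np.where(mask, "unexpressed", labels)
    out["label"] = labels
    return out


def classify_genes(
    results: pd.DataFrame,
    lfc_cut: float = GENE_LFC_CUT,
    padj_cut: float = GENE_PADJ_CUT,
    expressed: pd.Series | None = None,
) -> pd.DataFrame:
    """Label genes up/down at |log2FC| > 1 and adjusted p < 0.01 (strict).

    ``expressed`` (boolean per feature) routes filtered genes to
    'unexpressed' before thresholding.
    """
    return _classify(results, lfc_cut, "padj", padj_cut, expressed)


def classify_mirnas(
    results: pd.DataFrame,
    lfc_cut: float = MIRNA_LFC_CUT,
    p_cut: float = MIRNA_P_CUT,
    expressed: pd.Series | None = None,
) -> pd.DataFrame:
    """Label miRNAs at |log2FC| > 1 and RAW p < 0.05 (the miRNA layer
    thresholds on the unadjusted p-value)."""
    return _classify(results, lfc_cut, "pvalue", p_cut, expressed)


def classify_peaks(
    results: pd.DataFrame,
    lfc_cut: float = PEAK_LFC_CUT,
    padj_cut: float = PEAK_PADJ_CUT,
) -> pd.DataFrame:
    """Label peaks increased/decreased at |log2FC| > 1.5 and adjusted p < 0.05."""
    return _classify(results, lfc_cut, "padj", padj_cut, None, up_label="increased", down_label="decreased")


def flag_highly_accessible(
    cpm: pd.DataFrame,
    group_labels: pd.Series | dict[str, str],
    log_cpm_cut: float = 5.0,
    log_base: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Flag peaks whose log group-mean CPM exceeds ``log_cpm_cut``.

    CPM is averaged within each group first, the two group means are averaged
    (balanced with unequal replicate numbers), and the log is taken last; the
    log base defaults to 2. Both the base and the cut are configurable.
    """
    if isinstance(group_labels, dict):
        group_labels = pd.Series(group_labels)
    group_labels = group_labels.reindex(cpm.columns)
    group_means = cpm.T.groupby(group_labels).mean().T
    pooled = group_means.mean(axis=1)
    return np.log(pooled + pseudocount) / np.log(log_base) > log_cpm_cut
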
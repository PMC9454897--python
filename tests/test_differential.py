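"""Normalization, the stand-in differential test, and threshold labeling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from triomics import differential as de


class TestNormalization:
    def test_cpm_simple_column(self):
        counts = pd.DataFrame({"s1": [1, 1, 2]}, index=["a", "b", "c"])
        cpm = de.normalize_cpm(counts)
        assert cpm["s1"].tolist() == [250_000.0, 250_000.0, 500_000.0]

    def test_cpm_uniform_column(self):
        counts = pd.DataFrame({"s1": [7] * 8}, index=list("abcdefgh"))
        assert np.allclose(de.normalize_cpm(counts)["s1"], 1e6 / 8)

    def test_cpm_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 1000, size=(100, 4)))
        sums = de.normalize_cpm(counts).sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_cpm_zero_column_raises(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]})
        with pytest.raises(ValueError, match="zero total"):
            de.normalize_cpm(counts)

    def test_tpm_length_ratio(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["a", "b"])
        tpm = de.normalize_tpm(counts, pd.Series({"a": 100, "b": 200}))
        assert tpm.at["a", "s1"] / tpm.at["b", "s1"] == pytest.approx(2.0)
        assert tpm["s1"].sum() == pytest.approx(1e6)

    def test_tpm_single_feature_is_one_million(self):
        counts = pd.DataFrame({"s1": [42]}, index=["a"])
        assert de.normalize_tpm(counts, pd.Series({"a": 500})).iat[0, 0] == pytest.approx(1e6)

    def test_tpm_matches_brute_force(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 500, size=(30, 3)), index=[f"g{i}" for i in range(30)])
        lengths = pd.Series(rng.integers(100, 5000, size=30), index=counts.index)
        tpm = de.normalize_tpm(counts, lengths)
        rate = counts.to_numpy() / lengths.to_numpy()[:, None]
        expected = rate / rate.sum(axis=0) * 1e6
        assert np.allclose(tpm.to_numpy(), expected)

    def test_tpm_missing_length_raises(self):
        counts = pd.DataFrame({"s1": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValueError, match="missing length"):
            de.normalize_tpm(counts, pd.Series({"a": 100}))


class TestDifferentialTest:
    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(2)
        block = rng.integers(10, 100, size=(20, 3))
        counts = pd.DataFrame(
            np.hstack([block, block]),
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
        res = de.test_differential(counts, groups)
        assert np.allclose(res["log2fc"], 0)
        assert np.allclose(res["pvalue"], 1)

    @pytest.mark.parametrize("method", ["logcpm_moderated", "logcpm_welch"])
    def test_single_replicate_raises(self, method):
        counts = pd.DataFrame(np.ones((5, 3)), columns=["a1", "b1", "b2"])
        groups = pd.Series(["A", "B", "B"], index=counts.columns)
        with pytest.raises(ValueError, match="replicates"):
            de.test_differential(counts, groups, method=method)

    def test_group_swap_negates_lfc_and_swaps_labels(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.negative_binomial(20, 0.1, size=(50, 8)),
            columns=[f"s{j}" for j in range(8)],
        ) + 1
        fwd = pd.Series(["A"] * 4 + ["B"] * 4, index=counts.columns)
        rev = pd.Series(["B"] * 4 + ["A"] * 4, index=counts.columns)
        r1 = de.classify_genes(de.test_differential(counts, fwd))
        r2 = de.classify_genes(de.test_differential(counts, rev))
        assert np.allclose(r1["log2fc"], -r2["log2fc"], atol=1e-10)
        swap = {"up": "down", "down": "up", "ns": "ns"}
        assert [swap[l] for l in r1["label"]] == list(r2["label"])

    def test_column_order_invariance(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(
            rng.integers(1, 200, size=(30, 6)), columns=[f"s{j}" for j in range(6)]
        )
        groups = pd.Series(["A", "B", "A", "B", "A", "B"], index=counts.columns)
        r1 = de.test_differential(counts, groups)
        shuffled = counts[["s5", "s2", "s1", "s4", "s3", "s0"]]
        r2 = de.test_differential(shuffled, groups.reindex(shuffled.columns))
        assert np.allclose(r1["pvalue"], r2["pvalue"])
        assert np.allclose(r1["log2fc"], r2["log2fc"])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=3, max_size=50))
    def test_bh_adjustment_matches_sorted_rank_oracle(self, pvals):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(pvals, method="fdr_bh")[1]
        # brute-force BH: sort, scale by m/rank, enforce monotonicity from the top
        m = len(pvals)
        order = np.argsort(pvals)
        scaled = np.array(pvals)[order] * m / np.arange(1, m + 1)
        running = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(running, 1.0)
        assert np.allclose(adj, expected)


class TestClassification:
    @pytest.mark.parametrize(
        "lfc,padj,label",
        [
            (1.92, 0.0002, "up"),     # strong induction passes both cuts
            (0.44, 0.001, "ns"),      # significant p but sub-threshold effect
            (0.83, 0.077, "ns"),      # moderate induction, weak significance
            (0.0, 1.0, "ns"),
            (-2.5, 0.004, "down"),
            (1.0, 0.0001, "ns"),      # boundary: strict inequality on lfc
            (1.5, 0.01, "ns"),        # boundary: strict inequality on padj
        ],
    )
    def test_gene_thresholds(self, lfc, padj, label):
        res = pd.DataFrame(
            {"feature_id": ["g"], "base_mean": [10.0], "log2fc": [lfc],
             "pvalue": [padj / 2], "padj": [padj], "label": ["ns"]}
        )
        assert de.classify_genes(res)["label"].iloc[0] == label

    @pytest.mark.parametrize(
        "lfc,p,label",
        [(1.2, 0.01, "up"), (1.2, 0.06, "ns"), (-3.0, 1e-4, "down")],
    )
    def test_mirna_thresholds_use_raw_p(self, lfc, p, label):
        res = pd.DataFrame(
            {"feature_id": ["m"], "base_mean": [10.0], "log2fc": [lfc],
             "pvalue": [p], "padj": [min(1.0, p * 10)], "label": ["ns"]}
        )
        assert de.classify_mirnas(res)["label"].iloc[0] == label

    @pytest.mark.parametrize(
        "lfc,padj,label",
        [(1.6, 0.01, "increased"), (1.4, 0.001, "ns"), (-2.0, 0.04, "decreased")],
    )
    def test_peak_thresholds(self, lfc, padj, label):
        res = pd.DataFrame(
            {"feature_id": ["p"], "base_mean": [10.0], "log2fc": [lfc],
             "pvalue": [padj / 2], "padj": [padj], "label": ["ns"]}
        )
        assert de.classify_peaks(res)["label"].iloc[0] == label

    def test_expression_filter_routes_to_unexpressed(self):
        counts = pd.DataFrame(
            {"s1": [5, 0, 1], "s2": [6, 0, 0], "s3": [7, 1, 0], "s4": [8, 0, 0]},
            index=["expressed", "silent", "one_sample"],
        )
        expressed = de.is_expressed(counts)
        res = pd.DataFrame(
            {"feature_id": counts.index, "base_mean": 1.0, "log2fc": 3.0,
             "pvalue": 1e-6, "padj": 1e-5, "label": "ns"}
        )
        labels = de.classify_genes(res, expressed=expressed)["label"].tolist()
        assert labels == ["up", "unexpressed", "unexpressed"]

    def test_labels_partition_features(self, result):
        for table in (result.gene_results, result.mirna_results, result.peak_results):
            counts = table["label"].value_counts()
            assert counts.sum() == len(table)


class TestHighlyAccessible:
    def test_flagging_examples(self):
        cpm = pd.DataFrame({"a1": [100.0, 10.0], "b1": [100.0, 10.0]}, index=["hi", "lo"])
        groups = {"a1": "A", "b1": "B"}
        flags = de.flag_highly_accessible(cpm, groups)
        assert flags.tolist() == [True, False]

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(5)
        cpm = pd.DataFrame(
            rng.uniform(0, 300, size=(40, 4)), columns=["a1", "a2", "b1", "b2"]
        )
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        flags = de.flag_highly_accessible(cpm, groups)
        for i in range(len(cpm)):
            pooled = (cpm.iloc[i, :2].mean() + cpm.iloc[i, 2:].mean()) / 2
            assert flags.iloc[i] == (np.log2(pooled + 1) > 5)
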
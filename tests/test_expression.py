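"""FPKM, normalization, NB dispersion, Wald DE, DEG rule, quartiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from epilink._rand import substream
from epilink.expression import (
    classify_expression,
    compute_fpkm,
    de_pipeline,
    estimate_nb_dispersion,
    expressed_gene_sets,
    filter_degs,
    median_of_ratios,
    wald_test_de,
)

SAMPLES = ["PC_1", "PC_2", "PC_3", "NC_1", "NC_2", "NC_3"]
GROUPS = {s: s[:2] for s in SAMPLES}


def _nb_counts(rng, mu, alpha, n_samples=6):
    cols = {}
    for j, s in enumerate(SAMPLES[:n_samples]):
        lam = rng.gamma(1.0 / alpha, mu * alpha) if alpha > 0 else mu
        cols[s] = rng.poisson(lam)
    return pd.DataFrame(cols, index=[f"g{i}" for i in range(len(mu))])


class TestFpkm:
    @pytest.mark.parametrize(
        "count,length,lib,expected",
        [(100, 1000, 1_000_000, 100.0), (0, 1000, 1_000_000, 0.0), (10, 500, 2_000_000, 10.0)],
    )
    def test_hand_computed(self, count, length, lib, expected):
        counts = pd.DataFrame({"s": [count]}, index=["g"])
        fpkm = compute_fpkm(counts, pd.Series({"g": length}), pd.Series({"s": lib}))
        assert fpkm.loc["g", "s"] == pytest.approx(expected)

    @given(st.integers(1, 10_000), st.integers(50, 100_000), st.integers(1, 50))
    def test_linearity(self, count, length, k):
        counts = pd.DataFrame({"s": [count]}, index=["g"])
        lens = pd.Series({"g": length})
        lib = pd.Series({"s": 2_000_000})
        base = compute_fpkm(counts, lens, lib).iloc[0, 0]
        assert compute_fpkm(counts * k, lens, lib).iloc[0, 0] == pytest.approx(k * base)
        assert compute_fpkm(counts, lens * k, lib).iloc[0, 0] == pytest.approx(base / k)

    def test_zero_library_is_error(self):
        counts = pd.DataFrame({"s": [0]}, index=["g"])
        with pytest.raises(ValueError):
            compute_fpkm(counts, pd.Series({"g": 100}), pd.Series({"s": 0}))


class TestMedianOfRatios:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        np.testing.assert_allclose(median_of_ratios(counts), 1.0)

    def test_doubled_column(self):
        counts = pd.DataFrame({"a": [10, 20, 30, 40], "b": [20, 40, 60, 80]})
        s = median_of_ratios(counts)
        assert s["b"] / s["a"] == pytest.approx(2.0)

    def test_matches_literal_definition_oracle(self):
        rng = substream(3, "mor-oracle")
        counts = _nb_counts(rng, np.exp(rng.normal(5, 1, 300)), 0.1) + 1
        s = median_of_ratios(counts)
        # brute force: ratios to geometric means, then medians, rescaled
        mat = counts.to_numpy(dtype=float)
        geo = np.exp(np.mean(np.log(mat), axis=1))
        raw = np.median(mat / geo[:, None], axis=0)
        raw /= np.exp(np.mean(np.log(raw)))
        np.testing.assert_allclose(s.to_numpy(), raw, rtol=1e-12)

    def test_robust_to_rescaling_one_gene(self):
        rng = substream(4, "mor-robust")
        counts = _nb_counts(rng, np.full(99, 200.0), 0.05) + 1
        before = median_of_ratios(counts)
        counts.iloc[0] = counts.iloc[0] * 50
        after = median_of_ratios(counts)
        np.testing.assert_allclose(before, after, rtol=1e-9)

    def test_no_universally_expressed_gene_is_error(self):
        counts = pd.DataFrame({"a": [1, 0], "b": [0, 1]})
        with pytest.raises(ValueError):
            median_of_ratios(counts)


class TestNbDispersion:
    def test_poisson_counts_give_near_zero_alpha(self):
        rng = substream(5, "poisson-alpha")
        counts = _nb_counts(rng, np.full(1000, 100.0), 0.0)
        alpha = estimate_nb_dispersion(counts.astype(float), pd.Series(GROUPS))
        assert alpha.median() <= 0.05

    def test_recovers_planted_alpha(self):
        rng = substream(6, "nb-recovery")
        counts = _nb_counts(rng, np.exp(rng.normal(np.log(300), 1.0, 2000)), 0.2)
        sf = median_of_ratios(counts + 1)
        alpha = estimate_nb_dispersion((counts / sf).astype(float), pd.Series(GROUPS))
        assert 0.12 <= alpha.median() <= 0.28

    def test_constant_gene_hits_floor(self):
        counts = pd.DataFrame({s: [50] for s in SAMPLES}, index=["g"], dtype=float)
        counts = pd.concat([counts] * 5, ignore_index=True)
        alpha = estimate_nb_dispersion(counts, pd.Series(GROUPS))
        assert (alpha <= 1e-6).all()


class TestWaldDe:
    def test_identical_groups_null_result(self):
        counts = pd.DataFrame({s: [100, 300, 50] for s in SAMPLES})
        res = wald_test_de(
            counts,
            pd.Series(1.0, index=SAMPLES),
            pd.Series(0.05, index=counts.index),
            pd.Series(GROUPS),
        )
        np.testing.assert_allclose(res["log2fc"], 0.0)
        np.testing.assert_allclose(res["p_value"], 1.0)

    def test_one_replicate_group_is_error(self):
        counts = pd.DataFrame({"PC_1": [10], "NC_1": [10], "NC_2": [12]})
        with pytest.raises(ValueError, match="replicates"):
            wald_test_de(
                counts,
                pd.Series(1.0, index=counts.columns),
                pd.Series(0.05, index=counts.index),
                pd.Series({"PC_1": "PC", "NC_1": "NC", "NC_2": "NC"}),
            )

    def test_all_zero_genes_excluded_from_testing(self):
        counts = pd.DataFrame({s: [100, 0] for s in SAMPLES})
        res = wald_test_de(
            counts,
            pd.Series(1.0, index=SAMPLES),
            pd.Series(0.05, index=counts.index),
            pd.Series(GROUPS),
        )
        assert len(res) == 1

    def test_agrees_with_independent_deseq2_implementation(self):
        # cross-check of effect estimates against pydeseq2 (never used as
        # the implementation) on a planted-fold-change simulation
        rng = substream(7, "deseq-xcheck")
        n = 250
        mu = np.exp(rng.normal(np.log(300), 1.0, n))
        fc = np.zeros(n)
        idx = rng.choice(n, 25, replace=False)
        fc[idx] = rng.choice([2.0, -2.0], 25)
        cols = {}
        for s in SAMPLES:
            m = mu * 2**fc if s.startswith("PC") else mu
            cols[s] = rng.poisson(rng.gamma(1 / 0.05, m * 0.05))
        counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(n)])

        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        meta = pd.DataFrame({"condition": [GROUPS[s] for s in SAMPLES]}, index=SAMPLES)
        dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~condition", quiet=True)
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", "PC", "NC"], quiet=True)
        stats.summary()
        ref = stats.results_df

        mine = de_pipeline(counts, GROUPS)["results"]
        joined = mine.join(ref[["log2FoldChange"]], how="inner").dropna()
        r = np.corrcoef(joined["log2fc"], joined["log2FoldChange"])[0, 1]
        assert r > 0.99
        assert (joined["log2fc"] - joined["log2FoldChange"]).abs().median() < 0.1


class TestFilterDegs:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["log2fc", "padj"],
                            index=[f"g{i}" for i in range(len(rows))])

    def test_boundary_log2fc_excluded(self):
        # |log2FC| must be strictly greater than 1
        up, down = filter_degs(self._frame([(1.0, 0.001)]))
        assert up == set() and down == set()

    def test_down_regulated(self):
        up, down = filter_degs(self._frame([(-2.0, 0.01)]))
        assert down == {"g0"} and up == set()

    def test_nonsignificant_padj_excluded(self):
        up, down = filter_degs(self._frame([(3.0, 0.06)]))
        assert up == set() and down == set()


class TestClassifyExpression:
    def test_below_one_is_no_expression(self):
        fpkm = pd.Series([0.5, 1, 2, 3, 4, 5, 6, 7, 8], index=list("abcdefghi"))
        out = classify_expression(fpkm)
        assert out.loc["a", "expression_class"] == "no"

    def test_printed_quartile_example(self):
        # expressed set {1..8}: Q1 = 2.75, Q3 = 6.25 by linear interpolation
        fpkm = pd.Series([1, 2, 3, 4, 5, 6, 7, 8], index=list("abcdefgh"), dtype=float)
        assert np.quantile(fpkm, 0.25) == pytest.approx(2.75)
        assert np.quantile(fpkm, 0.75) == pytest.approx(6.25)
        out = classify_expression(fpkm)
        assert out.loc["c", "expression_class"] == "medium"  # FPKM 3
        assert out.loc["a", "expression_class"] == "low"
        assert out.loc["h", "expression_class"] == "high"

    def test_value_equal_to_upper_quartile_is_high(self):
        fpkm = pd.Series([1, 2, 3, 4, 5, 6, 7, 8], index=list("abcdefgh"), dtype=float)
        out = classify_expression(fpkm)
        # 6.25 is Q3; the smallest value >= Q3 present is 7
        assert (out.loc[out["fpkm"] >= 6.25, "expression_class"] == "high").all()

    def test_too_few_expressed_genes_is_error(self):
        with pytest.raises(ValueError):
            classify_expression(pd.Series([0.1, 0.2, 1.5, 2.0]))


class TestExpressedSets:
    def _fpkm(self, pc, nc):
        genes = [f"g{i}" for i in range(len(pc))]
        return pd.DataFrame(
            {s: pc if s.startswith("PC") else nc for s in SAMPLES}, index=genes, dtype=float
        )

    def test_identical_groups_have_no_exclusive_genes(self):
        fpkm = self._fpkm([5, 0.2, 3], [5, 0.2, 3])
        sets = expressed_gene_sets(fpkm, pd.Series(GROUPS))
        assert sets["exclusive_PC"] == set() and sets["exclusive_NC"] == set()
        assert sets["shared"] == {"g0", "g2"}

    def test_group_exclusive_gene(self):
        fpkm = self._fpkm([5, 4], [5, 0.1])
        sets = expressed_gene_sets(fpkm, pd.Series(GROUPS))
        assert sets["exclusive_PC"] == {"g1"}

    def test_disjoint_sets_share_nothing(self):
        fpkm = self._fpkm([5, 0.1], [0.1, 5])
        sets = expressed_gene_sets(fpkm, pd.Series(GROUPS))
        assert sets["shared"] == set()
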
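"""Metagene profiles, methylation-expression correlation, enrichment."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from epilink.annotation import GeneModel
from epilink.integrate import (
    build_integration_records,
    correlate_dmg_expression,
    hypergeometric_enrichment,
    metagene_profile,
    overlap_dmg_deg,
)


def _uniform_methylome(contigs, ml=0.5, depth=10, step=50, length=30_000):
    rows = []
    for c in contigs:
        for pos in range(1, length, step):
            rows.append((c, pos, ".", int(ml * depth), depth - int(ml * depth)))
    return pd.DataFrame(rows, columns=["contig", "pos", "strand", "count_m", "count_u"])


GROUPS = {"PC_1": "PC", "NC_1": "NC"}


class TestMetageneProfile:
    def test_uniform_methylome_gives_flat_profiles(self):
        genes = [
            GeneModel("g1", "chr1", "+", 8001, 12_000, ((8001, 12_000),)),
            GeneModel("g2", "chr1", "-", 18_001, 22_000, ((18_001, 22_000),)),
        ]
        meth = {s: _uniform_methylome(["chr1"]) for s in GROUPS}
        classes = pd.Series({"g1": "high", "g2": "no"})
        prof = metagene_profile(meth, GROUPS, genes, classes)
        assert set(prof["group"]) == {"PC", "NC"}
        covered = prof.dropna(subset=["mean_ml"])
        np.testing.assert_allclose(covered["mean_ml"], 0.5)
        assert prof["bin"].max() == 99

    def test_strand_symmetry(self):
        # a minus-strand gene with mirror-image methylation yields the
        # same profile as its plus-strand twin
        L = 30_000
        rows_f, rows_r = [], []
        rng = np.random.default_rng(0)
        for pos in range(1, L, 40):
            ml = rng.uniform(0.1, 0.9)
            m = int(round(ml * 10))
            rows_f.append(("chr1", pos, ".", m, 10 - m))
            rows_r.append(("chr1", L - pos + 1, ".", m, 10 - m))
        cols = ["contig", "pos", "strand", "count_m", "count_u"]
        meth_f = {s: pd.DataFrame(rows_f, columns=cols) for s in GROUPS}
        meth_r = {s: pd.DataFrame(rows_r, columns=cols) for s in GROUPS}
        g_f = GeneModel("g", "chr1", "+", 10_001, 16_000, ((10_001, 16_000),))
        g_r = GeneModel("g", "chr1", "-", L - 16_000 + 1, L - 10_001 + 1,
                        ((L - 16_000 + 1, L - 10_001 + 1),))
        classes = pd.Series({"g": "medium"})
        p_f = metagene_profile(meth_f, GROUPS, [g_f], classes)
        p_r = metagene_profile(meth_r, GROUPS, [g_r], classes)
        a = p_f[p_f["group"] == "PC"].sort_values("bin")["mean_ml"].to_numpy()
        b = p_r[p_r["group"] == "PC"].sort_values("bin")["mean_ml"].to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_gene_order_invariance(self):
        genes = [
            GeneModel("g1", "chr1", "+", 8001, 12_000, ((8001, 12_000),)),
            GeneModel("g2", "chr1", "+", 18_001, 22_000, ((18_001, 22_000),)),
        ]
        meth = {s: _uniform_methylome(["chr1"]) for s in GROUPS}
        classes = pd.Series({"g1": "high", "g2": "high"})
        a = metagene_profile(meth, GROUPS, genes, classes)
        b = metagene_profile(meth, GROUPS, genes[::-1], classes)
        pd.testing.assert_frame_equal(
            a.sort_values(["group", "bin"]).reset_index(drop=True),
            b.sort_values(["group", "bin"]).reset_index(drop=True),
        )

    def test_hypomethylated_promoters_of_high_class_show_in_upstream_bins(self):
        rng = np.random.default_rng(1)
        genes, rows = [], []
        for i in range(12):
            start = 10_001 + i * 20_000
            gid = f"g{i}"
            hypo = i < 6  # first six genes: high expression, low promoter ML
            genes.append(GeneModel(gid, "chr1", "+", start, start + 4000,
                                   ((start, start + 4000),)))
            for pos in range(start - 2500, start + 6500, 40):
                in_promoter = pos < start
                ml = 0.1 if (hypo and in_promoter) else 0.8
                m = rng.binomial(20, ml)
                rows.append(("chr1", pos, ".", m, 20 - m))
        meth = {s: pd.DataFrame(rows, columns=["contig", "pos", "strand", "count_m", "count_u"])
                for s in GROUPS}
        classes = pd.Series({f"g{i}": ("high" if i < 6 else "no") for i in range(12)})
        prof = metagene_profile(meth, GROUPS, genes, classes)
        pc = prof[prof["group"] == "PC"]
        up_high = pc[(pc["expression_class"] == "high") & (pc["bin"] < 20)]["mean_ml"].mean()
        up_no = pc[(pc["expression_class"] == "no") & (pc["bin"] < 20)]["mean_ml"].mean()
        assert up_high < up_no - 0.3


class TestCorrelation:
    def _records(self, pairs, cls="promoter"):
        return pd.DataFrame(
            [
                {"gene_id": f"g{i}", "region_class": cls, "delta_ml": x,
                 "delta_expr": y, "is_dmg": True, "is_deg": False}
                for i, (x, y) in enumerate(pairs)
            ]
        )

    def test_perfect_antimonotone(self):
        rho, p = correlate_dmg_expression(self._records([(1, -1), (2, -2), (3, -3)]), "promoter")
        assert rho == pytest.approx(-1.0)

    def test_perfect_monotone(self):
        rho, _ = correlate_dmg_expression(self._records([(1, 1), (2, 2), (3, 3)]), "promoter")
        assert rho == pytest.approx(1.0)

    def test_exact_permutation_p_for_monotone_n5(self):
        # only the identity and the reversal reach |rho| = 1: p = 2/5!
        pairs = [(i, i) for i in range(5)]
        _, p = correlate_dmg_expression(self._records(pairs), "promoter")
        assert p == pytest.approx(2 / math.factorial(5))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        base, _ = correlate_dmg_expression(self._records(list(zip(x, y))), "promoter")
        warped, _ = correlate_dmg_expression(
            self._records(list(zip(np.exp(x), y**3))), "promoter"
        )
        # note: y**3 is monotone; exp is monotone
        assert warped == pytest.approx(base)

    def test_constant_input_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            correlate_dmg_expression(self._records([(1, 1), (1, 2), (1, 3)]), "promoter")

    def test_too_few_records_is_error(self):
        with pytest.raises(ValueError, match=">= 3"):
            correlate_dmg_expression(self._records([(1, 1), (2, 2)]), "promoter")


class TestOverlap:
    def test_disjoint_sets_empty(self):
        dmgs = pd.DataFrame(
            [{"gene_id": "gA", "region_class": "promoter", "direction": "hyper", "dmr_ids": "d1"}]
        )
        de = pd.DataFrame({"log2fc": [2.0], "padj": [0.01], "is_deg": [True]}, index=["gB"])
        assert len(overlap_dmg_deg(dmgs, de)) == 0

    def test_union_semantics_single_row_per_gene(self):
        dmgs = pd.DataFrame(
            [
                {"gene_id": "gA", "region_class": "promoter", "direction": "hyper", "dmr_ids": "d1"},
                {"gene_id": "gA", "region_class": "gene_body", "direction": "hyper", "dmr_ids": "d2"},
            ]
        )
        de = pd.DataFrame({"log2fc": [-2.0], "padj": [0.001], "is_deg": [True]}, index=["gA"])
        out = overlap_dmg_deg(dmgs, de)
        assert len(out) == 1
        assert out.iloc[0]["region_classes"] == "gene_body,promoter"


class TestIntegrationRecords:
    def test_delta_ml_is_cpg_weighted_mean(self):
        dmgs = pd.DataFrame(
            [{"gene_id": "gA", "region_class": "promoter", "direction": "hyper",
              "dmr_ids": "d1,d2"}]
        )
        dmrs = pd.DataFrame(
            {"dmr_id": ["d1", "d2"], "contig": "c", "start": [0, 100], "end": [50, 150],
             "n_cpg": [3, 9], "delta": [0.2, 0.4]}
        )
        de = pd.DataFrame({"log2fc": [1.5], "padj": [0.01], "is_deg": [True]}, index=["gA"])
        rec = build_integration_records(dmgs, dmrs, de)
        assert rec.iloc[0]["delta_ml"] == pytest.approx((3 * 0.2 + 9 * 0.4) / 12)
        assert rec.iloc[0]["delta_expr"] == pytest.approx(1.5)


def hypergeom_oracle(N, K, n, k_obs):
    """Brute force: enumerate every n-subset of an N-element universe."""
    universe = range(N)
    term = set(range(K))
    hits = total = 0
    for draw in combinations(universe, n):
        total += 1
        if len(term & set(draw)) >= k_obs:
            hits += 1
    return hits / total


class TestEnrichment:
    def _run(self, N, K, n, k):
        universe = {f"g{i}" for i in range(N)}
        term_genes = frozenset(f"g{i}" for i in range(K))
        query = {f"g{i}" for i in range(k)} | {f"g{K + i}" for i in range(n - k)}
        assert len(query) == n
        sets = {"T": ("term", term_genes)}
        return hypergeometric_enrichment(query, sets, universe)

    def test_full_overlap_small_universe(self):
        # query of 5, term of 5, overlap 5 in a 20-gene universe
        out = self._run(20, 5, 5, 5)
        assert out.iloc[0]["p_value"] == pytest.approx(1 / math.comb(20, 5))

    def test_no_overlap_is_near_one(self):
        out = self._run(20, 3, 5, 0)
        assert out.iloc[0]["p_value"] == pytest.approx(1.0)

    @pytest.mark.parametrize("N", [5, 8, 12])
    def test_matches_exhaustive_enumeration(self, N):
        for K in range(1, N + 1):
            for n in range(1, N + 1):
                for k in range(0, min(K, n) + 1):
                    if n - k > N - K:
                        continue
                    out = self._run(N, K, n, k)
                    assert out.iloc[0]["p_value"] == pytest.approx(
                        hypergeom_oracle(N, K, n, k), rel=1e-9
                    ), (N, K, n, k)

    def test_empty_query_is_error(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(set(), {"T": ("t", frozenset({"g1"}))}, {"g1"})

    def test_query_outside_universe_is_error(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment({"x"}, {"T": ("t", frozenset({"g1"}))}, {"g1"})
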
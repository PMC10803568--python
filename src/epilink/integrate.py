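"""Methylome-transcriptome integration.

Joins the DMR/DMG output with differential expression: metagene
methylation profiles stratified by expression quartile class, Spearman
correlation between differential methylation and differential expression
of DMGs (expected negative at promoters, positive over gene bodies),
DMG-DEG overlap, and hypergeometric gene-set enrichment against
user-supplied GMT collections.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import GeneModel

__all__ = [
    "pool_group_methylation",
    "metagene_profile",
    "build_integration_records",
    "correlate_dmg_expression",
    "overlap_dmg_deg",
    "hypergeometric_enrichment",
]


def pool_group_methylation(
    methylomes: dict[str, pd.DataFrame], group_map: dict[str, str]
) -> dict[str, pd.DataFrame]:
    """Sum counts across replicates of each group, per CpG."""
    out = {}
    for g in sorted(set(group_map.values()), reverse=True):
        frames = [df for s, df in methylomes.items() if group_map[s] == g]
        pooled = (
            pd.concat(frames, ignore_index=True)
            .groupby(["contig", "pos"], as_index=False, sort=True)[["count_m", "count_u"]]
            .sum()
        )
        out[g] = pooled
    return out


def _gene_bin_means(
    pos0: np.ndarray,
    ml: np.ndarray,
    gene: GeneModel,
    flank: int,
    body_bins: int,
    flank_bins: int,
) -> np.ndarray:
    """Mean ML per metagene bin for one gene (NaN where no site)."""
    total = 2 * flank_bins + body_bins
    body_start, body_end = gene.start - 1, gene.end
    body_len = body_end - body_start
    lo, hi = body_start - flank, body_end + flank
    i0, i1 = np.searchsorted(pos0, [lo, hi])
    p = pos0[i0:i1]
    v = ml[i0:i1]
    if len(p) == 0:
        return np.full(total, np.nan)
    bin_size = flank / flank_bins
    idx = np.empty(len(p), dtype=int)
    left = p < body_start
    right = p >= body_end
    body = ~left & ~right
    idx[left] = np.minimum(((p[left] - lo) / bin_size).astype(int), flank_bins - 1)
    idx[body] = flank_bins + np.minimum(
        ((p[body] - body_start) / body_len * body_bins).astype(int), body_bins - 1
    )
    idx[right] = (
        flank_bins
        + body_bins
        + np.minimum(((p[right] - body_end) / bin_size).astype(int), flank_bins - 1)
    )
    if gene.strand == "-":
        idx = total - 1 - idx
    sums = np.bincount(idx, weights=v, minlength=total)
    counts = np.bincount(idx, minlength=total)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def metagene_profile(
    methylomes: dict[str, pd.DataFrame],
    group_map: dict[str, str],
    genes: list[GeneModel],
    expression_classes: pd.Series,
    flank: int = 2000,
    body_bins: int = 60,
    flank_bins: int = 20,
    min_depth: int = 5,
) -> pd.DataFrame:
    """Average methylation over scaled gene bodies plus 2-kb flanks.

    Bins run 5' -> 3' (minus-strand genes are reversed): ``flank_bins``
    fixed-width upstream bins, ``body_bins`` gene-length-scaled body
    bins, ``flank_bins`` downstream bins.  Within each expression class
    and group the per-bin value is the unweighted mean over genes with
    coverage in that bin.  Tidy output: expression_class, group, bin,
    mean_ml, n_genes.
    """
    pooled = pool_group_methylation(methylomes, group_map)
    total = 2 * flank_bins + body_bins
    rows = []
    for group, df in pooled.items():
        cov = df["count_m"] + df["count_u"]
        df = df.loc[cov >= min_depth].copy()
        df["ml"] = df["count_m"] / (df["count_m"] + df["count_u"])
        by_contig = {
            c: (sub["pos"].to_numpy() - 1, sub["ml"].to_numpy())
            for c, sub in df.groupby("contig", sort=False)
        }
        per_class: dict[str, list[np.ndarray]] = {}
        for gene in genes:
            if gene.contig not in by_contig:
                continue
            cls = expression_classes.get(gene.gene_id)
            if cls is None or (isinstance(cls, float) and np.isnan(cls)):
                continue
            pos0, ml = by_contig[gene.contig]
            per_class.setdefault(cls, []).append(
                _gene_bin_means(pos0, ml, gene, flank, body_bins, flank_bins)
            )
        for cls, mats in per_class.items():
            stack = np.vstack(mats)
            with np.errstate(invalid="ignore"):
                mean = np.nanmean(stack, axis=0)
            n_genes = np.sum(~np.isnan(stack), axis=0)
            for b in range(total):
                rows.append(
                    {
                        "expression_class": cls,
                        "group": group,
                        "bin": b,
                        "mean_ml": mean[b],
                        "n_genes": int(n_genes[b]),
                    }
                )
    return pd.DataFrame(rows)


def build_integration_records(
    dmgs: pd.DataFrame, dmrs: pd.DataFrame, de_results: pd.DataFrame
) -> pd.DataFrame:
    """One record per (DMG, region_class).

    delta_ml aggregates the gene's overlapping DMR deltas by a
    CpG-count-weighted mean; delta_expr is the DE log2 fold change.
    """
    dmr_ix = dmrs.set_index("dmr_id")
    rows = []
    if len(dmgs) == 0:
        return pd.DataFrame(
            columns=["gene_id", "region_class", "delta_ml", "delta_expr", "is_dmg", "is_deg"]
        )
    for (gene, cls), sub in dmgs.groupby(["gene_id", "region_class"]):
        ids = sorted({i for s in sub["dmr_ids"] for i in s.split(",") if i})
        d = dmr_ix.loc[ids]
        w = d["n_cpg"].to_numpy(dtype=float)
        delta_ml = float(np.average(d["delta"].to_numpy(), weights=w))
        if gene in de_results.index:
            delta_expr = float(de_results.loc[gene, "log2fc"])
            is_deg = bool(de_results.loc[gene, "is_deg"])
        else:
            delta_expr, is_deg = np.nan, False
        rows.append(
            {
                "gene_id": gene,
                "region_class": cls,
                "delta_ml": delta_ml,
                "delta_expr": delta_expr,
                "is_dmg": True,
                "is_deg": is_deg,
            }
        )
    return pd.DataFrame(rows)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho at small n."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(rx)
    denom = np.sqrt(((rx - rx.mean()) ** 2).sum() * ((ry - ry.mean()) ** 2).sum())
    perms = np.array(list(permutations(range(n))), dtype=np.intp)
    scores = (rx - rx.mean())[perms] @ (ry - ry.mean()) / denom
    return float(np.mean(np.abs(scores) >= abs(rho_obs) - 1e-12))


def correlate_dmg_expression(
    records: pd.DataFrame, region_class: str, exact_below: int = 10
) -> tuple[float, float]:
    """Spearman correlation of (delta_ml, delta_expr) for one region class.

    Large-sample t approximation for the p-value; exact permutation p
    when n < ``exact_below``.  Constant inputs are an error (rho
    undefined).
    """
    sub = records[records["region_class"] == region_class].dropna(
        subset=["delta_ml", "delta_expr"]
    )
    if len(sub) < 3:
        raise ValueError(f"need >= 3 records for region class {region_class!r}")
    x = sub["delta_ml"].to_numpy()
    y = sub["delta_expr"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; Spearman rho undefined")
    rho, p = sps.spearmanr(x, y)
    if len(sub) < exact_below:
        p = _exact_spearman_p(x, y, rho)
    return float(rho), float(p)


def overlap_dmg_deg(dmgs: pd.DataFrame, de_results: pd.DataFrame) -> pd.DataFrame:
    """Genes that are DMG (promoter and/or gene body) AND DEG."""
    deg = de_results[de_results["is_deg"]]
    if len(dmgs) == 0:
        return pd.DataFrame(columns=["gene_id", "region_classes", "directions", "log2fc", "padj"])
    rows = []
    for gene, sub in dmgs.groupby("gene_id"):
        if gene not in deg.index:
            continue
        rows.append(
            {
                "gene_id": gene,
                "region_classes": ",".join(sorted(set(sub["region_class"]))),
                "directions": ",".join(sorted(set(sub["direction"]))),
                "log2fc": float(deg.loc[gene, "log2fc"]),
                "padj": float(deg.loc[gene, "padj"]),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "region_classes", "directions", "log2fc", "padj"])


def hypergeometric_enrichment(
    query: set[str],
    gene_sets: dict[str, tuple[str, frozenset[str]]],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each gene set.

    Sets are intersected with the universe first; the query must be a
    subset of the universe.  p = P(X >= k) for k observed overlaps with a
    K-gene term in an N-gene universe and an n-gene query.
    """
    if not query or not universe:
        raise ValueError("empty query or universe")
    if not query <= universe:
        raise ValueError("query genes outside the universe")
    N = len(universe)
    n = len(query)
    rows = []
    for term, (desc, genes) in gene_sets.items():
        members = genes & universe
        K = len(members)
        if K == 0:
            continue
        k = len(query & members)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term,
                "term_name": desc,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": p,
                "significant": p < alpha,
            }
        )
    return (
        pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p_value", "significant"])
        .sort_values("p_value", kind="stable")
        .reset_index(drop=True)
    )
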
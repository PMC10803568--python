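"""Site-level methylation: ML, binomial site calling, conversion efficiency.

The methylation level of a cytosine is the fraction of methylated reads,
ML = mC / (mC + nonmC).  A site is called methylated when its methylated
read count is implausible under the bisulfite non-conversion rate r alone:
one-sided binomial test P(X >= mC | n = mC + nonmC, p = r), BH-adjusted
across all tested sites, called at FDR alpha.  r itself is estimated from
the unmethylated lambda spike-in contig, where every methylated read is a
conversion failure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import FeatureMap

__all__ = [
    "ConversionEstimate",
    "methylation_level",
    "collapse_strands",
    "estimate_conversion",
    "call_methylated_sites",
    "summarize_feature_methylation",
    "sample_correlation",
    "delta_delta_ct",
]


@dataclass(frozen=True)
class ConversionEstimate:
    """Bisulfite non-conversion rate from an unmethylated spike-in."""

    r: float
    n_sites: int
    total_coverage: int

    @property
    def conversion_efficiency(self) -> float:
        return 1.0 - self.r


def methylation_level(count_methylated: int, count_unmethylated: int) -> float:
    """ML = mC / (mC + nonmC); zero coverage is an error, not 0."""
    if count_methylated < 0 or count_unmethylated < 0:
        raise ValueError("negative read count")
    cov = count_methylated + count_unmethylated
    if cov == 0:
        raise ValueError("methylation level undefined at zero coverage")
    return count_methylated / cov


def collapse_strands(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse symmetric CpG dyads onto the + strand cytosine.

    A CpG on the minus strand at position p is the G-complement of the CpG
    whose C sits at p-1 on the plus strand; counts of the two strands are
    summed.  Records already collapsed (strand '.') pass through.
    """
    df = records.copy()
    minus = df["strand"] == "-"
    df.loc[minus, "pos"] = df.loc[minus, "pos"] - 1
    out = (
        df.groupby(["contig", "pos"], as_index=False, sort=True)[
            ["count_m", "count_u"]
        ].sum()
    )
    out["strand"] = "."
    return out[["contig", "pos", "strand", "count_m", "count_u"]]


def estimate_conversion(spike_records: pd.DataFrame) -> ConversionEstimate:
    """Pool all spike-in cytosines: r = sum(mC) / sum(mC + nonmC)."""
    cov = spike_records["count_m"].sum() + spike_records["count_u"].sum()
    if len(spike_records) == 0 or cov == 0:
        raise ValueError("no covered spike-in cytosines")
    r = float(spike_records["count_m"].sum() / cov)
    return ConversionEstimate(r=r, n_sites=int(len(spike_records)), total_coverage=int(cov))


def call_methylated_sites(
    records: pd.DataFrame, r: float, alpha: float = 0.05
) -> pd.DataFrame:
    """Binomial site test against the non-conversion rate.

    Returns the input sites (coverage > 0 only) with ``ml``, one-sided
    ``p_value`` = P(X >= mC | n, r), BH ``q_value`` across all tested
    sites, and ``is_methylated`` = q < alpha.
    """
    if not 0 <= r < 1:
        raise ValueError(f"non-conversion rate r={r} outside [0, 1)")
    df = records.copy()
    cov = df["count_m"].to_numpy() + df["count_u"].to_numpy()
    df = df.loc[cov > 0].copy()
    if len(df) == 0:
        raise ValueError("no covered sites to test")
    mc = df["count_m"].to_numpy()
    n = mc + df["count_u"].to_numpy()
    df["ml"] = mc / n
    # upper tail including mC itself
    df["p_value"] = stats.binom.sf(mc - 1, n, r)
    _, q, _, _ = multipletests(df["p_value"].to_numpy(), method="fdr_bh")
    df["q_value"] = q
    df["is_methylated"] = df["q_value"] < alpha
    return df


def summarize_feature_methylation(
    records: pd.DataFrame, features: FeatureMap, min_depth: int = 5
) -> pd.Series:
    """Unweighted mean site ML per feature class.

    Only sites with coverage >= ``min_depth`` count; a class with no
    qualifying site is reported as NaN.  A site inside two classes (an
    exon in a CGI, say) contributes to both.
    """
    df = records.copy()
    cov = df["count_m"] + df["count_u"]
    df = df.loc[cov >= min_depth].copy()
    df["ml"] = df["count_m"] / (df["count_m"] + df["count_u"])
    out = {}
    for cls in features.classes():
        vals = []
        for contig, sub in df.groupby("contig", sort=False):
            pos0 = sub["pos"].to_numpy() - 1
            hit = features.membership(cls, contig, pos0)
            if hit.any():
                vals.append(sub["ml"].to_numpy()[hit])
        out[cls] = float(np.mean(np.concatenate(vals))) if vals else np.nan
    return pd.Series(out, name="mean_ml")


def sample_correlation(
    profiles: dict[str, pd.DataFrame], min_depth: int = 5, method: str = "pearson"
) -> pd.DataFrame:
    """Sample x sample correlation of ML over common CpGs.

    Common CpGs are sites covered at >= ``min_depth`` in *every* sample.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two samples")
    mls = []
    for name, df in profiles.items():
        cov = df["count_m"] + df["count_u"]
        sub = df.loc[cov >= min_depth]
        s = pd.Series(
            (sub["count_m"] / (sub["count_m"] + sub["count_u"])).to_numpy(),
            index=pd.MultiIndex.from_frame(sub[["contig", "pos"]]),
            name=name,
        )
        mls.append(s)
    mat = pd.concat(mls, axis=1, join="inner")
    if len(mat) == 0:
        raise ValueError("no CpG common to all samples at the required depth")
    return mat.corr(method=method)


def delta_delta_ct(
    ct_target_treat: float,
    ct_ref_treat: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCT method (reference-normalized)."""
    ddct = (ct_target_treat - ct_ref_treat) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
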
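"""Self-contained validation experiments for the pipeline's statistics.

Each function simulates data with known ground truth under the package's
study-design defaults, runs the corresponding stage, and returns the
measured operating characteristic: FDR and type-I control on null data,
dispersion parameter recovery, DMR recovery against planted regions,
differential-expression power, and the promoter-negative /
gene-body-positive correlation sign pattern under methylation-expression
coupling.  They are used by the acceptance checks and are available to
users who want to re-verify calibration under their own settings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rand import substream
from .annotation import derive_features, detect_cgi
from .dmr import DmrParams, call_dmr_pipeline
from .expression import de_pipeline, estimate_nb_dispersion, median_of_ratios
from .integrate import build_integration_records, correlate_dmg_expression
from .methylation import call_methylated_sites, estimate_conversion
from .simulate import SimulationConfig, simulate_dataset

__all__ = [
    "site_fdr_on_unmethylated",
    "de_null_type_one",
    "dmr_null_rate",
    "phi_recovery",
    "alpha_recovery",
    "dmr_recovery",
    "de_power",
    "coupling_sign_pattern",
    "conversion_recovery",
    "reciprocal_overlap_match",
]

SAMPLES = ("PC_1", "PC_2", "PC_3", "NC_1", "NC_2", "NC_3")
GROUPS = {s: s[:2] for s in SAMPLES}


def site_fdr_on_unmethylated(
    seed: int, n_sites: int = 100_000, r: float = 0.01, depth: float = 30.0,
    alpha: float = 0.05,
) -> float:
    """Fraction of fully-unmethylated sites called methylated at FDR alpha.

    Every methylated read on such data is a conversion failure, so the
    fraction of calls bounds the realized false discovery rate.
    """
    rng = substream(seed, "site-fdr-null")
    cov = np.maximum(1, rng.poisson(depth, n_sites))
    mc = rng.binomial(cov, r)
    recs = pd.DataFrame(
        {"contig": "null", "pos": np.arange(1, n_sites + 1), "strand": ".",
         "count_m": mc, "count_u": cov - mc}
    )
    calls = call_methylated_sites(recs, r=r, alpha=alpha)
    return float(calls["is_methylated"].mean())


def de_null_type_one(seed: int, n_genes: int = 5000, alpha_disp: float = 0.05) -> float:
    """Empirical P(p < 0.05) of the DE Wald test on null NB data, 3v3."""
    rng = substream(seed, "de-null")
    q = np.exp(rng.normal(np.log(300), 1.2, n_genes))
    cols = {s: rng.poisson(rng.gamma(1 / alpha_disp, q * alpha_disp)) for s in SAMPLES}
    counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])
    res = de_pipeline(counts, GROUPS)["results"]
    return float((res["p_value"] < 0.05).mean())


def dmr_null_rate(seed: int, n_runs: int = 3) -> tuple[int, int]:
    """(called DMRs, tested sites) on no-difference methylomes (~85k sites each)."""
    n_dmrs = n_sites = 0
    for k in range(n_runs):
        cfg = SimulationConfig(
            seed=(seed + 1000 * k) % 2**31, n_contigs=4, contig_length=2_000_000,
            n_genes=0, n_true_dmrs=0, n_intergenic_cgi=20,
        )
        ds = simulate_dataset(cfg)
        genomic = {s: d[d["contig"] != "lambda_spike"] for s, d in ds.methylomes.items()}
        res = call_dmr_pipeline(genomic, cfg.group_map, DmrParams())
        n_dmrs += len(res["dmrs"])
        n_sites += len(res["site_stats"])
    return n_dmrs, n_sites


def phi_recovery(seed: int, n_sites: int = 5000, phi: float = 0.1, depth: float = 30.0) -> float:
    """Median beta-binomial dispersion estimate at p = 0.5, 3+3 replicates."""
    from .dmr import estimate_dispersion

    rng = substream(seed, "phi-recovery")
    a = b = 0.5 * (1 - phi) / phi
    mc, cov = {}, {}
    for g in ("PC", "NC"):
        c = np.maximum(1, rng.poisson(depth, (3, n_sites)))
        mc[g] = rng.binomial(c, rng.beta(a, b, (3, n_sites)))
        cov[g] = c
    return float(np.median(estimate_dispersion(mc, cov)))


def alpha_recovery(seed: int, n_genes: int = 2000, alpha: float = 0.2) -> float:
    """Median NB dispersion estimate on 3v3 counts with planted alpha."""
    rng = substream(seed, "alpha-recovery")
    q = np.exp(rng.normal(np.log(300), 1.0, n_genes))
    cols = {s: rng.poisson(rng.gamma(1 / alpha, q * alpha)) for s in SAMPLES}
    counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])
    sf = median_of_ratios(counts + 1)
    est = estimate_nb_dispersion(counts.div(sf, axis=1), pd.Series(GROUPS))
    return float(est.median())


def reciprocal_overlap_match(
    truth: pd.DataFrame, called: pd.DataFrame, frac: float = 0.5
) -> tuple[int, int]:
    """(matched truth regions, matched called regions) at reciprocal overlap."""
    tp_t = 0
    for t in truth.itertuples():
        sub = called[called["contig"] == t.contig]
        if len(sub):
            ov = np.minimum(sub["end"], t.end) - np.maximum(sub["start"], t.start)
            ok = (ov >= frac * (t.end - t.start)) & (ov >= frac * (sub["end"] - sub["start"]))
            tp_t += bool(ok.any())
    tp_c = 0
    for c in called.itertuples():
        sub = truth[truth["contig"] == c.contig]
        if len(sub):
            ov = np.minimum(sub["end"], c.end) - np.maximum(sub["start"], c.start)
            ok = (ov >= frac * (c.end - c.start)) & (ov >= frac * (sub["end"] - sub["start"]))
            tp_c += bool(ok.any())
    return tp_t, tp_c


def dmr_recovery(
    seed: int, n_runs: int = 4, n_true_dmrs: int = 50, delta: float = 0.3,
) -> tuple[float, float, int]:
    """Pooled sensitivity/precision over ``n_runs`` planted-DMR methylomes.

    Each run plants ``n_true_dmrs`` regions of the given effect size at
    30x coverage, 3v3; matching requires >= 50% reciprocal overlap.
    Pooling several runs controls the Monte-Carlo error of the estimate
    (a single 50-region run has a binomial standard error of ~3.5%).
    """
    tp_t = n_t = tp_c = n_c = 0
    for k in range(n_runs):
        cfg = SimulationConfig(
            seed=(seed + 1000 * k) % 2**31, n_true_dmrs=n_true_dmrs, dmr_delta=delta
        )
        ds = simulate_dataset(cfg)
        genomic = {s: d[d["contig"] != "lambda_spike"] for s, d in ds.methylomes.items()}
        called = call_dmr_pipeline(genomic, cfg.group_map, DmrParams())["dmrs"]
        a, b = reciprocal_overlap_match(ds.truth.dmrs, called)
        tp_t += a
        n_t += len(ds.truth.dmrs)
        tp_c += b
        n_c += len(called)
    return tp_t / n_t, tp_c / max(n_c, 1), n_t


def de_power(
    seed: int, n_genes: int = 2000, n_deg: int = 100, log2fc: float = 2.0,
    depth: float = 500.0, alpha_disp: float = 0.05,
) -> float:
    """Power of the DEG rule (|log2FC| > 1, padj < 0.05) on planted 4-fold genes."""
    rng = substream(seed, "de-power")
    mu = np.full(n_genes, depth)
    fc = np.zeros(n_genes)
    idx = rng.choice(n_genes, n_deg, replace=False)
    fc[idx] = rng.choice([log2fc, -log2fc], n_deg)
    cols = {}
    for s in SAMPLES:
        m = mu * 2**fc if s.startswith("PC") else mu
        cols[s] = rng.poisson(rng.gamma(1 / alpha_disp, m * alpha_disp))
    counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])
    de = de_pipeline(counts, GROUPS)
    hits = de["up"] | de["down"]
    return float(np.mean([f"g{i}" in hits for i in idx]))


def coupling_sign_pattern(seed: int, strength: float) -> dict:
    """One coupled (or uncoupled, strength=0) end-to-end correlation run.

    DMRs are planted on promoters and gene bodies; with positive
    coupling strength, promoter methylation represses and gene-body
    methylation activates expression.  Returns per-class Spearman rho, p
    and record count from the full DMR -> DMG -> DE -> integration chain.
    """
    big = strength == 0.0  # the null bound |rho| < 0.15 needs n >> 100
    cfg = SimulationConfig(
        seed=seed,
        coupling="both",
        coupling_strength=strength,
        n_contigs=4 if big else 3,
        contig_length=1_150_000 if big else 400_000,
        n_genes=600 if big else 150,
        n_true_dmrs=520 if big else 120,
        n_true_degs=0,
    )
    ds = simulate_dataset(cfg)
    lengths = {c: len(g) for c, g in ds.genome.items()}
    cgis = [iv for g in ds.genome.values() if not g.is_spike_in for iv in detect_cgi(g)]
    features = derive_features(ds.genes, cgis, lengths)
    genomic = {s: d[d["contig"] != "lambda_spike"] for s, d in ds.methylomes.items()}
    res = call_dmr_pipeline(genomic, cfg.group_map, DmrParams(), features)
    de = de_pipeline(ds.counts, cfg.group_map)
    rec = build_integration_records(res["dmgs"], res["dmrs"], de["results"])
    out = {}
    for cls in ("promoter", "gene_body"):
        rho, p = correlate_dmg_expression(rec, cls)
        out[cls] = {"rho": rho, "p": p, "n": int((rec["region_class"] == cls).sum())}
    return out


def conversion_recovery(seed: int, r: float = 0.005) -> dict:
    """Spike-in conversion estimate vs truth, with its binomial SE."""
    cfg = SimulationConfig(seed=seed, nonconversion_rate=r)
    ds = simulate_dataset(cfg)
    spike = pd.concat(
        [df[df["contig"] == "lambda_spike"] for df in ds.methylomes.values()]
    )
    est = estimate_conversion(spike)
    se = float(np.sqrt(r * (1 - r) / est.total_coverage))
    return {"estimate": est.r, "true": r, "se": se, "coverage": est.total_coverage}
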
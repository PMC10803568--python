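"""End-to-end orchestration of the RRBS + RNA-seq integration stages.

Stage order: annotation -> site calling (with spike-in conversion
estimate) -> feature methylation & sample correlation -> DMR/DMG ->
differential expression -> integration (metagene profiles, correlations,
DMG-DEG overlap) -> enrichment.  Every stage writes its flat-file output
under the configured output directory and contributes to a summary JSON
with the headline counts.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import dmr as dmrmod
from . import expression as expr
from . import integrate as integ
from . import methylation as meth
from .config import RunConfig, ValidationError
from .io import read_count_matrix, read_gmt, read_methylation_file, write_bed

log = logging.getLogger("epilink")

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class _Stage:
    """Context manager logging a stage timer and wrapping failures."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is None:
            log.info("stage %s: done in %.1fs", self.name, dt)
            return False
        log.error("stage %s: FAILED after %.1fs (%s)", self.name, dt, exc)
        if isinstance(exc, (PipelineError, ValidationError)):
            return False
        raise PipelineError(self.name, exc) from exc


def load_annotation(cfg: RunConfig):
    genome = ann.load_genome(cfg.genome, spike_in_contig=cfg.spike_in_contig)
    genes = ann.load_gene_models(cfg.annotation)
    cgis = [
        iv
        for g in genome.values()
        if not g.is_spike_in
        for iv in ann.detect_cgi(g, cfg.cgi_min_len, cfg.cgi_min_gc, cfg.cgi_min_oe)
    ]
    lengths = {c: len(g) for c, g in genome.items()}
    features = ann.derive_features(
        genes, cgis, lengths, promoter_size=cfg.promoter_size, shore_size=cfg.shore_size
    )
    return genome, genes, cgis, features


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns the summary dict (also written as JSON)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "groups": sorted(set(cfg.groups.values()), reverse=True)}

    with _Stage("annotation"):
        genome, genes, cgis, features = load_annotation(cfg)
        write_bed(
            ((iv.contig, iv.start, iv.end, "cgi") for iv in cgis), outdir / "cgi.bed"
        )
        summary["n_genes"] = len(genes)
        summary["n_cgi"] = len(cgis)

    with _Stage("load_methylomes"):
        methylomes = {}
        for sample, path in cfg.cytosine_reports.items():
            df = read_methylation_file(path)
            if cfg.collapse_strands:
                df = meth.collapse_strands(df)
            methylomes[sample] = df

    with _Stage("conversion"):
        conv_rows = []
        pooled_spike = []
        for sample, df in methylomes.items():
            spike = df[df["contig"] == cfg.spike_in_contig]
            if len(spike):
                est = meth.estimate_conversion(spike)
                conv_rows.append(
                    {"sample": sample, "r": est.r,
                     "conversion_efficiency": est.conversion_efficiency,
                     "n_sites": est.n_sites, "total_coverage": est.total_coverage}
                )
                pooled_spike.append(spike)
        if pooled_spike:
            pooled = meth.estimate_conversion(pd.concat(pooled_spike))
            r = pooled.r
        else:
            r = 0.0
            log.warning("no spike-in records; assuming r = 0")
        pd.DataFrame(conv_rows).to_csv(outdir / "conversion.tsv", sep="\t", index=False)
        summary["nonconversion_rate"] = r
        summary["conversion_efficiency"] = 1.0 - r

    with _Stage("site_calls"):
        site_dir = outdir / "site_calls"
        site_dir.mkdir(exist_ok=True)
        n_meth = {}
        genomic = {
            s: df[df["contig"] != cfg.spike_in_contig] for s, df in methylomes.items()
        }
        for sample, df in genomic.items():
            calls = meth.call_methylated_sites(df, r, alpha=cfg.site_alpha)
            calls.to_csv(site_dir / f"{sample}.tsv", sep="\t", index=False)
            n_meth[sample] = int(calls["is_methylated"].sum())
        summary["n_methylated_sites"] = n_meth

    with _Stage("feature_methylation"):
        feat = pd.DataFrame(
            {
                s: meth.summarize_feature_methylation(df, features, cfg.min_depth)
                for s, df in genomic.items()
            }
        )
        feat.to_csv(outdir / "feature_methylation.tsv", sep="\t", index_label="feature_class")
        corr = meth.sample_correlation(genomic, min_depth=cfg.min_depth)
        corr.to_csv(outdir / "sample_correlation.tsv", sep="\t")
        summary["min_sample_correlation"] = float(corr.min().min())

    with _Stage("dmr"):
        dmr_res = dmrmod.call_dmr_pipeline(
            genomic, {s: cfg.groups[s] for s in genomic}, cfg.dmr, features
        )
        dmrs = dmr_res["dmrs"]
        dmrs.to_csv(outdir / "dmrs.tsv", sep="\t", index=False)
        write_bed(
            (
                (d.contig, d.start, d.end, d.direction, int(round(1000 * abs(d.delta))),
                 ".", d.n_cpg, d.ml_1, d.ml_2)
                for d in dmrs.itertuples()
            ),
            outdir / "dmrs.bed",
        )
        dmgs = dmr_res["dmgs"]
        dmgs.to_csv(outdir / "dmgs.tsv", sep="\t", index=False)
        summary["n_dmrs"] = int(len(dmrs))
        summary["n_dmrs_hyper"] = int((dmrs["direction"] == "hyper").sum())
        summary["n_dmrs_hypo"] = int((dmrs["direction"] == "hypo").sum())
        summary["dmg"] = dmr_res["summary"]

    with _Stage("expression"):
        counts = read_count_matrix(cfg.counts)
        missing = [s for s in cfg.groups if s not in counts.columns]
        if missing:
            raise ValueError(f"samples missing from the count matrix: {missing}")
        de = expr.de_pipeline(counts, cfg.groups)
        res = de["results"]
        res.to_csv(outdir / "de_results.tsv", sep="\t", index_label="gene_id")
        lengths = pd.Series({g.gene_id: g.gene_length for g in genes})
        fpkm = expr.compute_fpkm(counts, lengths.reindex(counts.index))
        fpkm.to_csv(outdir / "fpkm.tsv", sep="\t", index_label="gene_id")
        groups = pd.Series(cfg.groups)
        classes = {}
        for gname in summary["groups"]:
            gmean = fpkm.loc[:, (groups.reindex(fpkm.columns) == gname).to_numpy()].mean(axis=1)
            classes[gname] = expr.classify_expression(gmean)
        cls_df = pd.concat(
            {g: c["expression_class"] for g, c in classes.items()}, axis=1
        )
        cls_df.to_csv(outdir / "expression_classes.tsv", sep="\t", index_label="gene_id")
        esets = expr.expressed_gene_sets(fpkm, groups)
        summary["n_degs"] = int(len(de["up"]) + len(de["down"]))
        summary["n_degs_up"] = int(len(de["up"]))
        summary["n_degs_down"] = int(len(de["down"]))
        summary["n_expressed_shared"] = len(esets.get("shared", ()))
        for k, v in esets.items():
            if k.startswith("exclusive_"):
                summary[f"n_{k}"] = len(v)

    with _Stage("integration"):
        control = summary["groups"][1]
        profiles = integ.metagene_profile(
            genomic,
            {s: cfg.groups[s] for s in genomic},
            genes,
            classes[control]["expression_class"],
            flank=cfg.metagene_flank,
            body_bins=cfg.metagene_body_bins,
            flank_bins=cfg.metagene_flank_bins,
            min_depth=cfg.min_depth,
        )
        profiles.to_csv(outdir / "metagene_profiles.tsv", sep="\t", index=False)
        records = integ.build_integration_records(dmgs, dmrs, res)
        records.to_csv(outdir / "integration.tsv", sep="\t", index=False)
        rho = {}
        for cls in ("promoter", "gene_body"):
            try:
                r_, p_ = integ.correlate_dmg_expression(records, cls)
                rho[cls] = {"rho": r_, "p": p_}
            except ValueError as exc:
                rho[cls] = {"rho": None, "p": None, "note": str(exc)}
        summary["dmg_expression_correlation"] = rho
        overlap = integ.overlap_dmg_deg(dmgs, res)
        overlap.to_csv(outdir / "dmg_deg_overlap.tsv", sep="\t", index=False)
        summary["n_dmg_deg_overlap"] = int(len(overlap))

    if cfg.gmt is not None:
        with _Stage("enrichment"):
            sets = read_gmt(cfg.gmt)
            universe = set(res.index)
            query = set(overlap["gene_id"]) & universe
            if query:
                enr = integ.hypergeometric_enrichment(
                    query, sets, universe, alpha=cfg.enrichment_alpha
                )
            else:
                enr = pd.DataFrame(
                    columns=["term_id", "term_name", "k", "K", "n", "N", "p_value", "significant"]
                )
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            summary["n_enriched_terms"] = int(enr["significant"].sum()) if len(enr) else 0

    if cfg.make_plots:
        with _Stage("plots"):
            _make_plots(records, profiles, outdir)

    with _Stage("summary"):
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        cfg.to_yaml(outdir / "run_config.yaml")
    return summary


def _make_plots(records: pd.DataFrame, profiles: pd.DataFrame, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, cls in zip(axes, ("promoter", "gene_body")):
        sub = records[records["region_class"] == cls]
        ax.scatter(sub["delta_ml"], sub["delta_expr"], s=12, alpha=0.7)
        ax.axhline(0, lw=0.5, color="grey")
        ax.axvline(0, lw=0.5, color="grey")
        ax.set_title(cls)
        ax.set_xlabel("differential methylation (delta ML)")
    axes[0].set_ylabel("differential expression (log2FC)")
    fig.tight_layout()
    fig.savefig(outdir / "integration_scatter.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(
        1, profiles["group"].nunique(), figsize=(9, 4), sharey=True, squeeze=False
    )
    for ax, (grp, sub) in zip(axes[0], profiles.groupby("group")):
        for cls, csub in sub.groupby("expression_class"):
            ax.plot(csub["bin"], csub["mean_ml"], label=cls)
        ax.set_title(grp)
        ax.set_xlabel("metagene bin")
    axes[0][0].set_ylabel("mean ML")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "metagene_profiles.png", dpi=120)
    plt.close(fig)
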
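"""Coupled methylome + transcriptome simulator with known ground truth.

Emulates the study design this package analyses: two groups of three
replicates (PC_1..PC_3 knockdown, NC_1..NC_3 control), RRBS-style
CpG counts with beta-binomial between-replicate variability and bisulfite
non-conversion noise, an unmethylated lambda-like spike-in contig,
negative-binomial gene counts, planted DMRs and DEGs, and an optional
methylation-to-expression coupling (promoter-repressive and/or
gene-body-activating) whose sign pattern the integration stage must
recover.

All randomness flows from ``SimulationConfig.seed`` through named
substreams, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._rand import substream
from .annotation import FeatureInterval, GeneModel, GenomeSequence

__all__ = [
    "SimulationConfig",
    "TruthManifest",
    "SimulatedDataset",
    "simulate_genome",
    "simulate_methylome",
    "simulate_expression",
    "simulate_dataset",
    "write_dataset",
    "write_truth",
    "read_truth",
    "cpg_positions",
]

GROUPS = ("PC", "NC")
SPIKE_IN_NAME = "lambda_spike"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for the generator.

    Defaults describe a small diploid-agnostic desk-scale genome with
    CGI-like promoter patches, 30x CpG coverage, 0.5% bisulfite
    non-conversion, and moderate biological overdispersion on both the
    methylation (phi = 0.1) and expression (alpha = 0.05) side.
    """

    seed: int = 0
    # genome shape
    n_contigs: int = 2
    contig_length: int = 400_000
    spike_in_length: int = 20_000
    n_genes: int = 80
    promoter_cgi_fraction: float = 0.5
    n_intergenic_cgi: int = 8  # per contig
    # methylome
    n_replicates_per_group: int = 3
    depth_mean: float = 30.0
    nonconversion_rate: float = 0.005
    bb_dispersion: float = 0.1
    cgi_baseline_ml: float = 0.10
    background_baseline_ml: float = 0.75
    baseline_concentration: float = 15.0
    # planted differential methylation (PC relative to NC)
    n_true_dmrs: int = 40
    dmr_delta: float = 0.3
    dmr_length: int = 500
    dmr_min_cpg: int = 8
    # expression
    nb_dispersion: float = 0.05
    n_true_degs: int = 60
    deg_log2fc: float = 2.0
    expr_mean_log: float = float(np.log(300.0))
    expr_sd_log: float = 1.2
    # methylation -> expression coupling
    coupling: str = "none"  # none | promoter_negative | genebody_positive | both
    coupling_strength: float = 3.0

    def __post_init__(self) -> None:
        for name in ("nonconversion_rate", "bb_dispersion", "dmr_delta",
                     "promoter_cgi_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_contigs", "contig_length", "n_replicates_per_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.coupling not in ("none", "promoter_negative", "genebody_positive", "both"):
            raise ValueError(f"unknown coupling mode {self.coupling!r}")

    @property
    def sample_names(self) -> list[str]:
        return [
            f"{g}_{i + 1}" for g in GROUPS for i in range(self.n_replicates_per_group)
        ]

    @property
    def group_map(self) -> dict[str, str]:
        return {s: s.split("_")[0] for s in self.sample_names}


@dataclass
class TruthManifest:
    """Ground truth of one simulated dataset.

    ``dmrs``: contig, start, end (0-based half-open), direction
    (hyper/hypo, PC relative to NC), delta, target_gene, region_class.
    ``degs``: gene_id, log2fc (PC over NC).  ``site_baseline``: per contig,
    CpG position (1-based) with per-group true methylation.
    """

    dmrs: pd.DataFrame
    degs: pd.DataFrame
    site_baseline: dict[str, pd.DataFrame] = field(default_factory=dict)
    gene_baseline: pd.DataFrame | None = None


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, GenomeSequence]
    genes: list[GeneModel]
    methylomes: dict[str, pd.DataFrame]
    counts: pd.DataFrame
    truth: TruthManifest


def cpg_positions(sequence: str) -> np.ndarray:
    """0-based positions of the C of every CpG dinucleotide."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng, n, p) -> np.ndarray:
    return _BASES[rng.choice(4, size=n, p=p)]


def _thin_cpgs(rng, arr: np.ndarray, keep_frac: float) -> None:
    """Break a fraction of CpG dinucleotides (G -> A) in place.

    Random iid sequence has CpG obs/exp ~ 1; vertebrate background is
    CpG-depleted, and a depleted background also keeps islands sharp.
    """
    pos = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
    kill = pos[rng.random(len(pos)) > keep_frac]
    arr[kill + 1] = ord("A")


def _make_exons(rng, start: int, end: int) -> tuple[tuple[int, int], ...]:
    """Random exon/intron partition of a 1-based inclusive gene span."""
    length = end - start + 1
    n_ex = int(rng.integers(2, 5))
    n_seg = 2 * n_ex - 1
    base = 30
    extra = rng.multinomial(length - base * n_seg, np.full(n_seg, 1.0 / n_seg))
    lens = base + extra
    exons = []
    cur = start
    for i, ln in enumerate(lens):
        if i % 2 == 0:
            exons.append((cur, cur + int(ln) - 1))
        cur += int(ln)
    exons[-1] = (exons[-1][0], end)
    return tuple(exons)


def simulate_genome(
    cfg: SimulationConfig,
) -> tuple[dict[str, GenomeSequence], list[GeneModel]]:
    """Random genome with CGI-like patches, gene models, and a spike-in.

    Background sequence is AT-rich and CpG-depleted; a fraction of gene
    promoters and a few intergenic spots carry GC-rich CpG-dense patches
    that the island scanner should find.  Genes are placed without
    overlap, leaving room for their 2-kb promoters; placement failure at
    the requested density is an error.
    """
    rng = substream(cfg.seed, "genome")
    bg_p = np.array([0.3, 0.2, 0.2, 0.3])
    patch_p = np.array([0.17, 0.33, 0.33, 0.17])

    genes: list[GeneModel] = []
    genome: dict[str, GenomeSequence] = {}
    per_contig = int(np.ceil(cfg.n_genes / cfg.n_contigs))
    gene_idx = 0
    for ci in range(cfg.n_contigs):
        name = f"chr{ci + 1}"
        arr = _random_seq(rng, cfg.contig_length, bg_p)
        _thin_cpgs(rng, arr, keep_frac=0.25)

        # place genes left to right with promoter-sized spacing
        cursor = 2500
        spans: list[tuple[int, int]] = []
        n_here = min(per_contig, cfg.n_genes - gene_idx)
        for _ in range(n_here):
            gap = int(rng.integers(2500, 4500))
            glen = int(rng.integers(2000, 5001))
            start = cursor + gap  # 1-based
            end = start + glen - 1
            if end > cfg.contig_length - 2500:
                raise ValueError(
                    f"cannot place {n_here} genes on a {cfg.contig_length}-bp contig"
                )
            spans.append((start, end))
            cursor = end
        strands = rng.choice(["+", "-"], size=len(spans))
        patch_sites: list[tuple[int, int]] = []  # 0-based half-open
        for (start, end), strand in zip(spans, strands):
            gene_idx += 1
            genes.append(
                GeneModel(
                    gene_id=f"g{gene_idx:04d}",
                    contig=name,
                    strand=str(strand),
                    start=start,
                    end=end,
                    exons=_make_exons(rng, start, end),
                )
            )
            if rng.random() < cfg.promoter_cgi_fraction:
                # mid-promoter island, kept clear of the TSS so that a
                # methylation change planted over the promoter and one
                # planted over the gene body stay separable
                plen = int(rng.integers(400, 801))
                offset = 400 + int(rng.integers(0, 401))
                tss0 = start - 1 if strand == "+" else end - 1
                if strand == "+":
                    hi = max(0, tss0 - offset)
                    patch_sites.append((max(0, hi - plen), hi))
                else:
                    lo = min(cfg.contig_length, tss0 + 1 + offset)
                    patch_sites.append((lo, min(cfg.contig_length, lo + plen)))
        # intergenic patches in the tail of the contig
        for _ in range(cfg.n_intergenic_cgi):
            plen = int(rng.integers(400, 801))
            ps = int(rng.integers(0, cfg.contig_length - plen))
            patch_sites.append((ps, ps + plen))
        for ps, pe in patch_sites:
            arr[ps:pe] = _random_seq(rng, pe - ps, patch_p)
        genome[name] = GenomeSequence(name, arr.tobytes().decode("ascii"))

    spike = _random_seq(rng, cfg.spike_in_length, np.full(4, 0.25))
    genome[SPIKE_IN_NAME] = GenomeSequence(
        SPIKE_IN_NAME, spike.tobytes().decode("ascii"), is_spike_in=True
    )
    return genome, genes


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------


def _beta_proportions(rng, p: np.ndarray, phi: float) -> np.ndarray:
    """Replicate proportions ~ Beta(mean p, dispersion phi).

    Parameterized as alpha = p(1-phi)/phi, beta = (1-p)(1-phi)/phi, so a
    Binomial(n, draw) count has the beta-binomial variance
    n p (1-p) (1 + (n-1) phi).  Boundary p (0 or 1) and phi ~ 0 pass
    through unchanged.
    """
    p = np.asarray(p, dtype=float)
    if phi < 1e-6:
        return p.copy()
    interior = (p > 0.0) & (p < 1.0)
    pi = p.copy()
    if interior.any():
        a = p[interior] * (1.0 - phi) / phi
        b = (1.0 - p[interior]) * (1.0 - phi) / phi
        pi[interior] = rng.beta(a, b)
    return pi


def _beta_binomial(rng, n: np.ndarray, p: np.ndarray, phi: float) -> np.ndarray:
    """Counts ~ BetaBinomial(n, p, phi) with alpha = p(1-phi)/phi."""
    return rng.binomial(n, np.clip(_beta_proportions(rng, p, phi), 0.0, 1.0))


def _plant_dmrs(
    cfg: SimulationConfig,
    genome: dict[str, GenomeSequence],
    genes: list[GeneModel],
    rng,
) -> pd.DataFrame:
    """Choose planted DMR intervals (0-based half-open) with direction.

    With coupling off they land anywhere with enough CpGs; with coupling
    on they land on promoters and/or inside gene bodies of sampled genes
    so that the methylation change can drive expression.
    """
    cpgs = {
        c: cpg_positions(g.sequence)
        for c, g in genome.items()
        if not g.is_spike_in
    }
    rows = []

    def count_cpg(contig, s, e):
        pos = cpgs[contig]
        return int(np.searchsorted(pos, e) - np.searchsorted(pos, s))

    def homogeneous(contig, s, e):
        """Locally uniform CpG density, so the nominal regional effect
        size is the realized one (a window straddling a sharp density
        boundary, e.g. a CGI edge, would dilute the planted delta)."""
        half = (e - s) // 2
        n_l = count_cpg(contig, s, s + half)
        n_r = count_cpg(contig, e - half, e)
        if min(n_l, n_r) < 3 or max(n_l, n_r) > 3 * min(n_l, n_r):
            return False
        inside_density = (n_l + n_r) / (e - s)
        clen = len(genome[contig])
        n_out = count_cpg(contig, max(0, s - 300), s) + count_cpg(
            contig, e, min(clen, e + 300)
        )
        return n_out <= 2.0 * inside_density * 600

    if cfg.coupling == "none":
        contigs = [c for c in genome if not genome[c].is_spike_in]
        taken: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
        attempts = 0
        while len(rows) < cfg.n_true_dmrs and attempts < 200 * cfg.n_true_dmrs:
            attempts += 1
            contig = contigs[int(rng.integers(len(contigs)))]
            clen = len(genome[contig])
            s = int(rng.integers(0, clen - cfg.dmr_length))
            e = s + cfg.dmr_length
            if any(s < te + 2000 and e > ts - 2000 for ts, te in taken[contig]):
                continue
            if count_cpg(contig, s, e) < cfg.dmr_min_cpg:
                continue
            if not homogeneous(contig, s, e):
                continue
            taken[contig].append((s, e))
            rows.append((contig, s, e, None, None))
        if len(rows) < cfg.n_true_dmrs:
            raise ValueError("genome too CpG-sparse to plant the requested DMRs")
    else:
        want_prom = cfg.coupling in ("promoter_negative", "both")
        want_body = cfg.coupling in ("genebody_positive", "both")
        n_classes = int(want_prom) + int(want_body)
        order = rng.permutation(len(genes))
        n_prom = cfg.n_true_dmrs // n_classes if want_prom else 0
        n_body = cfg.n_true_dmrs - n_prom if want_body else 0
        # planted feature DMRs stay >= `clear` bp away from the TSS on
        # both sides: smoothing carries a called region ~span/2 past its
        # true edge, and a promoter call creeping across the TSS would
        # mislabel the gene body (and vice versa)
        clear = 400
        for gi in order:
            g = genes[gi]
            clen = len(genome[g.contig])
            if n_prom > 0:
                if g.strand == "+":
                    s, e = max(0, g.start - 1 - 2000), max(0, g.start - 1 - clear)
                else:
                    s, e = min(clen, g.end + clear), min(clen, g.end + 2000)
                if e > s and count_cpg(g.contig, s, e) >= cfg.dmr_min_cpg:
                    rows.append((g.contig, s, e, g.gene_id, "promoter"))
                    n_prom -= 1
                    continue
            if n_body > 0:
                if g.strand == "+":
                    s, e = g.start - 1 + clear, g.end
                else:
                    s, e = g.start - 1, g.end - clear
                if e > s and count_cpg(g.contig, s, e) >= cfg.dmr_min_cpg:
                    rows.append((g.contig, s, e, g.gene_id, "gene_body"))
                    n_body -= 1
            if n_prom == 0 and n_body == 0:
                break
        if n_prom > 0 or n_body > 0:
            raise ValueError("not enough CpG-dense gene features to plant coupled DMRs")

    direction = rng.choice(["hyper", "hypo"], size=len(rows))
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "target_gene", "region_class"])
    df["direction"] = direction
    df["delta"] = np.where(df["direction"] == "hyper", cfg.dmr_delta, -cfg.dmr_delta)
    return df.sort_values(["contig", "start"]).reset_index(drop=True)


def simulate_methylome(
    cfg: SimulationConfig,
    genome: dict[str, GenomeSequence],
    genes: list[GeneModel] | None = None,
    cgi_intervals: list[FeatureInterval] | None = None,
    truth_dmrs: pd.DataFrame | None = None,
) -> tuple[dict[str, pd.DataFrame], TruthManifest]:
    """Per-sample CpG count tables plus the truth manifest.

    Per CpG dyad (strands collapsed): baseline methylation m drawn from a
    Beta centred low inside CGI-like regions and high in background;
    inside a planted DMR the PC group is shifted by +-delta, with the
    baseline resampled so the shifted value stays in [0.05, 0.95] (the
    planted effect is never silently clipped away).  Each replicate's
    biological proportion is a beta draw around m with the configured
    dispersion; bisulfite non-conversion then acts per read, so the
    observed success probability is p_obs = m_i + (1 - m_i) * r and the
    methylated count is Binomial(n, p_obs) with coverage n ~ Poisson
    (depth) truncated at >= 1.  Keeping the conversion noise binomial
    (not beta-inflated) matters: a fully unmethylated site, e.g. on the
    spike-in contig, must show pure Binomial(n, r) noise for the site
    caller's FDR control to be meaningful.
    """
    rng = substream(cfg.seed, "methylome")
    if truth_dmrs is None:
        truth_dmrs = _plant_dmrs(cfg, genome, genes or [], substream(cfg.seed, "dmr-placement"))
    for _, d in truth_dmrs.iterrows():
        if d.contig not in genome or d.end > len(genome[d.contig]):
            raise ValueError(f"true DMR {d.contig}:{d.start}-{d.end} outside genome")

    # CGI-like membership per contig from supplied intervals or GC-rich runs
    cgi_by_contig: dict[str, list[tuple[int, int]]] = {}
    if cgi_intervals is not None:
        for iv in cgi_intervals:
            cgi_by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))

    conc = cfg.baseline_concentration
    r = cfg.nonconversion_rate
    phi = cfg.bb_dispersion
    n_rep = cfg.n_replicates_per_group
    methylomes: dict[str, list[pd.DataFrame]] = {s: [] for s in cfg.sample_names}
    site_baseline: dict[str, pd.DataFrame] = {}

    for contig, gseq in genome.items():
        pos0 = cpg_positions(gseq.sequence)
        if len(pos0) == 0:
            continue
        if gseq.is_spike_in:
            m_nc = np.zeros(len(pos0))
        else:
            in_cgi = np.zeros(len(pos0), dtype=bool)
            for s, e in cgi_by_contig.get(contig, []):
                in_cgi |= (pos0 >= s) & (pos0 < e)
            mean_ml = np.where(in_cgi, cfg.cgi_baseline_ml, cfg.background_baseline_ml)
            a = mean_ml * conc
            b = (1.0 - mean_ml) * conc
            m_nc = rng.beta(a, b)
        m_pc = m_nc.copy()
        sub = truth_dmrs[truth_dmrs["contig"] == contig]
        for _, d in sub.iterrows():
            inside = (pos0 >= d.start) & (pos0 < d.end)
            if not inside.any():
                continue
            delta = float(d.delta)
            lo, hi = (0.05, 0.95 - delta) if delta > 0 else (0.05 - delta, 0.95)
            base = rng.uniform(lo, hi, size=int(inside.sum()))
            m_nc[inside] = base
            m_pc[inside] = base + delta
        site_baseline[contig] = pd.DataFrame(
            {"pos": pos0 + 1, "m_nc": m_nc, "m_pc": m_pc}
        )
        for sample in cfg.sample_names:
            m = m_pc if sample.startswith("PC") else m_nc
            m_i = _beta_proportions(rng, m, phi)
            p_obs = m_i + (1.0 - m_i) * r
            cov = np.maximum(1, rng.poisson(cfg.depth_mean, size=len(pos0)))
            mc = rng.binomial(cov, p_obs)
            methylomes[sample].append(
                pd.DataFrame(
                    {
                        "contig": contig,
                        "pos": pos0 + 1,
                        "strand": ".",
                        "count_m": mc,
                        "count_u": cov - mc,
                    }
                )
            )

    out = {
        s: pd.concat(frames, ignore_index=True) for s, frames in methylomes.items()
    }
    truth = TruthManifest(dmrs=truth_dmrs, degs=pd.DataFrame(), site_baseline=site_baseline)
    return out, truth


def true_feature_ml(
    truth: TruthManifest, genes: list[GeneModel], contig_lengths: dict[str, int]
) -> pd.DataFrame:
    """Per-gene true mean methylation of promoter and gene body, per group.

    Computed from the truth manifest's baseline methylation, used to drive
    the expression coupling.
    """
    rows = []
    for g in genes:
        base = truth.site_baseline.get(g.contig)
        if base is None:
            continue
        pos0 = base["pos"].to_numpy() - 1
        clen = contig_lengths[g.contig]
        if g.strand == "+":
            ps, pe = max(0, g.start - 1 - 2000), g.start - 1
        else:
            ps, pe = g.end, min(clen, g.end + 2000)
        prom = (pos0 >= ps) & (pos0 < pe)
        body = (pos0 >= g.start - 1) & (pos0 < g.end)
        row = {"gene_id": g.gene_id}
        for grp, col in (("PC", "m_pc"), ("NC", "m_nc")):
            vals = base[col].to_numpy()
            row[f"promoter_{grp}"] = float(vals[prom].mean()) if prom.any() else 0.0
            row[f"genebody_{grp}"] = float(vals[body].mean()) if body.any() else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def simulate_expression(
    cfg: SimulationConfig,
    genes: list[GeneModel],
    truth: TruthManifest,
    feature_ml: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, TruthManifest]:
    """Negative-binomial count matrix with planted DEGs and coupling.

    counts_gj ~ NB(mean = s_j * q_gj, dispersion alpha).  True DEGs get
    q multiplied by 2^log2fc in PC; with coupling on, log q is shifted by
    -strength * promoter ML and/or +strength * gene-body ML of the
    sample's group, so differential methylation drives differential
    expression with the promoter-negative / gene-body-positive sign
    pattern.
    """
    rng = substream(cfg.seed, "expression")
    if cfg.coupling != "none" and feature_ml is None:
        raise ValueError("expression coupling requested without per-gene methylation input")

    gene_ids = [g.gene_id for g in genes]
    n_genes = len(gene_ids)
    q = np.exp(rng.normal(cfg.expr_mean_log, cfg.expr_sd_log, size=n_genes))

    coupled_genes = set()
    if cfg.coupling != "none":
        coupled_genes = set(truth.dmrs["target_gene"].dropna())
    candidates = [i for i, g in enumerate(gene_ids) if g not in coupled_genes]
    n_deg = min(cfg.n_true_degs, len(candidates))
    deg_idx = rng.choice(candidates, size=n_deg, replace=False) if n_deg else np.array([], int)
    deg_sign = rng.choice([1.0, -1.0], size=n_deg)
    log2fc = np.zeros(n_genes)
    log2fc[deg_idx] = deg_sign * cfg.deg_log2fc

    size_factors = rng.uniform(0.75, 1.3, size=len(cfg.sample_names))
    size_factors /= np.exp(np.mean(np.log(size_factors)))

    alpha = cfg.nb_dispersion
    cols = {}
    for j, sample in enumerate(cfg.sample_names):
        group = "PC" if sample.startswith("PC") else "NC"
        logq = np.log(q).copy()
        if group == "PC":
            logq += np.log(2.0) * log2fc
        if cfg.coupling != "none":
            fm = feature_ml.reindex(gene_ids)
            if cfg.coupling in ("promoter_negative", "both"):
                logq += -cfg.coupling_strength * fm[f"promoter_{group}"].to_numpy()
            if cfg.coupling in ("genebody_positive", "both"):
                logq += cfg.coupling_strength * fm[f"genebody_{group}"].to_numpy()
        mu = size_factors[j] * np.exp(logq)
        if alpha < 1e-8:
            cols[sample] = rng.poisson(mu)
        else:
            lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
            cols[sample] = rng.poisson(lam)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))

    degs = pd.DataFrame({"gene_id": np.array(gene_ids)[deg_idx], "log2fc": log2fc[deg_idx]})
    truth = replace_truth(truth, degs=degs.sort_values("gene_id").reset_index(drop=True),
                          gene_baseline=pd.DataFrame({"gene_id": gene_ids, "q": q}))
    return counts, truth


def replace_truth(truth: TruthManifest, **kw) -> TruthManifest:
    return TruthManifest(
        dmrs=kw.get("dmrs", truth.dmrs),
        degs=kw.get("degs", truth.degs),
        site_baseline=kw.get("site_baseline", truth.site_baseline),
        gene_baseline=kw.get("gene_baseline", truth.gene_baseline),
    )


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Full coupled dataset: genome, genes, methylomes, counts, truth."""
    from .annotation import detect_cgi

    genome, genes = simulate_genome(cfg)
    cgis = [
        iv
        for gseq in genome.values()
        if not gseq.is_spike_in
        for iv in detect_cgi(gseq)
    ]
    methylomes, truth = simulate_methylome(cfg, genome, genes, cgi_intervals=cgis)
    contig_lengths = {c: len(g) for c, g in genome.items()}
    fm = true_feature_ml(truth, genes, contig_lengths) if cfg.coupling != "none" else None
    counts, truth = simulate_expression(cfg, genes, truth, feature_ml=fm)
    return SimulatedDataset(cfg, genome, genes, methylomes, counts, truth)


# ---------------------------------------------------------------------------
# on-disk forms
# ---------------------------------------------------------------------------


def write_fasta(genome: dict[str, GenomeSequence], path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            s = seq.sequence
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")


def write_gtf(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.contig}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.contig}\tsim\texon\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def write_truth(truth: TruthManifest, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bed = truth.dmrs[["contig", "start", "end", "direction", "delta"]]
    bed.to_csv(outdir / "truth_dmrs.bed", sep="\t", header=False, index=False)
    truth.dmrs.to_csv(outdir / "truth_dmrs.tsv", sep="\t", index=False)
    truth.degs.to_csv(outdir / "truth_degs.tsv", sep="\t", index=False)
    if truth.gene_baseline is not None:
        truth.gene_baseline.to_csv(outdir / "truth_gene_baseline.tsv", sep="\t", index=False)
    for contig, df in truth.site_baseline.items():
        df.to_csv(outdir / f"truth_sites_{contig}.tsv", sep="\t", index=False)


def read_truth(outdir) -> TruthManifest:
    outdir = Path(outdir)
    dmrs = pd.read_csv(outdir / "truth_dmrs.tsv", sep="\t")
    for col in ("target_gene", "region_class"):
        if col in dmrs:
            dmrs[col] = dmrs[col].astype(object)
            dmrs.loc[dmrs[col].isna(), col] = None
    degs = pd.read_csv(outdir / "truth_degs.tsv", sep="\t")
    gb_path = outdir / "truth_gene_baseline.tsv"
    gene_baseline = pd.read_csv(gb_path, sep="\t") if gb_path.exists() else None
    site_baseline = {}
    for f in sorted(outdir.glob("truth_sites_*.tsv")):
        contig = f.stem.replace("truth_sites_", "")
        site_baseline[contig] = pd.read_csv(f, sep="\t")
    return TruthManifest(dmrs, degs, site_baseline, gene_baseline)


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write FASTA + GTF + per-sample cytosine reports + counts + truth."""
    from .io import write_count_matrix, write_cytosine_report

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    write_fasta(ds.genome, paths["genome"])
    paths["annotation"] = outdir / "genes.gtf"
    write_gtf(ds.genes, paths["annotation"])
    for sample, df in ds.methylomes.items():
        p = outdir / f"{sample}.cytosine.tsv"
        write_cytosine_report(df, p)
        paths[f"methylome:{sample}"] = p
    paths["counts"] = outdir / "counts.tsv"
    write_count_matrix(ds.counts, paths["counts"])
    write_truth(ds.truth, outdir / "truth")
    return paths
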
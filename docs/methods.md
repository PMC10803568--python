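# Methods

This note documents the statistical models behind `epilink`, the
numerical choices that are not visible from the API, what the synthetic
data generator does and does not emulate, and the known limitations.

## Site-level methylation model

Each CpG dyad is summarized by methylated (mC) and unmethylated (nonmC)
read counts; symmetric dyads may be collapsed onto the plus-strand
cytosine by summing both strands (`collapse_strands`), the standard
treatment for CpG context. The methylation level is ML = mC/(mC+nonmC),
defined only at positive coverage — zero-coverage sites raise an error
rather than silently reporting 0.

Bisulfite conversion failures make unmethylated cytosines read as
methylated at the non-conversion rate *r*, estimated by pooling all
cytosines of the unmethylated spike-in contig: r = ΣmC / Σ(mC+nonmC).
This is the maximum-likelihood binomial estimate; its standard error at
the default design (≈ 2×10⁵ spike-in reads) is ≈ 1.5×10⁻⁴.

A site is called methylated when its count is implausible under
conversion error alone: one-sided p = P(X ≥ mC | n, r) for
X ~ Binomial(n, r), BH-adjusted across all tested sites of a sample,
called at FDR α = 0.05. The test is upper-tailed because the alternative
("methylation above the error rate") is directional, and BH is used for
the FDR correction; both are conventional defaults rather than facts
about any particular dataset.

## Genomic features

Promoters are strand-aware 2-kb windows upstream of the TSS, clipped at
contig edges; gene bodies run TSS→TTS; introns are gene body minus
merged exons; UTRs are taken from the annotation when present. All
in-memory intervals are 0-based half-open; 1-based inclusive coordinates
appear only at file boundaries (GTF, cytosine reports). A DMR
overlapping both a promoter and a gene body yields labels in both
classes — region classes are deliberately not made exclusive, since a
gene can legitimately be differentially methylated in both compartments.

CpG islands are found de novo by Gardiner–Garden scanning: 200-bp
windows at 1-bp steps scored by GC fraction and
obs/exp CpG = N_CpG·L/(N_C·N_G) (0 when C or G is absent); qualifying
windows (all three criteria strict: length > 200 bp, GC > 0.5,
obs/exp > 0.65) are merged, and each merged region is trimmed at CpG
boundaries until the whole region satisfies the criteria. The trim is
greedy — drop the first or the last CpG, whichever removal leaves the
higher GC fraction, both on a tie — which approximates the maximal
qualifying sub-interval at O(n) cost and is symmetric under reverse
complement (verified by property test). An optional BED mask (e.g. a
repeat mask) excludes sequence before scanning; the default is no mask
because synthetic genomes are unmasked. Every emitted island re-scores
as an island; shores are the 2-kb flanks minus any island overlap.

## DMR calling

A deliberately transparent, simplified implementation of the
smoothed-Wald / beta-binomial approach popularized by DSS. It does not
attempt numerical equivalence with DSS.

**Smoothing.** Per group, site ML is replaced by the coverage-weighted
mean of all reads in a ±`span_bp`/2 window (default span 500 bp). The
window read total N is the effective sample size of the smoothed
estimate.

**Dispersion.** Between-replicate overdispersion is modelled as
beta-binomial with mean p and dispersion φ (α = p(1−φ)/φ,
β = (1−p)(1−φ)/φ), so Var(X) = n·p(1−p)(1+(n−1)φ). Per site, the
method-of-moments estimate solves E[s²/(p̄(1−p̄))] = φ + (1−φ)·mean(1/n)
with the replicate variance pooled across groups by degrees of freedom.
Raw estimates are shrunk toward a genome-wide target with weight
w = C/(C+300) (C = site coverage), clipped to [10⁻⁴, 0.999]. The target
is a ratio of sums (Σs² over Σp̄(1−p̄)), not a mean or median of
per-site ratios: at ~4 df the per-site ratio has a strongly skewed
sampling distribution, and averaging (worse, taking the median of)
ratios biases the target low, which deflates the Wald variance and
inflates the type-I error. With the pooled target, a planted φ = 0.1 is
recovered with median ≈ 0.10 and the site test's null rejection rate at
p < 0.05 sits at 0.045–0.056.

**Site test.** z = (p̂₁−p̂₂)/√(V₁+V₂) with
V_g = p_g(1−p_g)(1+(n̄_g−1)φ)/N_g, where N_g is the window read total
and n̄_g the mean per-replicate coverage. The p-value uses a Student-t
reference with df = (replicate-site draws in the two windows) − 2: the
variance estimate rests on a handful of beta draws, and a normal
reference has tails several-fold too light beyond |z| ≈ 4 — measured as
~4 spurious DMRs per 85k null sites with the normal reference versus
~0.5 per 10⁵ with the t reference.

**Segmentation.** Two thresholds: candidate sites at p < `p_extend`
(default 0.05) form maximal same-sign runs (one interior non-candidate
site may be bridged when the next candidate follows within span/2 — a
single noise dip must not split a sparse region whose CpG spacing
exceeds the merge gap); same-direction runs closer than `merge_gap`
(100 bp) are merged. A region qualifies if it contains a core site at
p < `p_site` (10⁻⁵) **or** passes a region-level Wald test at the same
level on the unsmoothed pooled counts of its span (t reference; the
binomial variance term aggregates per-site p(1−p), since the pooled-ML
form overstates the variance when site MLs vary). The two routes are
complementary: smoothing attenuates the group difference at region
edges and in CpG-sparse regions, so the strict per-site threshold alone
fires only in region centres, while the pooled statistic sees the
undiluted regional difference. Region edges are trimmed back to sites
with |smoothed Δ| ≥ `min_delta` whose raw site Δ has the region's sign
(high-coverage halo sites reach candidate significance at negligible
effect size and would otherwise drag boundaries ~250 bp outward).
Surviving regions must span ≥ `min_len` (50 bp, consistent with the
shortest regions such analyses report), contain ≥ `min_cpg` (3) CpGs
with ≥ `pct_sig` (0.5) of them candidates, and have coverage-weighted
|raw Δ| ≥ `min_delta` (0.1). Reported per-group MLs and Δ are
coverage-weighted raw values; `area_stat` is the sum of site Wald
statistics.

At the package's default design (Δ = 0.3, 30× coverage, 3v3, planted
500-bp regions), recovery at ≥ 50% reciprocal overlap is 0.86–1.0
sensitivity (median 0.94) and ≥ 0.92 precision across seeds, with a
null rate ≈ 0.5 called regions per 10⁵ sites. The residual misses are
regions whose pooled evidence lands just above p = 10⁻⁵ (typically 8
CpGs with a realized Δ slightly under 0.3) and occasional ~2σ flank
excursions that merge into a true region and shift its boundary.

**DMG mapping.** Any ≥ 1-bp overlap between a DMR and a promoter or
gene-body interval labels the gene as a DMG of that class and
direction; a gene can carry several labels. The summary reports, per
class, total / hyper / hypo / both-direction counts (satisfying
total = hyper + hypo − both) plus genes shared between the classes.

## Differential expression

A compact NB Wald workflow in the spirit of DESeq2, without Cook's
distance, independent filtering or LFC shrinkage — the package's focus
is the downstream integration, not DE methodology.

Size factors are median-of-ratios over genes expressed in all samples
(medians taken on the ratio scale, matching the literal definition),
rescaled to geometric mean 1. Per-gene NB dispersion α is estimated by
method of moments within groups, (s²−μ)/μ², pooled by df, then shrunk
(weight df/(df+10)) toward a trend over mean expression computed in
sliding 101-gene windows as a pooled moment ratio (Σ(s²−μ)/Σμ²) — a
running median would be biased low at 4 df for the same reason as
above. The Wald statistic uses the delta-method variance of the log
ratio, Var ≈ (1/μ₁+α)/n₁ + (1/μ₂+α)/n₂, with a 0.5 pseudocount guarding
zero-mean groups; all-zero genes are excluded from testing and from the
BH adjustment. Measured null behaviour at 3v3, α = 0.05: P(p<0.05) ≈
0.052–0.064; planted α = 0.2 recovered with median ≈ 0.18; power on
4-fold changes at deep coverage ≈ 1.0 under the strict DEG rule
(|log2FC| > 1 and padj < 0.05). Effect estimates agree with an
independent DESeq2 implementation (pydeseq2) to r > 0.999 on planted
fold changes; that implementation is used only as a cross-check.

Expression classes are computed per group on group-mean FPKM: "no"
below 1, then low/medium/high by the lower and upper quartiles of the
expressed genes (type-7 linear-interpolation quantiles; lower-inclusive
boundaries exactly as the class definitions state).

## Integration

Metagene profiles pool replicate counts per group, bin each gene into
20 fixed 100-bp upstream bins, 60 length-scaled body bins and 20
downstream bins (5′→3′; minus-strand genes reversed), average site MLs
within gene × bin, and then average over genes per expression class —
unweighted, so long genes do not dominate. Bins with no covered site
are missing, not zero.

Each DMG × region-class record carries delta_ml — the CpG-count-weighted
mean Δ of the gene's overlapping DMRs (a single scalar per record even
for multi-DMR genes) — and delta_expr, the DE log2 fold change.
Spearman's ρ is computed per region class; the p-value uses the
large-sample t approximation, switching to the exact permutation
distribution (full enumeration) below n = 10. Constant inputs raise an
error rather than returning NaN. Points are per gene; a per-DMR variant
can be built directly from the DMR table.

Enrichment is the upper-tail hypergeometric test per GMT term,
intersected with the universe (default: all genes tested for DE),
nominally significant at p < 0.05. GO/KEGG term collections are user
inputs; no ontology propagation is performed.

## Synthetic data generator

The generator emulates the study design the package targets: two groups
× three replicates, RRBS-like CpG counts, a lambda-like spike-in, and NB
expression counts. Defaults (all configurable, chosen once as
representative of somatic methylomes and bulk RNA-seq):

| parameter | default | meaning |
|---|---|---|
| genome | 2 × 400 kb + 20 kb spike-in | AT-rich, CpG-depleted background (CpG obs/exp ≈ 0.25) |
| CGI patches | ~50% of promoters + 8/contig | GC-rich iid patches (obs/exp ≈ 1) the scanner detects |
| baseline ML | Beta(mean 0.10, conc 15) in CGI; Beta(0.75, 15) elsewhere | low islands, high background |
| coverage | Poisson(30), truncated ≥ 1 | RRBS-like depth heterogeneity |
| dispersion φ | 0.1 | between-replicate beta-binomial noise |
| non-conversion r | 0.005 | >99% conversion efficiency |
| DMRs | 40 × 500 bp, Δ = 0.3, ≥ 8 CpGs | shift applied to the PC group |
| expression | q ~ LogNormal(log 300, 1.2), α = 0.05 | size factors U(0.75, 1.3), geometric mean 1 |
| DEGs | 60, |log2FC| = 2 | applied in PC |

Replicate biological proportions are beta draws around the site's m;
non-conversion then acts per read, so observed counts are
Binomial(n, m_i + (1−m_i)r). Keeping the conversion noise binomial
(rather than folding r into the beta) matters: a fully unmethylated
site must show pure Binomial(n, r) noise for FDR control of the site
caller to be meaningful — this is also chemically the right model, as
conversion failure is a per-molecule event, not a biological state.

Planted DMRs resample the baseline inside the region so that
baseline ± Δ stays in [0.05, 0.95]; otherwise clipping would silently
shrink the planted effect and the truth manifest would overstate it.
Placement requires locally homogeneous CpG density (balanced halves; no
300-bp flank more than twice as dense) for the same reason: a window
straddling a CGI edge has a realized regional effect far below the
nominal Δ. With coupling enabled, DMRs are planted on promoters and/or
gene bodies, kept ≥ 400 bp clear of the TSS (and promoter CGI patches
moved 400–800 bp upstream of it) so that a called promoter region's
smoothing halo cannot creep across the TSS and mislabel the gene body,
and vice versa. Expression coupling shifts log q by
−strength·(promoter ML) and/or +strength·(gene-body ML) of the sample's
group, computed from the true baseline methylation — so differential
methylation drives differential expression with the promoter-repressive
/ gene-body-activating sign pattern the integration stage must recover.

What the generator does **not** emulate: read-level data (FASTQ),
MspI fragment selection and the resulting coverage correlation along
fragments, M-bias, batch effects, strand-asymmetric methylation,
non-CpG contexts, isoform structure, and GC-dependent coverage bias.
Passing tests therefore demonstrate statistical correctness and
calibration of the downstream methods under a clean generative model,
not robustness to alignment artefacts or library chemistry.

## Validation experiments (`epilink.benchmarks`)

The acceptance checks run, at fixed problem sizes chosen to keep the
full suite in a couple of minutes on one CPU: site-caller FDR on 10⁵
fully unmethylated sites; DE null type-I on 5,000 genes; null DMR rate
on ~2.5×10⁵ sites; φ and α recovery (5,000 sites / 2,000 genes); DMR
recovery pooled over 4 × 50 planted regions (pooling controls the
~3.5% binomial standard error of a single 50-region run); DE power on
100 planted 4-fold genes; and the coupling sign pattern over 20 coupled
runs plus 50 uncoupled runs with ~300 DMG records per class. The
uncoupled pattern is assessed per region class: "p > 0.05" is a
5%-level event per class per seed, so the per-class seed fraction is
the quantity with a stable expectation (~0.95).

## Known limitations

* The Wald variance pools reads within group after smoothing; replicate
  identity is used only through the dispersion estimate. Strongly
  unbalanced replicate coverage is therefore handled only approximately.
* The DMR caller reports no region-level FDR; `p_site` acts as a
  genome-wide evidence threshold, as in DSS.
* The DE module is two-group only; no covariates, no multi-factor
  designs, no shrunken fold changes.
* UTR features require annotation support; they are never inferred from
  CDS records.
* Exact permutation p-values for Spearman correlations are enumerated
  only below n = 10 (9! ≈ 3.6×10⁵ permutations); above that the t
  approximation is used.
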
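"""Genome, gene-model and genomic-feature annotation.

Derives every feature class methylation is summarized over: promoters
(2 kb upstream of the TSS), gene bodies (TSS..TTS), exons, introns, UTRs
when annotated, CpG islands found de novo by Gardiner-Garden style
scanning, and CGI shores (2 kb flanks of each island).

Coordinate conventions: file formats keep their native convention
(FASTA/GTF 1-based inclusive, BED 0-based half-open); everything in memory
is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from intervaltree import IntervalTree

__all__ = [
    "GenomeSequence",
    "GeneModel",
    "FeatureInterval",
    "FeatureMap",
    "load_genome",
    "load_gene_models",
    "detect_cgi",
    "derive_features",
    "merge_intervals",
]

VALID_ALPHABET = frozenset("ACGTN")

FEATURE_CLASSES = (
    "promoter",
    "gene_body",
    "exon",
    "intron",
    "utr5",
    "utr3",
    "cgi",
    "cgi_shore",
)


@dataclass(frozen=True)
class GenomeSequence:
    """One contig: name, uppercase A/C/G/T/N sequence, spike-in flag."""

    contig_name: str
    sequence: str
    is_spike_in: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for contig {self.contig_name!r}")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"contig {self.contig_name!r} contains non-ACGTN characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene: 1-based inclusive span plus merged exons.

    TSS is the ``start`` terminus on the + strand and ``end`` on the -
    strand; the TTS is the opposite terminus.  ``gene_length`` is the sum
    of merged exon lengths, the denominator FPKM uses.
    """

    gene_id: str
    contig: str
    strand: str
    start: int  # 1-based inclusive
    end: int
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive, merged, sorted
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id!r}: start > end")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id!r} has no exons")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"gene {self.gene_id!r}: exon {s}..{e} outside gene span "
                    f"{self.start}..{self.end}"
                )

    @property
    def tss(self) -> int:
        """Transcription start site, 1-based."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        """Transcription termination site, 1-based."""
        return self.end if self.strand == "+" else self.start

    @property
    def gene_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass(frozen=True)
class FeatureInterval:
    """A 0-based half-open interval of one feature class."""

    contig: str
    start: int
    end: int
    feature_class: str
    owner_gene: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"degenerate interval {self.contig}:{self.start}-{self.end}"
            )
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")


def load_genome(
    path, spike_in_contig: str | None = "lambda_spike"
) -> dict[str, GenomeSequence]:
    """Read a FASTA into a dict of :class:`GenomeSequence`.

    Lowercase bases are uppercased.  The contig named ``spike_in_contig``
    (if present) is flagged as the unmethylated conversion-control
    spike-in.  Duplicate headers and empty records are errors.
    """
    genome: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
        genome[rec.id] = GenomeSequence(
            contig_name=rec.id,
            sequence=str(rec.seq).upper(),
            is_spike_in=(rec.id == spike_in_contig),
        )
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def _merge_1based(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def load_gene_models(path) -> list[GeneModel]:
    """Parse gene models from GTF/GFF3 via gffutils.

    One :class:`GeneModel` per ``gene`` feature; exons are pooled across
    transcripts by their ``gene_id`` attribute and merged when they
    overlap.  A gene without exons, an exon outside its gene span, or a
    strand other than +/- is an error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    def _gene_id(feat) -> str | None:
        for key in ("gene_id", "ID", "Parent", "gene"):
            if key in feat.attributes:
                val = feat.attributes[key][0]
                return val.split(":", 1)[-1]
        return None

    exons: dict[str, list[tuple[int, int]]] = {}
    utr5: dict[str, list[tuple[int, int]]] = {}
    utr3: dict[str, list[tuple[int, int]]] = {}
    buckets = {
        "exon": exons,
        "five_prime_utr": utr5,
        "five_prime_UTR": utr5,
        "three_prime_utr": utr3,
        "three_prime_UTR": utr3,
    }
    for ftype, bucket in buckets.items():
        for feat in db.features_of_type(ftype):
            gid = _gene_id(feat)
            if gid is None:
                raise ValueError(f"{ftype} record without gene_id at {feat.seqid}:{feat.start}")
            if feat.strand not in ("+", "-"):
                raise ValueError(
                    f"{ftype} of gene {gid!r} has unknown strand {feat.strand!r}"
                )
            bucket.setdefault(gid, []).append((feat.start, feat.end))

    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        gid = _gene_id(feat)
        if gid is None:
            raise ValueError(f"gene record without gene_id at {feat.seqid}:{feat.start}")
        if gid not in exons:
            raise ValueError(f"gene {gid!r} has no exon records")
        genes.append(
            GeneModel(
                gene_id=gid,
                contig=feat.seqid,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
                exons=_merge_1based(exons[gid]),
                utr5=_merge_1based(utr5.get(gid, [])),
                utr3=_merge_1based(utr3.get(gid, [])),
            )
        )
    genes.sort(key=lambda g: (g.contig, g.start))
    return genes


# ---------------------------------------------------------------------------
# CpG island scanning
# ---------------------------------------------------------------------------


def _cgi_stats(cum_c, cum_g, cum_cpg, a: int, b: int) -> tuple[int, float, float]:
    """(length, GC fraction, obs/exp CpG) for the 0-based window [a, b)."""
    length = b - a
    n_c = int(cum_c[b] - cum_c[a])
    n_g = int(cum_g[b] - cum_g[a])
    # CpG dinucleotide starts lie in [a, b-1)
    n_cpg = int(cum_cpg[b - 1] - cum_cpg[a]) if b - 1 > a else 0
    gc = (n_c + n_g) / length
    oe = (n_cpg * length) / (n_c * n_g) if n_c > 0 and n_g > 0 else 0.0
    return length, gc, oe


def detect_cgi(
    seq: GenomeSequence | str,
    min_len: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.65,
    mask: Sequence[tuple[int, int]] | None = None,
    window: int = 200,
) -> list[FeatureInterval]:
    """Find CpG islands: maximal regions >``min_len`` bp with GC fraction
    >``min_gc`` and observed/expected CpG >``min_oe`` (all strict).

    Scans ``window``-bp windows at 1-bp step, merges qualifying windows,
    then greedily trims each merged region at CpG boundaries until the
    whole region satisfies all three criteria.  obs/exp follows the
    Gardiner-Garden convention (N_CpG * L) / (N_C * N_G); windows without
    both C and G score 0.  ``mask`` intervals (0-based half-open, e.g. a
    repeat mask) are excluded before scanning.
    """
    if isinstance(seq, GenomeSequence):
        contig, s = seq.contig_name, seq.sequence
    else:
        contig, s = "seq", str(seq).upper()
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()
    if mask:
        for ms, me in mask:
            arr[max(0, ms) : max(0, me)] = ord("N")
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    n = len(arr)
    if n < window + 1:
        return []
    is_cpg = np.zeros(n, dtype=bool)
    is_cpg[:-1] = is_c[:-1] & is_g[1:]
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cpg = np.concatenate([[0], np.cumsum(is_cpg)])

    starts = np.arange(0, n - window + 1)
    n_c = cum_c[starts + window] - cum_c[starts]
    n_g = cum_g[starts + window] - cum_g[starts]
    n_cpg = cum_cpg[starts + window - 1] - cum_cpg[starts]
    gc_ok = (n_c + n_g) > min_gc * window
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(
            (n_c > 0) & (n_g > 0), n_cpg * window / (n_c * n_g + 1e-300), 0.0
        )
    qualifying = gc_ok & (oe > min_oe)
    if not qualifying.any():
        return []

    # merge overlapping / adjacent qualifying windows into candidate regions
    qs = starts[qualifying]
    regions: list[list[int]] = []
    for a in qs:
        b = a + window
        if regions and a <= regions[-1][1]:
            regions[-1][1] = b
        else:
            regions.append([a, b])

    cpg_pos = np.flatnonzero(is_cpg)
    islands: list[FeatureInterval] = []
    for a, b in regions:
        iv = _trim_region(a, b, cpg_pos, cum_c, cum_g, cum_cpg, min_len, min_gc, min_oe)
        if iv is not None:
            islands.append(FeatureInterval(contig, iv[0], iv[1], "cgi"))
    return islands


def _trim_region(
    a, b, cpg_pos, cum_c, cum_g, cum_cpg, min_len, min_gc, min_oe
) -> tuple[int, int] | None:
    """Greedy trim of [a, b) to a sub-interval meeting all CGI criteria.

    The region is snapped to CpG boundaries; while it fails, the first or
    last CpG is dropped — whichever removal yields the higher GC fraction
    (both on a tie, which keeps the procedure symmetric under
    reverse-complement).
    """
    lo = np.searchsorted(cpg_pos, a, side="left")
    hi = np.searchsorted(cpg_pos, b - 1, side="right")  # CpG must fit inside
    while hi - lo > 0:
        ca, cb = int(cpg_pos[lo]), int(cpg_pos[hi - 1]) + 2
        length, gc, oe = _cgi_stats(cum_c, cum_g, cum_cpg, ca, cb)
        if length > min_len and gc > min_gc and oe > min_oe:
            return ca, cb
        if hi - lo == 1:
            return None
        _, gc_dropfirst, _ = _cgi_stats(cum_c, cum_g, cum_cpg, int(cpg_pos[lo + 1]), cb)
        _, gc_droplast, _ = _cgi_stats(cum_c, cum_g, cum_cpg, ca, int(cpg_pos[hi - 2]) + 2)
        if gc_dropfirst > gc_droplast:
            lo += 1
        elif gc_droplast > gc_dropfirst:
            hi -= 1
        else:
            lo += 1
            hi -= 1
    return None


# ---------------------------------------------------------------------------
# Feature map
# ---------------------------------------------------------------------------


def merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent 0-based half-open intervals."""
    out: list[list[int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _subtract(
    ivs: list[tuple[int, int]], minus: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference of interval lists (both 0-based half-open)."""
    minus = merge_intervals(minus)
    out: list[tuple[int, int]] = []
    for s, e in merge_intervals(ivs):
        cur = s
        for ms, me in minus:
            if me <= cur or ms >= e:
                continue
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


@dataclass
class FeatureMap:
    """Interval index per feature class, with owner genes where defined."""

    intervals: dict[str, list[FeatureInterval]] = field(default_factory=dict)
    _merged: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False
    )

    def add(self, iv: FeatureInterval) -> None:
        self.intervals.setdefault(iv.feature_class, []).append(iv)
        self._merged.clear()

    def classes(self) -> list[str]:
        return [c for c in FEATURE_CLASSES if c in self.intervals]

    def _merged_arrays(self, cls: str, contig: str) -> tuple[np.ndarray, np.ndarray]:
        key = (cls, contig)
        if key not in self._merged:
            ivs = [
                (iv.start, iv.end)
                for iv in self.intervals.get(cls, [])
                if iv.contig == contig
            ]
            m = merge_intervals(ivs)
            self._merged[key] = (
                np.array([s for s, _ in m], dtype=np.int64),
                np.array([e for _, e in m], dtype=np.int64),
            )
        return self._merged[key]

    def membership(self, cls: str, contig: str, pos0: np.ndarray) -> np.ndarray:
        """Boolean array: does each 0-based position fall in class ``cls``?"""
        starts, ends = self._merged_arrays(cls, contig)
        if len(starts) == 0:
            return np.zeros(len(pos0), dtype=bool)
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos0[ok] < ends[idx[ok]]
        return ok

    def tree(self, cls: str, contig: str) -> IntervalTree:
        """IntervalTree of class ``cls`` on ``contig`` (data = owner gene)."""
        t = IntervalTree()
        for iv in self.intervals.get(cls, []):
            if iv.contig == contig:
                t.addi(iv.start, iv.end, iv.owner_gene)
        return t

    def contigs(self, cls: str) -> list[str]:
        return sorted({iv.contig for iv in self.intervals.get(cls, [])})


def derive_features(
    genes: Sequence[GeneModel],
    cgis: Sequence[FeatureInterval],
    contig_lengths: Mapping[str, int],
    promoter_size: int = 2000,
    shore_size: int = 2000,
) -> FeatureMap:
    """Build the feature map: promoters, gene bodies, exons, introns, UTRs
    (when annotated), CGIs and CGI shores.

    Promoters are strand-aware ``promoter_size``-bp windows upstream of the
    TSS, clipped at contig edges; shores are flanks of each island minus
    any island overlap; introns are gene body minus exons.  All intervals
    are emitted 0-based half-open.
    """
    fmap = FeatureMap()
    for g in genes:
        if g.contig not in contig_lengths:
            raise ValueError(f"gene {g.gene_id!r} on unknown contig {g.contig!r}")
        clen = contig_lengths[g.contig]
        body = (g.start - 1, g.end)
        fmap.add(FeatureInterval(g.contig, *body, "gene_body", g.gene_id))
        if g.strand == "+":
            ps, pe = max(0, g.start - 1 - promoter_size), g.start - 1
        else:
            ps, pe = g.end, min(clen, g.end + promoter_size)
        if ps < pe:
            fmap.add(FeatureInterval(g.contig, ps, pe, "promoter", g.gene_id))
        exon_ivs = [(s - 1, e) for s, e in g.exons]
        for s, e in exon_ivs:
            fmap.add(FeatureInterval(g.contig, s, e, "exon", g.gene_id))
        for s, e in _subtract([body], exon_ivs):
            fmap.add(FeatureInterval(g.contig, s, e, "intron", g.gene_id))
        for cls, ivs in (("utr5", g.utr5), ("utr3", g.utr3)):
            for s, e in ivs:
                fmap.add(FeatureInterval(g.contig, s - 1, e, cls, g.gene_id))

    cgi_by_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in cgis:
        fmap.add(FeatureInterval(iv.contig, iv.start, iv.end, "cgi"))
        cgi_by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    for contig, ivs in cgi_by_contig.items():
        clen = contig_lengths.get(contig)
        shores: list[tuple[int, int]] = []
        for s, e in ivs:
            left = (max(0, s - shore_size), s)
            right = (e, e + shore_size if clen is None else min(clen, e + shore_size))
            shores.extend([left, right])
        for s, e in _subtract(shores, ivs):
            fmap.add(FeatureInterval(contig, s, e, "cgi_shore"))
    return fmap
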
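"""Readers and writers for the flat-file interfaces.

Cytosine-level methylation is exchanged in two Bismark dialects:

* cytosine report — 7 columns: contig, 1-based position, strand,
  count_methylated, count_unmethylated, context, trinucleotide;
* coverage file — 6 columns: contig, start, end (1-based, start == end),
  percent methylation, count_methylated, count_unmethylated.

Both are normalized to a DataFrame with columns
``contig, pos, strand, count_m, count_u`` (pos 1-based).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "read_cytosine_report",
    "write_cytosine_report",
    "read_methylation_file",
    "read_count_matrix",
    "write_count_matrix",
    "read_gmt",
    "write_gmt",
    "write_bed",
]

_REPORT_COLS = ["contig", "pos", "strand", "count_m", "count_u", "context", "tri"]
_COVERAGE_COLS = ["contig", "pos", "end", "pct", "count_m", "count_u"]
_CORE = ["contig", "pos", "strand", "count_m", "count_u"]


def read_cytosine_report(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=_REPORT_COLS, dtype={0: str})
    return df[_CORE].copy()


def read_methylation_file(path) -> pd.DataFrame:
    """Read either dialect, sniffed by column count."""
    head = pd.read_csv(path, sep="\t", header=None, nrows=1)
    ncol = head.shape[1]
    if ncol >= 7:
        return read_cytosine_report(path)
    if ncol == 6:
        df = pd.read_csv(path, sep="\t", header=None, names=_COVERAGE_COLS, dtype={0: str})
        df["strand"] = "."
        return df[_CORE].copy()
    raise ValueError(f"{path}: expected 6 (coverage) or 7 (cytosine report) columns, got {ncol}")


def write_cytosine_report(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "context" not in out:
        out["context"] = "CpG"
    if "tri" not in out:
        out["tri"] = "CGN"
    out[_REPORT_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_count_matrix(path) -> pd.DataFrame:
    """Gene x sample integer count matrix, gene ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df


def write_count_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path) -> dict[str, tuple[str, frozenset[str]]]:
    """GMT gene sets: term -> (description, genes)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT line with fewer than 3 fields: {line[:50]!r}")
        term, desc, genes = parts[0], parts[1], parts[2:]
        sets[term] = (desc, frozenset(g for g in genes if g))
    return sets


def write_gmt(sets: Mapping[str, tuple[str, Iterable[str]]], path) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in sets.items():
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def write_bed(intervals: Iterable[tuple], path, extra_header: str | None = None) -> None:
    """Write BED rows (tuples of columns, 0-based half-open)."""
    with open(path, "w") as fh:
        if extra_header:
            fh.write("#" + extra_header + "\n")
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")
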
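"""Read collapsing and CPM filtering for trimmed small-RNA libraries.

Reads (FASTA/FASTQ, optionally gzipped) are collapsed to unique sequences with
per-sample counts.  Counts-per-million are computed against the per-sample total
of reads entering the collapse (after dropping ambiguous reads), so pre-filter
CPM values sum to one million in every sample.  Sequences are then retained if
they reach the CPM threshold (default 10, boundary inclusive: a sequence at
exactly 10 CPM is kept) in at least one sample; per-sample retention flags are
kept alongside so per-sample tallies remain reproducible.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._util import is_unambiguous, normalize_seq

MIN_LEN = 15
MAX_LEN = 75


@dataclass
class LibraryStats:
    sample_id: str
    total_reads: int
    reads_discarded_ambiguous: int
    reads_discarded_length: int
    sequences_pre_filter: int
    sequences_post_filter: int | None = None


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(path: str | Path) -> Iterable[str]:
    """Yield raw read strings from FASTA or FASTQ (gzip-transparent).

    Format is taken from the file name; .fq/.fastq parse as FASTQ, anything
    else as FASTA.
    """
    name = str(path)
    base = name[:-3] if name.endswith(".gz") else name
    fastq = base.endswith((".fq", ".fastq"))
    with _open_text(path) as fh:
        if fastq:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                yield seq
        else:
            for _title, seq in SimpleFastaParser(fh):
                yield seq


def clip_adapter(seq: str, adapter: str, min_overlap: int = 1) -> str:
    """Clip a 3' adapter: remove from the first occurrence of an adapter prefix
    (>= min_overlap nt) at the read's 3' end.  Plumbing only — the pipeline
    expects pre-trimmed reads."""
    for i in range(len(seq)):
        tail = seq[i:]
        if adapter.startswith(tail) and len(tail) >= min_overlap:
            return seq[:i]
        if tail.startswith(adapter):
            return seq[:i]
    return seq


def collapse(
    reads_by_sample: Mapping[str, Iterable[str] | str | Path],
) -> tuple[pd.DataFrame, dict[str, LibraryStats]]:
    """Collapse reads to unique sequences with per-sample counts.

    ``reads_by_sample`` maps sample id to an iterable of read strings or to a
    FASTA/FASTQ path.  Reads are uppercased with U mapped to T; reads containing
    ambiguity codes, or outside 15–75 nt, are discarded and tallied.

    Returns a counts DataFrame (index: sequence; one column per sample) and
    per-sample :class:`LibraryStats`.
    """
    counters: dict[str, dict[str, int]] = {}
    stats: dict[str, LibraryStats] = {}
    for sample, src in reads_by_sample.items():
        reads = read_sequences(src) if isinstance(src, (str, Path)) else src
        ctr: dict[str, int] = {}
        n_total = n_amb = n_len = 0
        for raw in reads:
            seq = normalize_seq(raw)
            if not is_unambiguous(seq):
                n_amb += 1
                continue
            if not MIN_LEN <= len(seq) <= MAX_LEN:
                n_len += 1
                continue
            n_total += 1
            ctr[seq] = ctr.get(seq, 0) + 1
        counters[sample] = ctr
        stats[sample] = LibraryStats(
            sample_id=sample,
            total_reads=n_total,
            reads_discarded_ambiguous=n_amb,
            reads_discarded_length=n_len,
            sequences_pre_filter=len(ctr),
        )
    counts = pd.DataFrame(counters).fillna(0).astype(int)
    counts = counts.reindex(columns=list(reads_by_sample))
    counts.index.name = "sequence"
    return counts.sort_index(), stats


def library_totals(counts: pd.DataFrame) -> pd.Series:
    """Per-sample CPM denominators: the pre-filter collapsed totals."""
    return counts.sum(axis=0)


def compute_cpm(counts: pd.DataFrame, totals: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million per sample. ``totals`` defaults to the column sums of
    ``counts``; pass the pre-filter totals when computing CPM on a subset."""
    if totals is None:
        totals = library_totals(counts)
    totals = totals.astype(float)
    return (counts * 1e6).div(totals.where(totals > 0), axis=1).fillna(0.0)


def filter_cpm(
    counts: pd.DataFrame,
    threshold: float = 10.0,
    totals: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain sequences reaching ``threshold`` CPM in at least one sample.

    The boundary is inclusive: exactly-threshold CPM is retained ("under"
    threshold is discarded).  Returns the retained counts and a boolean
    per-sample retention-flag frame over the retained sequences
    (``retained_in[s] = cpm[s] >= threshold``).
    """
    if threshold < 0:
        raise ValueError("CPM threshold must be >= 0")
    cpm = compute_cpm(counts, totals)
    flags = cpm >= threshold
    keep = flags.any(axis=1)
    return counts.loc[keep], flags.loc[keep]


def expand(counts: pd.DataFrame, sample: str) -> list[str]:
    """Inverse of collapse for one sample: the multiset of reads, sorted."""
    out: list[str] = []
    for seq, n in counts[sample].items():
        out.extend([seq] * int(n))
    return sorted(out)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sequence")


def stats_table(stats: Mapping[str, LibraryStats]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in stats.values()]).set_index("sample_id")
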
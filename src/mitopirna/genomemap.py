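"""Bounded-mismatch placement of small-RNA sequences on nuclear and mitochondrial genomes.

Every retained sequence is searched against two genomes independently, allowing at
most ``k`` substitutions (no indels, i.e. Hamming distance), on both strands.  Only
the minimal-distance stratum is reported: if a sequence has any perfect placement on
a genome, imperfect placements on that same genome are suppressed.  The mitochondrial
genome is circular; the search text is extended by a copy of its first 74 bases so
junction-spanning placements are found, with coordinates reported modulo the length.

The class label of a sequence follows from hit existence:

* ``NU``       — hits on the nuclear genome only
* ``MT``       — hits on the mitochondrial genome only
* ``NUMT``     — hits on both (the nuclear copy is a nuclear-mitochondrial insertion)
* ``UNMAPPED`` — hits on neither

Coordinates are 1-based inclusive throughout the public interface (GenBank
convention); the BED writer converts to 0-based half-open at the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from ._util import hamming_le, revcomp

MAX_QUERY_LEN = 75
#: extension appended to a circular sequence so any query up to MAX_QUERY_LEN
#: can span the junction
_CIRC_EXT = MAX_QUERY_LEN - 1

NUCLEAR = "nuclear"
MITO = "mito"

CLASS_NU = "NU"
CLASS_MT = "MT"
CLASS_NUMT = "NUMT"
CLASS_UNMAPPED = "UNMAPPED"


@dataclass(frozen=True, order=True)
class GenomeHit:
    """One placement of a query on a genome.

    ``start`` is the 1-based leftmost coordinate of the aligned window on the
    forward reference strand; for a minus-strand hit the query's 5' end sits at
    ``start + len(query) - 1``.  ``window(...)`` reconstructs the genomic string
    the query was compared against.
    """

    genome: str
    contig: str
    strand: str
    start: int
    mismatches: int

    def five_prime_position(self, query_len: int, circular_length: int | None = None) -> int:
        """1-based coordinate of the query's 5' end on the forward reference."""
        if self.strand == "+":
            return self.start
        pos = self.start + query_len - 1
        if circular_length is not None:
            pos = (pos - 1) % circular_length + 1
        return pos


class Genome:
    """A named set of contigs, optionally circular (single-contig mitochondrial)."""

    def __init__(self, contigs: dict[str, str], *, circular: bool = False, name: str = NUCLEAR):
        if not contigs:
            raise ValueError("genome needs at least one contig")
        self.name = name
        self.circular = circular
        self.contigs = {c: s.upper() for c, s in contigs.items()}
        # search texts: circular contigs are extended so windows may wrap once
        self._texts = {
            c: (s + s[:_CIRC_EXT] if circular else s) for c, s in self.contigs.items()
        }

    @classmethod
    def from_fasta(cls, path: str | Path, *, circular: bool = False, name: str = NUCLEAR) -> "Genome":
        contigs: dict[str, str] = {}
        with open(path) as fh:
            for header, seq in SimpleFastaParser(fh):
                contigs[header.split()[0]] = seq.upper()
        return cls(contigs, circular=circular, name=name)

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def window(self, contig: str, strand: str, start: int, length: int) -> str:
        """Genomic string a query aligned at (contig, strand, start, length) was
        compared against (reverse-complemented for minus-strand hits)."""
        text = self._texts[contig]
        w = text[start - 1 : start - 1 + length]
        return revcomp(w) if strand == "-" else w


def _candidate_starts(text: str, pattern: str, k: int) -> set[int]:
    """Pigeonhole seeding: split the pattern into k+1 chunks; any placement with
    <= k mismatches matches at least one chunk exactly."""
    L = len(pattern)
    n = len(text)
    parts = k + 1
    bounds = [i * L // parts for i in range(parts + 1)]
    cand: set[int] = set()
    for i in range(parts):
        chunk = pattern[bounds[i] : bounds[i + 1]]
        off = bounds[i]
        j = text.find(chunk)
        while j != -1:
            s = j - off
            if 0 <= s <= n - L:
                cand.add(s)
            j = text.find(chunk, j + 1)
    return cand


def find_hits(query: str, genome: Genome, k: int = 1) -> list[GenomeHit]:
    """All minimal-stratum placements of ``query`` on ``genome`` with <= k mismatches.

    Both strands are searched.  Raises ``ValueError`` for k outside 1..3 or an
    overlong query; queries are expected to be plain ACGT (enforced upstream).
    """
    if not 0 <= k <= 3:
        raise ValueError(f"mismatch allowance k={k} out of range 0..3")
    if len(query) > MAX_QUERY_LEN:
        raise ValueError(f"query longer than {MAX_QUERY_LEN} nt")
    L = len(query)
    hits: list[GenomeHit] = []
    for contig, text in genome._texts.items():
        clen = len(genome.contigs[contig])
        if L > clen:
            continue
        for strand, pattern in (("+", query), ("-", revcomp(query))):
            for s0 in _candidate_starts(text, pattern, k):
                if genome.circular and s0 >= clen:
                    continue  # wrapped duplicate of a start already in range
                mm = hamming_le(pattern, text[s0 : s0 + L], k)
                if mm >= 0:
                    hits.append(GenomeHit(genome.name, contig, strand, s0 + 1, mm))
    if not hits:
        return []
    best = min(h.mismatches for h in hits)
    return sorted(h for h in hits if h.mismatches == best)


def classify(query: str, nuclear: Genome, mito: Genome, k: int = 1) -> tuple[str, list[GenomeHit]]:
    """NU/MT/NUMT/UNMAPPED label plus the cached minimal-stratum hits of both genomes.

    The two genomes are searched independently (the minimal stratum is taken per
    genome, not across genomes), so a perfect nuclear placement does not mask a
    one-mismatch mitochondrial placement.
    """
    nuc_hits = find_hits(query, nuclear, k)
    mt_hits = find_hits(query, mito, k)
    if nuc_hits and mt_hits:
        label = CLASS_NUMT
    elif mt_hits:
        label = CLASS_MT
    elif nuc_hits:
        label = CLASS_NU
    else:
        label = CLASS_UNMAPPED
    return label, nuc_hits + mt_hits


def span_length(a: int, b: int, *, circular_length: int | None = None):
    """Inclusive span between two 1-based coordinates, order-free.

    ``span_length(16119, 16188)`` is 70.  With ``circular_length`` the wrap-around
    alternative ``L - |a-b| + 1`` is returned as well, as ``(linear, circular)``.
    """
    if a < 1 or b < 1:
        raise ValueError("coordinates are 1-based; got a value < 1")
    linear = abs(a - b) + 1
    if circular_length is None:
        return linear
    return linear, circular_length - abs(a - b) + 1


# ---------------------------------------------------------------------------
# serialization

def hits_to_str(hits: Iterable[GenomeHit]) -> str:
    return ";".join(f"{h.genome}:{h.contig}:{h.strand}:{h.start}:{h.mismatches}" for h in hits)


def hits_from_str(s: str) -> list[GenomeHit]:
    if not s or s != s:  # empty or NaN
        return []
    out = []
    for part in str(s).split(";"):
        g, c, st, pos, mm = part.split(":")
        out.append(GenomeHit(g, c, st, int(pos), int(mm)))
    return out


def hits_table(queries: dict[str, list[GenomeHit]]) -> pd.DataFrame:
    """Long-form 1-based inclusive hit table (one row per hit)."""
    rows = [
        {
            "sequence": q,
            "genome": h.genome,
            "contig": h.contig,
            "strand": h.strand,
            "start": h.start,
            "end": h.start + len(q) - 1,
            "mismatches": h.mismatches,
        }
        for q, hs in queries.items()
        for h in hs
    ]
    return pd.DataFrame(rows, columns=["sequence", "genome", "contig", "strand", "start", "end", "mismatches"])


def write_hits_bed(queries: dict[str, list[GenomeHit]], path: str | Path) -> None:
    """BED6 export; the 1-based inclusive internal convention becomes 0-based
    half-open here and nowhere else."""
    with open(path, "w") as fh:
        for q, hs in queries.items():
            for h in hs:
                fh.write(
                    f"{h.contig}\t{h.start - 1}\t{h.start - 1 + len(q)}\t{q}\t{h.mismatches}\t{h.strand}\n"
                )
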
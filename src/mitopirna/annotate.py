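"""Reference-set matching and mitochondrial feature assignment.

A sequence is called a piRNA if it matches an entry of the PIWI-immunoprecipitation
piRNA reference set at equal length within 1 mismatch, a miRNA if it matches the
miRNA reference set at equal length within 2 mismatches, "dual" if both, and
"other" if neither.  Equal-length Hamming matching keeps the mature/precursor
distinction sharp: a precursor never matches the reference set through a shared
prefix (precursor-prefix relations are the families module's job).

Mitochondrially placed sequences are assigned to annotated genome features
(tRNA/rRNA/CDS/D-loop/origin) with an orientation: forward when the read strand
equals the feature's annotated strand, reverse otherwise.  The D-loop carries no
transcript strand, so its orientation baseline is the forward reference strand —
a minus-strand read in the D-loop is "reverse".  Positions not covered by any
feature are reported as "intergenic", so per-hit overlap lengths always sum to
the read length.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from ._util import hamming_le, normalize_seq
from .genomemap import GenomeHit

CAT_PIRNA = "piRNA"
CAT_MIRNA = "miRNA"
CAT_DUAL = "dual"
CAT_OTHER = "other"

FEATURE_TYPES = ("tRNA", "rRNA", "D-loop", "CDS", "origin", "intergenic")


@dataclass
class DbMatch:
    pirna_ids: list[str] = field(default_factory=list)
    mirna_ids: list[str] = field(default_factory=list)

    @property
    def pirna_multi(self) -> bool:
        return len(self.pirna_ids) > 1

    @property
    def category(self) -> str:
        if self.pirna_ids and self.mirna_ids:
            return CAT_DUAL
        if self.pirna_ids:
            return CAT_PIRNA
        if self.mirna_ids:
            return CAT_MIRNA
        return CAT_OTHER


@dataclass(frozen=True)
class FeatureOverlap:
    feature_name: str
    feature_type: str
    orientation: str  # forward | reverse
    overlap_nt: int


def load_reference(path: str | Path) -> dict[str, str]:
    """Load a reference set from FASTA (id in header) or two-column TSV
    (id<TAB>sequence).  Sequences are normalized to DNA uppercase."""
    path = str(path)
    db: dict[str, str] = {}
    if path.endswith((".fa", ".fasta", ".fna")):
        with open(path) as fh:
            for header, seq in SimpleFastaParser(fh):
                db[header.split()[0]] = normalize_seq(seq)
    else:
        for line in open(path):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, seq = line.split("\t")[:2]
            db[name] = normalize_seq(seq)
    return db


def match_db(query: str, db: dict[str, str], k: int) -> list[tuple[str, int]]:
    """Equal-length Hamming matches of ``query`` against a reference set.

    Only entries of the same length are compared (same strand, no offsets); all
    matches within the minimal-distance stratum are returned, sorted by id.
    """
    L = len(query)
    matches = []
    for name, seq in db.items():
        if len(seq) != L:
            continue
        mm = hamming_le(query, seq, k)
        if mm >= 0:
            matches.append((name, mm))
    if not matches:
        return []
    best = min(m for _, m in matches)
    return sorted((n, m) for n, m in matches if m == best)


def categorize(query: str, pirna_db: dict[str, str], mirna_db: dict[str, str],
               k_pirna: int = 1, k_mirna: int = 2) -> DbMatch:
    """piRNA/miRNA/dual/other call for one sequence."""
    return DbMatch(
        pirna_ids=[n for n, _ in match_db(query, pirna_db, k_pirna)],
        mirna_ids=[n for n, _ in match_db(query, mirna_db, k_mirna)],
    )


# ---------------------------------------------------------------------------
# feature annotation

def load_features(path: str | Path) -> pd.DataFrame:
    """Load a mitochondrial feature annotation from BED6 or GFF3.

    Returns a frame with 1-based inclusive ``start``/``end`` plus ``name``,
    ``type`` and ``strand`` columns.  BED names are expected as "type:name" or
    plain names (type defaults to the name).  Malformed intervals (end < start)
    raise at load time.
    """
    path = str(path)
    rows = []
    if path.endswith(".bed"):
        for line in open(path):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            c = line.rstrip("\n").split("\t")
            name = c[3]
            ftype, _, fname = name.partition(":")
            rows.append(
                {
                    "contig": c[0],
                    "name": fname or name,
                    "type": ftype if fname else name,
                    "start": int(c[1]) + 1,
                    "end": int(c[2]),
                    "strand": c[5] if len(c) > 5 else ".",
                }
            )
    else:  # GFF3
        for line in open(path):
            if not line.strip() or line.startswith("#"):
                continue
            c = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in c[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "contig": c[0],
                    "name": attrs.get("Name", attrs.get("ID", c[2])),
                    "type": c[2],
                    "start": int(c[3]),
                    "end": int(c[4]),
                    "strand": c[6],
                }
            )
    df = pd.DataFrame(rows, columns=["contig", "name", "type", "start", "end", "strand"])
    bad = df[df["end"] < df["start"]]
    if len(bad):
        raise ValueError(f"malformed feature interval(s): {bad['name'].tolist()}")
    return df


def _segments(start: int, length: int, circ_len: int) -> list[tuple[int, int]]:
    """1-based inclusive segment(s) covered by a window, split at the circular junction."""
    end = start + length - 1
    if end <= circ_len:
        return [(start, end)]
    return [(start, circ_len), (1, end - circ_len)]


def assign_features(
    hit: GenomeHit,
    read_len: int,
    features: pd.DataFrame,
    genome_length: int,
) -> list[FeatureOverlap]:
    """All annotated features overlapped by a mitochondrial hit, circular-aware.

    Uncovered positions become a single "intergenic" record, so overlap lengths
    sum to ``read_len`` whenever the annotation itself is non-overlapping.
    """
    segs = _segments(hit.start, read_len, genome_length)
    out: list[FeatureOverlap] = []
    covered = 0
    for row in features.itertuples():
        ov = sum(
            max(0, min(e, row.end) - max(s, row.start) + 1) for s, e in segs
        )
        if ov > 0:
            base = "+" if (row.type == "D-loop" or row.strand not in "+-") else row.strand
            orientation = "forward" if hit.strand == base else "reverse"
            out.append(FeatureOverlap(row.name, row.type, orientation, ov))
            covered += ov
    if covered < read_len:
        orientation = "forward" if hit.strand == "+" else "reverse"
        out.append(FeatureOverlap("intergenic", "intergenic", orientation, read_len - covered))
    return out


def overlaps_to_str(overlaps: list[FeatureOverlap]) -> str:
    return ";".join(
        f"{o.feature_name}|{o.feature_type}|{o.orientation}|{o.overlap_nt}" for o in overlaps
    )


def overlaps_from_str(s: str) -> list[FeatureOverlap]:
    if not s or s != s:
        return []
    out = []
    for part in str(s).split(";"):
        name, ftype, ori, ov = part.split("|")
        out.append(FeatureOverlap(name, ftype, ori, int(ov)))
    return out
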
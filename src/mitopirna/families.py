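"""5'-anchored piRNA families and mito-nuclear communication inference.

A piRNA family groups sequences that share an identical 5' end and differ only
by progressive 3' trimming — a putative precursor (pre-piRNA) and its processed
mature piRNAs.  Families are built as connected components of the exact
5'-prefix relation over sequences of at least ``anchor_min`` nt, optionally
requiring members to share a genomic 5'-anchor locus (same genome, contig,
strand and 5'-end coordinate among minimal-stratum hits).

Roles within a family:

* mature    — the member matches the piRNA reference set (it was seen bound to PIWI);
* precursor — the member is absent from the reference set, is longer than every
  mature member, and maps full-length to a genome;
* none      — anything else (kept, but outside the eligibility counts).

A family is *eligible* for communication inference when it has >= 3 members, at
least one precursor and one mature, and at least one member of class MT or NUMT.
The inferred direction reflects where the precursor could have been transcribed
and where the processed piRNA can act:

* retrograde  — precursors exclusively mitochondrial (MT) and some mature is a
  NUMT (the processed piRNA also matches nuclear DNA): mitochondria → nucleus;
* anterograde — precursors exclusively nuclear (NU) and some mature matches the
  mitochondrial genome (NUMT or MT): nucleus → mitochondria;
* self        — every precursor and mature class confined to a single genome;
* unresolved  — anything else, or an ineligible family.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genomemap import CLASS_MT, CLASS_NU, CLASS_NUMT, CLASS_UNMAPPED, MITO, GenomeHit

DIRECTIONS = ("retrograde", "anterograde", "self")


@dataclass
class FamilyMember:
    sequence: str
    genome_class: str
    role: str = "none"  # precursor | mature | none
    pirna_ids: list[str] = field(default_factory=list)
    hits: list[GenomeHit] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def pirna_multi(self) -> bool:
        return len(self.pirna_ids) > 1


@dataclass
class PiRNAFamily:
    family_id: str
    members: list[FamilyMember]
    eligible: bool = False
    direction: str = "unresolved"

    @property
    def representative(self) -> str:
        longest = max(m.length for m in self.members)
        return min(m.sequence for m in self.members if m.length == longest)

    @property
    def anchor_locus(self) -> GenomeHit | None:
        rep = self.representative
        for m in self.members:
            if m.sequence == rep:
                return m.hits[0] if m.hits else None
        return None


def _anchors(member: FamilyMember, mito_length: int | None) -> set[tuple]:
    acc = set()
    for h in member.hits:
        circ = mito_length if h.genome == MITO else None
        acc.add((h.genome, h.contig, h.strand, h.five_prime_position(member.length, circ)))
    return acc


def build_families(
    members: list[FamilyMember],
    *,
    anchor_min: int = 20,
    require_shared_locus: bool = True,
    mito_length: int | None = None,
) -> list[PiRNAFamily]:
    """Cluster sequences into 5'-anchored families.

    Two sequences join when the shorter equals a 5' prefix of the longer (both
    >= anchor_min nt) and, when ``require_shared_locus`` is set, they share a
    genomic 5'-anchor.  Connected components of this relation are the families;
    singletons are dropped from the family list (the sequences themselves stay
    in all other outputs).  ``mito_length`` enables circular wrapping of
    mitochondrial anchor coordinates.
    """
    pool = [m for m in members if m.length >= anchor_min]
    by_seq = {m.sequence: i for i, m in enumerate(pool)}
    anchors = [_anchors(m, mito_length) for m in pool]
    parent = list(range(len(pool)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    lengths = sorted({m.length for m in pool})
    for i, m in enumerate(pool):
        for L in lengths:
            if L >= m.length:
                break
            j = by_seq.get(m.sequence[:L])
            if j is None:
                continue
            if require_shared_locus and not (anchors[i] & anchors[j]):
                continue
            union(i, j)

    comps: dict[int, list[FamilyMember]] = {}
    for i, m in enumerate(pool):
        comps.setdefault(find(i), []).append(m)
    multi = sorted(
        (sorted(ms, key=lambda m: (-m.length, m.sequence)) for ms in comps.values() if len(ms) > 1),
        key=lambda ms: ms[0].sequence,
    )
    return [PiRNAFamily(f"FAM{i + 1:04d}", ms) for i, ms in enumerate(multi)]


def assign_roles(family: PiRNAFamily) -> PiRNAFamily:
    """Precursor/mature role assignment (in place) per the family rules."""
    matures = [m for m in family.members if m.pirna_ids]
    for m in matures:
        m.role = "mature"
    max_mature = max((m.length for m in matures), default=0)
    for m in family.members:
        if m.pirna_ids:
            continue
        full_length_hit = m.genome_class != CLASS_UNMAPPED
        m.role = "precursor" if (m.length > max_mature and full_length_hit) else "none"
    family.eligible = (
        len(family.members) >= 3
        and any(m.role == "precursor" for m in family.members)
        and any(m.role == "mature" for m in family.members)
        and any(m.genome_class in (CLASS_MT, CLASS_NUMT) for m in family.members)
    )
    return family


def infer_direction(family: PiRNAFamily) -> str:
    """Communication direction label; pure function of the role/class pairs."""
    if not family.eligible:
        family.direction = "unresolved"
        return family.direction
    P = {m.genome_class for m in family.members if m.role == "precursor"}
    M = {m.genome_class for m in family.members if m.role == "mature"}
    if P <= {CLASS_MT} and CLASS_NUMT in M:
        direction = "retrograde"
    elif P <= {CLASS_NU} and (M & {CLASS_NUMT, CLASS_MT}):
        direction = "anterograde"
    elif (P | M) <= {CLASS_MT} or (P | M) <= {CLASS_NU}:
        direction = "self"
    else:
        direction = "unresolved"
    family.direction = direction
    return direction


def direction_proportions(families: list[PiRNAFamily]) -> dict:
    """Counts and percentages of eligible, resolved families per direction.

    Families are counted once per cohort.  Percentages are over the resolved
    eligible families; unresolved eligible families are reported separately.
    """
    eligible = [f for f in families if f.eligible]
    resolved = [f for f in eligible if f.direction in DIRECTIONS]
    counts = {d: sum(1 for f in resolved if f.direction == d) for d in DIRECTIONS}
    n = len(resolved)
    return {
        "counts": counts,
        "percentages": {d: (100.0 * c / n if n else 0.0) for d, c in counts.items()},
        "n_eligible": len(eligible),
        "n_resolved": n,
        "n_unresolved": len(eligible) - n,
        "empty": n == 0,
    }


def length_by_class(
    members: list[FamilyMember], read_totals: dict[str, float]
) -> pd.DataFrame:
    """Read-weighted length histogram stratified by MT/NUMT class and role.

    ``read_totals`` maps sequence -> total reads across samples.  Rows are
    sequence lengths; columns are (class, role) read totals.
    """
    rows: dict[tuple[int, str, str], float] = {}
    for m in members:
        if m.genome_class not in (CLASS_MT, CLASS_NUMT):
            continue
        key = (m.length, m.genome_class, m.role)
        rows[key] = rows.get(key, 0.0) + float(read_totals.get(m.sequence, 0.0))
    df = pd.DataFrame(
        [
            {"length": L, "genome_class": c, "role": r, "reads": v}
            for (L, c, r), v in sorted(rows.items())
        ],
        columns=["length", "genome_class", "role", "reads"],
    )
    return df


def families_table(
    families: list[PiRNAFamily], counts: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Flat per-member family table (one row per member), mirroring the layout
    used to present a family: sequence, length, class, role, piRNA ids with a
    '*' flag when several reference piRNAs matched, per-sample read counts."""
    rows = []
    for fam in families:
        for m in fam.members:
            ann = ",".join(m.pirna_ids)
            if m.pirna_multi:
                ann = "*" + ann
            row = {
                "family_id": fam.family_id,
                "sequence": m.sequence,
                "length": m.length,
                "genome_class": m.genome_class,
                "role": m.role,
                "pirna_ids": ann,
                "eligible": fam.eligible,
                "direction": fam.direction,
            }
            if counts is not None and m.sequence in counts.index:
                row.update(counts.loc[m.sequence].to_dict())
            rows.append(row)
    return pd.DataFrame(rows)
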
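"""Synthetic small-RNA sequencing cohorts with machine-readable ground truth.

The generator emulates the study design this package analyzes: 12 single-end
small-RNA libraries (germ vs somatic cells, two sexes, three developmental
days) sequenced to <= 75 nt, over a circular mitochondrial genome with
annotated tRNA/rRNA/CDS/D-loop/origin features and a nuclear genome carrying
planted NUMT insertions (mitochondrial fragments copied into nuclear contigs,
optionally diverged).  It plants:

* piRNA *families* — a precursor sequence and its 5'-anchored 3'-trimmed ladder
  of mature piRNAs, placed so each family realizes a chosen mito-nuclear
  communication direction by construction: a retrograde family's precursor is
  mitochondria-only with the mature prefix also inside a NUMT; an anterograde
  family's precursor straddles a NUMT boundary in the nuclear genome (mature
  head inside the NUMT copy, tail in nuclear flank); a self family is confined
  to the mitochondrial genome;
* reference sets — the mature ladder members (never the precursor) populate the
  piRNA set; decoys, nuclear-only singletons and NUMT-class entries populate
  both sets; optionally one mature is duplicated into the miRNA set to create a
  dual miRNA/piRNA case;
* background genomic fragments with a configurable first-position adenine bias,
  D-loop reads emitted antisense to the reference with configurable
  probability, and unmappable noise.

Default mixture weights reproduce the cohort composition the generator is
meant to emulate: ~0.7% of reads mitochondria-associated, of which ~86% are
mature piRNAs and ~1% miRNAs.  Everything is deterministic given the seed:
identical configurations produce byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import BASES, revcomp, substreams

MITO_CONTIG = "chrM"

_TRNA_NAMES = [
    "tRNA-Phe", "tRNA-Val", "tRNA-LeuTAA", "tRNA-Ile", "tRNA-Met",
    "tRNA-AspGTC", "tRNA-SerGCT", "tRNA-SerTGA", "tRNA-ProTGG", "tRNA-Thr",
    "tRNA-Glu", "tRNA-Gln",
]
_CDS_NAMES = ["mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp6", "mt-Cytb", "mt-Nd3", "mt-Nd4"]


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    cell_type: str  # PGC | SC
    sex: str  # F | M
    dpc: str  # 11.5 | 12.5 | 13.5
    total_reads: int


def sample_grid(total_reads: int) -> list[SampleMeta]:
    """The 12-sample design: {PGC,SC} x {F,M} x {11.5,12.5,13.5} dpc."""
    out = []
    for ct in ("PGC", "SC"):
        for day in ("11.5", "12.5", "13.5"):
            for sex in ("F", "M"):
                sid = f"{ct}{day[:2]}{sex}"
                out.append(SampleMeta(sid, ct, sex, day, total_reads))
    return out


@dataclass
class SimConfig:
    """Full description of one synthetic cohort; see module docstring.

    ``mito_split`` divides the mitochondria-associated read mass into
    (mature piRNA, miRNA, precursor, background); ``nuclear_split`` divides the
    rest into (nuclear piRNA, nuclear miRNA, background, unmappable noise).
    """

    seed: int = 0
    # genomes
    mito_length: int = 16299
    nuclear_contigs: tuple = (("chr1", 30000), ("chr2", 30000))
    n_numts: int = 4
    numt_length_range: tuple = (300, 800)
    numt_divergence: float = 0.0
    # mito features
    n_trna: int = 10
    n_cds: int = 6
    rrna_lengths: tuple = (950, 1560)
    dloop_length: int = 1122
    # planted families and reference sets
    n_families: int = 10
    family_ladder: tuple = (60, 30, 28, 25)
    direction_mix: tuple = (0.7, 0.2, 0.1)  # retrograde, anterograde, self
    family_first_base: str | None = "A"
    decoy_db_entries: int = 50
    n_nu_pirnas: int = 40
    n_nu_mirnas: int = 15
    n_mito_mirnas: int = 2
    nu_first_base: str | None = "T"
    plant_dual: bool = True
    # reads
    samples: list[SampleMeta] | None = None
    reads_per_sample: int = 20000
    pos1_A_bias: float = 0.8
    dloop_reverse_fraction: float = 1.0
    frac_mito: float = 0.0071
    mito_split: tuple = (0.864, 0.009, 0.030, 0.097)
    nuclear_split: tuple = (0.620, 0.265, 0.110, 0.005)
    n_mito_bg_loci: int = 400
    n_nuclear_bg_loci: int = 800
    n_noise: int = 150
    pgc_family_fold: float = 1.0

    def __post_init__(self):
        if self.samples is None:
            self.samples = sample_grid(self.reads_per_sample)
        ladder = list(self.family_ladder)
        if ladder != sorted(ladder, reverse=True) or len(set(ladder)) != len(ladder):
            raise ValueError("family_ladder must be strictly decreasing")
        if ladder[0] > 75:
            raise ValueError("family_ladder lengths must be <= 75 nt")
        for name in ("numt_divergence", "pos1_A_bias", "dloop_reverse_fraction", "frac_mito"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("mito_length", "n_families", "reads_per_sample"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("mito_split", "nuclear_split", "direction_mix"):
            if abs(sum(getattr(self, name)) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        if any(s.total_reads <= 0 for s in self.samples):
            raise ValueError("sample total_reads must be positive")

    # -- config file round trip ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["samples"] = [dataclasses.asdict(s) for s in self.samples]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if d.get("samples"):
            d["samples"] = [SampleMeta(**s) for s in d["samples"]]
        for key in ("nuclear_contigs",):
            if key in d and d[key] is not None:
                d[key] = tuple(tuple(x) for x in d[key])
        for key in ("numt_length_range", "family_ladder", "direction_mix", "rrna_lengths",
                    "mito_split", "nuclear_split"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# genome generation

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, length)])


def gen_mito_genome(cfg: SimConfig, rng: np.random.Generator) -> tuple[str, pd.DataFrame]:
    """Random circular mitochondrial genome with non-overlapping features.

    The D-loop is pinned to the high-coordinate end of the genome; rRNA, tRNA,
    CDS and origin blocks are laid out in shuffled order with random gaps.
    Coordinates are 1-based inclusive.
    """
    L = cfg.mito_length
    seq = _random_seq(rng, L)
    feats: list[tuple[str, str, int, str]] = []  # name, type, length, strand
    for i, rl in enumerate(cfg.rrna_lengths):
        feats.append((f"mt-Rnr{i + 1}", "rRNA", int(rl), "+"))
    for i in range(cfg.n_trna):
        name = _TRNA_NAMES[i % len(_TRNA_NAMES)] + ("" if i < len(_TRNA_NAMES) else f"-{i}")
        feats.append((name, "tRNA", int(rng.integers(68, 73)), "+" if i % 2 == 0 else "-"))
    for i in range(cfg.n_cds):
        name = _CDS_NAMES[i % len(_CDS_NAMES)] + ("" if i < len(_CDS_NAMES) else f"-{i}")
        feats.append((name, "CDS", int(rng.integers(500, 1400)), "+" if rng.random() < 0.8 else "-"))
    feats.append(("OriL", "origin", 32, "+"))

    avail = L - cfg.dloop_length
    total = sum(f[2] for f in feats)
    if total >= avail:
        raise ValueError(
            f"cannot place features without overlap: {total} nt of features in "
            f"{avail} nt outside the D-loop (increase mito_length)"
        )
    order = [feats[i] for i in rng.permutation(len(feats))]
    gaps = rng.multinomial(avail - total, np.full(len(order) + 1, 1.0 / (len(order) + 1)))
    rows = []
    pos = 1
    for (name, ftype, flen, strand), gap in zip(order, gaps[:-1]):
        pos += int(gap)
        rows.append({"contig": MITO_CONTIG, "name": name, "type": ftype,
                     "start": pos, "end": pos + flen - 1, "strand": strand})
        pos += flen
    rows.append({"contig": MITO_CONTIG, "name": "D-loop", "type": "D-loop",
                 "start": L - cfg.dloop_length + 1, "end": L, "strand": "."})
    return seq, pd.DataFrame(rows)


def gen_nuclear_genome(
    cfg: SimConfig, mito: str, mito_features: pd.DataFrame, rng: np.random.Generator
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random nuclear contigs with planted NUMT insertions.

    Fragments of the mitochondrial sequence (lengths within
    ``numt_length_range``, random strand) are copied into the contigs with
    per-base substitution probability ``numt_divergence``, overwriting the
    random background so contig lengths stay as requested.  The first NUMT is
    sourced from a region overlapping the D-loop so D-loop families can be
    planted as NUMTs.  Returns the contigs and the insertion bookkeeping table.
    """
    L = len(mito)
    contigs = {name: _random_seq(rng, ln) for name, ln in cfg.nuclear_contigs}
    min_clen = min(len(s) for s in contigs.values())
    lo, hi = cfg.numt_length_range
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    dloop_start = int(mito_features.loc[mito_features["type"] == "D-loop", "start"].iloc[0])
    rows = []
    names = list(contigs)
    for i in range(cfg.n_numts):
        flen = int(rng.integers(lo, hi + 1))
        if flen >= min_clen:
            raise ValueError(f"NUMT of {flen} nt does not fit in the smallest contig ({min_clen} nt)")
        if i == 0:
            # sourced from inside the D-loop so antisense D-loop families are placeable
            ms = int(rng.integers(dloop_start, L - flen + 2))
        else:
            ms = int(rng.integers(1, L - flen + 2))
        frag = mito[ms - 1 : ms - 1 + flen]
        strand = "+" if (i == 0 or rng.random() < 0.5) else "-"
        if strand == "-":
            frag = revcomp(frag)
        subs = int(0)
        if cfg.numt_divergence > 0:
            chars = list(frag)
            for j in np.flatnonzero(rng.random(flen) < cfg.numt_divergence):
                chars[j] = BASES[(BASES.index(chars[j]) + int(rng.integers(1, 4))) % 4]
                subs += 1
            frag = "".join(chars)
        placed = False
        for _ in range(200):
            contig = names[int(rng.integers(0, len(names)))]
            clen = len(contigs[contig])
            margin = min(100, (clen - flen) // 4)
            off = int(rng.integers(margin, clen - flen - margin + 1))
            if all(off + flen <= s or off >= e for s, e in occupied[contig]):
                placed = True
                break
        if not placed:
            raise ValueError("cannot place NUMT without overlapping a previous insertion")
        occupied[contig].append((off, off + flen))
        contigs[contig] = contigs[contig][:off] + frag + contigs[contig][off + flen:]
        rows.append({"numt_id": f"NUMT{i + 1}", "contig": contig,
                     "contig_start": off + 1, "contig_end": off + flen,
                     "mito_start": ms, "mito_end": ms + flen - 1,
                     "strand": strand, "n_substitutions": subs})
    return contigs, pd.DataFrame(
        rows, columns=["numt_id", "contig", "contig_start", "contig_end",
                       "mito_start", "mito_end", "strand", "n_substitutions"]
    )


# ---------------------------------------------------------------------------
# family and reference-set planting

@dataclass
class PlannedFamily:
    family_id: str
    direction: str
    sense: str  # read strand relative to the forward reference at the locus
    genome: str  # mito | nuclear (genome of the precursor locus)
    contig: str
    start: int  # 1-based leftmost coordinate of the precursor window
    members: list[tuple[str, str]]  # (sequence, role)

    @property
    def precursor(self) -> str:
        return self.members[0][0]

    @property
    def matures(self) -> list[str]:
        return [s for s, r in self.members if r == "mature"]


@dataclass
class PlannedSingle:
    sequence: str
    kind: str  # nu_pirna | nu_mirna | mito_mirna


@dataclass
class FamilyPlan:
    families: list[PlannedFamily]
    singles: list[PlannedSingle]
    pirna_db: dict[str, str]
    mirna_db: dict[str, str]


class PlacementError(RuntimeError):
    """No genomic locus realizing the requested class pattern within budget."""


def _apportion(n: int, fracs: tuple) -> list[int]:
    raw = [f * n for f in fracs]
    base = [int(x) for x in raw]
    order = sorted(range(len(fracs)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[: n - sum(base)]:
        base[i] += 1
    return base


class _Scanner:
    """Both-strand substring membership for both genomes, exact or within a
    mismatch budget (naive all-offsets scans — oracle-grade, independent of
    the seeded mapper used by the analysis stages)."""

    def __init__(self, mito: str, contigs: dict[str, str]):
        self.mito_text = mito + mito[:74]
        self.nuc_texts = list(contigs.values())
        self._mito_arr = np.frombuffer(self.mito_text.encode(), dtype=np.uint8)
        self._nuc_arrs = [np.frombuffer(t.encode(), dtype=np.uint8) for t in self.nuc_texts]

    def in_mito(self, seq: str) -> bool:
        return self.mito_text.find(seq) != -1 or self.mito_text.find(revcomp(seq)) != -1

    def in_nuclear(self, seq: str) -> bool:
        rc = revcomp(seq)
        return any(t.find(seq) != -1 or t.find(rc) != -1 for t in self.nuc_texts)

    @staticmethod
    def _within(seq: str, arrays: list[np.ndarray], k: int) -> bool:
        from numpy.lib.stride_tricks import sliding_window_view

        L = len(seq)
        pats = [np.frombuffer(p.encode(), dtype=np.uint8) for p in (seq, revcomp(seq))]
        for arr in arrays:
            if L > len(arr):
                continue
            win = sliding_window_view(arr, L)
            for q in pats:
                if ((win != q).sum(axis=1) <= k).any():
                    return True
        return False

    def within_mito(self, seq: str, k: int) -> bool:
        return self._within(seq, [self._mito_arr], k)

    def within_nuclear(self, seq: str, k: int) -> bool:
        return self._within(seq, self._nuc_arrs, k)

    def genome_class(self, seq: str, k: int = 0) -> str:
        """Class label; with k > 0 membership allows up to k substitutions,
        mirroring the bounded-mismatch convention of the classifier."""
        if k == 0:
            m, n = self.in_mito(seq), self.in_nuclear(seq)
        else:
            m = self.in_mito(seq) or self.within_mito(seq, k)
            n = self.in_nuclear(seq) or self.within_nuclear(seq, k)
        if m and n:
            return "NUMT"
        if m:
            return "MT"
        if n:
            return "NU"
        return "UNMAPPED"


def plant_families(
    cfg: SimConfig,
    mito: str,
    mito_features: pd.DataFrame,
    contigs: dict[str, str],
    numt_df: pd.DataFrame,
    rng: np.random.Generator,
) -> FamilyPlan:
    """Plant piRNA families realizing the configured direction mix, and build
    the piRNA/miRNA reference sets.

    Each family is a precursor (longest ladder length) plus its 5' prefixes at
    the remaining ladder lengths.  Mature members enter the piRNA set; the
    precursor never does.  Placements are verified by exhaustive substring scan
    of both genomes and retried until the intended class pattern is realized
    (:class:`PlacementError` after budget exhaustion).
    """
    scan = _Scanner(mito, contigs)
    L = len(mito)
    ladder = list(cfg.family_ladder)
    Lp, Lm = ladder[0], ladder[1]
    dloop_start = int(mito_features.loc[mito_features["type"] == "D-loop", "start"].iloc[0])
    n_retro, n_antero, n_self = _apportion(cfg.n_families, cfg.direction_mix)
    directions = ["retrograde"] * n_retro + ["anterograde"] * n_antero + ["self"] * n_self

    numts = numt_df.to_dict("records")
    families: list[PlannedFamily] = []
    anchors: set[str] = set()

    def emit(window: str, sense: str) -> str:
        return revcomp(window) if sense == "-" else window

    def family_ok(prec: str, direction: str) -> bool:
        if cfg.family_first_base and prec[0] != cfg.family_first_base:
            return False
        if prec[: min(20, Lm)] in anchors:
            return False
        matures = [prec[:x] for x in ladder[1:]]
        # negative conditions hold up to one substitution so a 1-mismatch
        # classifier sees the same classes the construction intends (a window
        # straddling a NUMT boundary by one base is otherwise distance 1 from
        # the other genome)
        if direction == "retrograde":
            return (
                scan.in_mito(prec) and not scan.within_nuclear(prec, 1)
                and all(scan.in_mito(m) and scan.in_nuclear(m) for m in matures)
            )
        if direction == "anterograde":
            return (
                scan.in_nuclear(prec) and not scan.within_mito(prec, 1)
                and all(scan.in_mito(m) and scan.in_nuclear(m) for m in matures)
            )
        return (
            scan.in_mito(prec) and not scan.within_nuclear(prec, 1)
            and all(scan.in_mito(m) and not scan.within_nuclear(m, 1) for m in matures)
        )

    for idx, direction in enumerate(directions):
        placed = None
        for _attempt in range(500):
            if direction == "retrograde":
                numt = numts[int(rng.integers(0, len(numts)))] if idx else numts[0]
                ms, me = numt["mito_start"], numt["mito_end"]
                over_dloop = me >= dloop_start
                sense = "-" if (over_dloop and rng.random() < cfg.dloop_reverse_fraction) else "+"
                if sense == "+":
                    slo, shi = max(ms, me - Lp + 2), me - Lm + 1
                else:
                    slo, shi = max(1, ms - Lp + Lm), min(ms - 1, me - Lp + 1)
                if shi < slo or shi + Lp - 1 > L:
                    continue
                s = int(rng.integers(slo, shi + 1))
                if (s + Lp - 1 >= dloop_start) != over_dloop:
                    continue  # sense decision must reflect actual D-loop overlap
                window = mito[s - 1 : s - 1 + Lp]
                prec = emit(window, sense)
                if family_ok(prec, direction):
                    placed = PlannedFamily("", direction, sense, "mito", MITO_CONTIG, s,
                                           [(prec, "precursor")] + [(prec[:x], "mature") for x in ladder[1:]])
                    break
            elif direction == "anterograde":
                numt = numts[int(rng.integers(0, len(numts)))]
                cs, ce = numt["contig_start"], numt["contig_end"]
                contig = numt["contig"]
                slo, shi = max(cs, ce - Lp + 2), ce - Lm + 1
                if shi < slo or shi + Lp - 1 > len(contigs[contig]):
                    continue
                t = int(rng.integers(slo, shi + 1))
                if numt["strand"] == "+":
                    # mito image of the mature head; a plus-strand image inside
                    # the D-loop would be a forward D-loop match, which the
                    # all-antisense D-loop regime forbids
                    img_end = numt["mito_start"] + (t - cs) + Lm - 1
                    if img_end >= dloop_start:
                        continue
                prec = contigs[contig][t - 1 : t - 1 + Lp]
                if family_ok(prec, direction):
                    placed = PlannedFamily("", direction, "+", "nuclear", contig, t,
                                           [(prec, "precursor")] + [(prec[:x], "mature") for x in ladder[1:]])
                    break
            else:  # self, confined to the mitochondrial genome
                s = int(rng.integers(1, L - Lp + 2))
                if any(s <= n["mito_end"] and s + Lp - 1 >= n["mito_start"] for n in numts):
                    continue
                over_dloop = s + Lp - 1 >= dloop_start
                sense = "-" if (over_dloop and rng.random() < cfg.dloop_reverse_fraction) else "+"
                prec = emit(mito[s - 1 : s - 1 + Lp], sense)
                if family_ok(prec, direction):
                    placed = PlannedFamily("", direction, sense, "mito", MITO_CONTIG, s,
                                           [(prec, "precursor")] + [(prec[:x], "mature") for x in ladder[1:]])
                    break
        if placed is None:
            raise PlacementError(
                f"no locus realizing a {direction} family after 500 attempts "
                f"(n_numts={cfg.n_numts}, divergence={cfg.numt_divergence})"
            )
        placed.family_id = f"PF{idx + 1:03d}"
        anchors.add(placed.precursor[: min(20, Lm)])
        families.append(placed)

    # ---- reference sets ----------------------------------------------------
    pirna_db: dict[str, str] = {}
    mirna_db: dict[str, str] = {}
    used = {s for f in families for s, _ in f.members}
    k = 0
    for fam in families:
        for m in fam.matures:
            k += 1
            pirna_db[f"piR-sim-{k:06d}"] = m

    def random_absent(length: int) -> str:
        for _ in range(1000):
            s = _random_seq(rng, length)
            if s not in used and not scan.in_mito(s) and not scan.in_nuclear(s):
                used.add(s)
                return s
        raise PlacementError("could not draw a decoy absent from both genomes")

    for i in range(cfg.decoy_db_entries):
        pirna_db[f"piR-decoy-{i + 1:05d}"] = random_absent(int(rng.integers(26, 32)))
    for i in range(cfg.decoy_db_entries):
        mirna_db[f"mir-decoy-{i + 1:05d}"] = random_absent(int(rng.integers(20, 24)))

    singles: list[PlannedSingle] = []
    names = list(contigs)

    def prefix_clash(s: str) -> bool:
        return any(o.startswith(s) or s.startswith(o) for o in used)

    def nuclear_window(length: int, first: str | None) -> str | None:
        for _ in range(500):
            contig = names[int(rng.integers(0, len(names)))]
            off = int(rng.integers(0, len(contigs[contig]) - length + 1))
            w = contigs[contig][off : off + length]
            if first and w[0] != first:
                continue
            if prefix_clash(w) or scan.within_mito(w, 1):
                continue
            used.add(w)
            return w
        return None

    for i in range(cfg.n_nu_pirnas):
        w = nuclear_window(int(rng.integers(24, 33)), cfg.nu_first_base)
        if w is None:
            raise PlacementError("could not place a nuclear-only piRNA entry")
        pirna_db[f"piR-nu-{i + 1:05d}"] = w
        singles.append(PlannedSingle(w, "nu_pirna"))
    for i in range(cfg.n_nu_mirnas):
        w = nuclear_window(int(rng.integers(21, 24)), None)
        if w is None:
            raise PlacementError("could not place a nuclear-only miRNA entry")
        mirna_db[f"mmu-mir-nu-{i + 1:04d}"] = w
        singles.append(PlannedSingle(w, "nu_mirna"))
    for i in range(cfg.n_mito_mirnas):
        w = None
        for _ in range(500):
            numt = numts[int(rng.integers(0, len(numts)))]
            ms, me = numt["mito_start"], numt["mito_end"]
            length = int(rng.integers(21, 24))
            if me - ms + 1 <= length:
                continue
            s = int(rng.integers(ms, me - length + 2))
            if s + length - 1 >= dloop_start:
                continue  # keep planted sense-forward entries out of the D-loop
            cand = mito[s - 1 : s - 1 + length]
            if prefix_clash(cand) or not scan.in_nuclear(cand):
                continue
            w = cand
            used.add(w)
            break
        if w is None:
            raise PlacementError("could not place a NUMT-class miRNA entry")
        mirna_db[f"mmu-mir-numt-{i + 1:04d}"] = w
        singles.append(PlannedSingle(w, "mito_mirna"))
    if cfg.plant_dual and families:
        retro = next((f for f in families if f.direction == "retrograde"), families[0])
        mirna_db["mmu-mir-dual-0001"] = retro.matures[0]

    return FamilyPlan(families, singles, pirna_db, mirna_db)


# ---------------------------------------------------------------------------
# read simulation

def _overlaps_dloop(start: int, length: int, dloop_start: int, L: int) -> bool:
    end = start + length - 1
    if end <= L:
        return end >= dloop_start
    return True  # wraps through the junction, hence through the D-loop end


def build_read_pool(
    cfg: SimConfig,
    mito: str,
    mito_features: pd.DataFrame,
    contigs: dict[str, str],
    plan: FamilyPlan,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Emission pool: one row per emittable unique sequence with its relative
    intensity, mixture subgroup and truth bookkeeping."""
    scan = _Scanner(mito, contigs)
    L = len(mito)
    dloop_start = int(mito_features.loc[mito_features["type"] == "D-loop", "start"].iloc[0])
    rows: list[dict] = []
    seen: set[str] = set()

    def add(seq, group, subgroup, family_id="", role="noise", direction="none", sense="+"):
        if seq in seen:
            return False
        if not family_id:
            # non-family pool sequences must not form accidental 5'-prefix pairs
            # with anything already in the pool, so planted family membership
            # stays the unique ground truth for the clustering stage
            for other in seen:
                if other.startswith(seq) or seq.startswith(other):
                    return False
        seen.add(seq)
        rows.append({
            "sequence": seq, "group": group, "subgroup": subgroup,
            "family_id": family_id, "role": role, "direction": direction,
            "sense": sense, "intensity": float(rng.lognormal(0.0, 0.6)),
        })
        return True

    for fam in plan.families:
        for seq, role in fam.members:
            add(seq, "mature" if role == "mature" else "precursor",
                "mature" if role == "mature" else "precursor",
                family_id=fam.family_id, role=role, direction=fam.direction, sense=fam.sense)
    kind_group = {"nu_pirna": "nu_pirna", "nu_mirna": "nu_mirna", "mito_mirna": "mito_mirna"}
    for single in plan.singles:
        add(single.sequence, kind_group[single.kind], kind_group[single.kind])

    def fill_background(n: int, group: str, draw):
        """Draw loci until the A-start and non-A-start subpools are both served
        (mass splits by cfg.pos1_A_bias; an all-A or no-A bias leaves the other
        subpool empty with zero mass)."""
        n_a = round(n * cfg.pos1_A_bias)
        n_x = n - n_a
        got_a = got_x = 0
        for _ in range(50 * n + 100):
            if got_a >= n_a and got_x >= n_x:
                break
            seq, sense = draw()
            if seq is None or seq in seen:
                continue
            if seq[0] == "A" and got_a < n_a:
                got_a += int(add(seq, group, group + "_A", sense=sense))
            elif seq[0] != "A" and got_x < n_x:
                got_x += int(add(seq, group, group + "_x", sense=sense))

    def draw_mito():
        length = int(rng.integers(20, 34))
        s = int(rng.integers(1, L + 1))
        window = scan.mito_text[s - 1 : s - 1 + length]
        sense = "+"
        if _overlaps_dloop(s, length, dloop_start, L) and rng.random() < cfg.dloop_reverse_fraction:
            sense = "-"
        return (revcomp(window) if sense == "-" else window), sense

    names = list(contigs)

    def draw_nuclear():
        # windows matching the mitochondrial genome (NUMT copies) are rejected:
        # NUMT-derived expression is budgeted under the mitochondrial mass
        length = int(rng.integers(20, 34))
        contig = names[int(rng.integers(0, len(names)))]
        off = int(rng.integers(0, len(contigs[contig]) - length + 1))
        window = contigs[contig][off : off + length]
        if scan.within_mito(window, 1):
            return None, "+"
        sense = "+" if rng.random() < 0.5 else "-"
        return (revcomp(window) if sense == "-" else window), sense

    fill_background(cfg.n_mito_bg_loci, "mito_bg", draw_mito)
    fill_background(cfg.n_nuclear_bg_loci, "nuclear_bg", draw_nuclear)

    for _ in range(cfg.n_noise):
        for _try in range(100):
            s = _random_seq(rng, int(rng.integers(20, 31)))
            if (not scan.within_mito(s, 1) and not scan.within_nuclear(s, 1)
                    and add(s, "noise", "noise")):
                break

    pool = pd.DataFrame(rows)
    # subgroup masses -> per-sequence emission probability
    m, nm = cfg.frac_mito, 1.0 - cfg.frac_mito
    mat, mir, pre, mbg = cfg.mito_split
    npi, nmi, nbg, noi = cfg.nuclear_split
    b = cfg.pos1_A_bias
    masses = {
        "mature": m * mat, "mito_mirna": m * mir, "precursor": m * pre,
        "mito_bg_A": m * mbg * b, "mito_bg_x": m * mbg * (1 - b),
        "nu_pirna": nm * npi, "nu_mirna": nm * nmi,
        "nuclear_bg_A": nm * nbg * b, "nuclear_bg_x": nm * nbg * (1 - b),
        "noise": nm * noi,
    }
    prob = np.zeros(len(pool))
    for sub, mass in masses.items():
        sel = (pool["subgroup"] == sub).to_numpy()
        tot = pool.loc[sel, "intensity"].sum()
        if sel.any() and tot > 0:
            prob[sel] = mass * pool.loc[sel, "intensity"].to_numpy() / tot
    pool["prob"] = prob / prob.sum()
    return pool


def sample_counts(cfg: SimConfig, pool: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Per-sample multinomial counts over the pool; exactly ``total_reads``
    reads per sample.  ``pgc_family_fold`` != 1 plants a germ-cell-specific
    expression effect on the planted families (the default 1.0 reproduces the
    no-group-difference condition)."""
    base = pool["prob"].to_numpy().copy()
    fam_mask = (pool["family_id"] != "").to_numpy()
    counts = {}
    for s in cfg.samples:
        p = base.copy()
        if cfg.pgc_family_fold != 1.0 and s.cell_type == "PGC":
            p[fam_mask] *= cfg.pgc_family_fold
        p = p / p.sum()
        counts[s.sample_id] = rng.multinomial(s.total_reads, p)
    df = pd.DataFrame(counts, index=pool["sequence"])
    return df


def truth_table(
    cfg: SimConfig,
    pool: pd.DataFrame,
    counts: pd.DataFrame,
    mito: str,
    mito_features: pd.DataFrame,
    contigs: dict[str, str],
) -> pd.DataFrame:
    """Ground truth for every emitted collapsed sequence.

    Genome classes are recomputed by exhaustive all-offsets scans of both
    genomes at the 1-mismatch allowance (not taken from placement intent), so
    the table doubles as an independent oracle for the classifier at zero NUMT
    divergence.
    """
    scan = _Scanner(mito, contigs)
    L = len(mito)
    feat_rows = list(mito_features.itertuples())
    emitted = counts.sum(axis=1) > 0
    rows = []
    for rec, emit in zip(pool.itertuples(), emitted.to_numpy()):
        if not emit:
            continue
        seq = rec.sequence
        cls = scan.genome_class(seq, k=1)
        feats = ""
        if cls in ("MT", "NUMT") and scan.in_mito(seq):
            probe = seq if scan.mito_text.find(seq) != -1 else revcomp(seq)
            pos0 = scan.mito_text.find(probe)
            positions = {(pos0 + i) % L + 1 for i in range(len(seq))}
            feats = ";".join(
                sorted({f.name for f in feat_rows if positions & set(range(f.start, f.end + 1))})
            ) or "intergenic"
        rows.append({
            "sequence": seq, "true_class": cls, "true_features": feats,
            "family_id": rec.family_id, "role": rec.role,
            "direction": rec.direction, "sense": rec.sense, "group": rec.group,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers and the one-call entry point

def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_features_gff3(features: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, r in enumerate(features.itertuples(), 1):
            fh.write(
                f"{r.contig}\tmitopirna_sim\t{r.type}\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t"
                f"ID=feat{i};Name={r.name}\n"
            )


def write_features_bed(features: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in features.itertuples():
            fh.write(f"{r.contig}\t{r.start - 1}\t{r.end}\t{r.type}:{r.name}\t0\t{r.strand}\n")


def write_fastq(sample_id: str, pool: pd.DataFrame, counts: pd.Series, path: str | Path) -> None:
    lines: list[str] = []
    n = 0
    for seq, c in zip(pool["sequence"], counts.to_numpy()):
        qual = "I" * len(seq)
        for _ in range(int(c)):
            n += 1
            lines.append(f"@{sample_id}.{n}\n{seq}\n+\n{qual}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


@dataclass
class SimResult:
    cfg: SimConfig
    outdir: Path
    mito: str
    mito_features: pd.DataFrame
    contigs: dict[str, str]
    numt_table: pd.DataFrame
    plan: FamilyPlan
    pool: pd.DataFrame
    counts: pd.DataFrame
    truth: pd.DataFrame
    fastq_paths: dict[str, Path] = field(default_factory=dict)


def simulate(cfg: SimConfig, outdir: str | Path) -> SimResult:
    """Generate a full synthetic cohort under ``outdir``.

    Writes genomes (FASTA), the mitochondrial feature annotation (GFF3 + BED6),
    both reference sets (FASTA), per-sample FASTQ files, the per-sample
    metadata, the truth table and the resolved configuration.  Deterministic:
    the seed drives named substreams, one per stage.
    """
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    rngs = substreams(cfg.seed, ["mito", "nuclear", "families", "pool", "reads"])

    mito, features = gen_mito_genome(cfg, rngs["mito"])
    contigs, numt_df = gen_nuclear_genome(cfg, mito, features, rngs["nuclear"])
    plan = plant_families(cfg, mito, features, contigs, numt_df, rngs["families"])
    pool = build_read_pool(cfg, mito, features, contigs, plan, rngs["pool"])
    counts = sample_counts(cfg, pool, rngs["reads"])
    truth = truth_table(cfg, pool, counts, mito, features, contigs)

    write_fasta({MITO_CONTIG: mito}, outdir / "mito.fasta")
    write_fasta(contigs, outdir / "nuclear.fasta")
    write_features_gff3(features, outdir / "mito_features.gff3")
    write_features_bed(features, outdir / "mito_features.bed")
    write_fasta(plan.pirna_db, outdir / "pirna_db.fasta")
    write_fasta(plan.mirna_db, outdir / "mirna_db.fasta")
    numt_df.to_csv(outdir / "numts.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    pd.DataFrame([dataclasses.asdict(s) for s in cfg.samples]).to_csv(
        outdir / "samples.tsv", sep="\t", index=False
    )
    cfg.to_yaml(outdir / "config.yaml")
    fastq_paths = {}
    for s in cfg.samples:
        p = outdir / "reads" / f"{s.sample_id}.fastq"
        write_fastq(s.sample_id, pool, counts[s.sample_id], p)
        fastq_paths[s.sample_id] = p
    return SimResult(cfg, outdir, mito, features, contigs, numt_df, plan, pool, counts, truth, fastq_paths)
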
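"""Independent brute-force oracles used to check the mapper.

The naive scan compares the query against every offset of every contig on both
strands via numpy sliding windows — no seeding, no shortcuts — and then applies
the same minimal-distance-stratum rule the mapper promises.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from mitopirna._util import revcomp


def naive_hits(
    query: str,
    contigs: dict[str, str],
    *,
    circular: bool = False,
    k: int = 1,
    genome_name: str = "nuclear",
) -> list[tuple]:
    """All-offsets Hamming scan; returns (genome, contig, strand, start, mm)
    tuples of the minimal-mismatch stratum, 1-based starts."""
    L = len(query)
    found = []
    for name, seq in contigs.items():
        if L > len(seq):
            continue
        text = seq + seq[: L - 1] if circular else seq
        arr = np.frombuffer(text.encode(), dtype=np.uint8)
        windows = sliding_window_view(arr, L)
        for strand, pattern in (("+", query), ("-", revcomp(query))):
            q = np.frombuffer(pattern.encode(), dtype=np.uint8)
            mm = (windows != q).sum(axis=1)
            for s0 in np.flatnonzero(mm <= k):
                if circular and s0 >= len(seq):
                    continue
                found.append((genome_name, name, strand, int(s0) + 1, int(mm[s0])))
    if not found:
        return []
    best = min(h[4] for h in found)
    return sorted(h for h in found if h[4] == best)


def query_battery(mito: str, contigs: dict[str, str], rng: np.random.Generator, n_random: int = 30):
    """A mixed bag of queries: exact windows of both genomes (both strands,
    assorted lengths), 1- and 2-substitution mutants, mitochondrial
    junction-spanners, and random sequences unlikely to map."""
    bases = np.array(list("ACGT"))
    queries: list[str] = []
    sources = [("mito", mito)] + [("nuc", s) for s in contigs.values()]
    for _src, seq in sources:
        for _ in range(n_random // 3):
            L = int(rng.integers(15, 61))
            s = int(rng.integers(0, len(seq) - L))
            w = seq[s : s + L]
            queries.append(w)
            queries.append(revcomp(w))
            mut = list(w)
            j = int(rng.integers(0, L))
            mut[j] = "ACGT"[("ACGT".index(mut[j]) + 1) % 4]
            queries.append("".join(mut))
            j2 = (j + L // 2) % L
            mut[j2] = "ACGT"[("ACGT".index(mut[j2]) + 2) % 4]
            queries.append("".join(mut))
    # junction spanners
    for tail in (5, 10, 24):
        queries.append(mito[-tail:] + mito[: 30 - tail])
    for _ in range(n_random // 3):
        queries.append("".join(bases[rng.integers(0, 4, int(rng.integers(18, 40)))]))
    return queries
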
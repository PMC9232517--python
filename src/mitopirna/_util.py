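"""Small shared helpers: alphabet handling, hashing, seeded substreams."""
from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(seq: str) -> str:
    """Uppercase a read and map RNA U to DNA T. Does not validate the alphabet."""
    return seq.upper().replace("U", "T")


def is_unambiguous(seq: str) -> bool:
    return all(c in "ACGT" for c in seq)


def hamming_le(a: str, b: str, k: int) -> int:
    """Hamming distance of equal-length strings if <= k, else -1 (early exit)."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > k:
                return -1
    return mm


def substreams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    """Named, independent RNG substreams derived from one seed.

    Streams are spawned in a fixed name order so adding a consumer at the end
    never shifts the draws of existing consumers.
    """
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
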
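"""Small DNA string utilities shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

_BASE_TO_INT = {b: i for i, b in enumerate(BASES)}


def complement(seq: str) -> str:
    return seq.translate(_COMP)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def gc_content(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence has no GC content")
    return (seq.count("G") + seq.count("C")) / len(seq)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array (A=0, C=1, G=2, T=3)."""
    try:
        return np.array([_BASE_TO_INT[b] for b in seq.upper()], dtype=np.uint8)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"non-ACGT base in sequence: {exc}") from None


def decode(arr: np.ndarray) -> str:
    return "".join(BASES[i] for i in arr)


def count_overlapping(seq: str, sub: str) -> int:
    """Occurrences of ``sub`` in ``seq``, counting overlaps."""
    n, start = 0, 0
    while True:
        i = seq.find(sub, start)
        if i < 0:
            return n
        n += 1
        start = i + 1
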
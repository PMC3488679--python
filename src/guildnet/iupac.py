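"""IUPAC nucleotide code utilities shared across modules."""

from __future__ import annotations

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def matches(base: str, code: str) -> bool:
    """True if concrete ``base`` is among the bases denoted by IUPAC ``code``."""
    return base in IUPAC_SETS[code]


def motif_score(window: str, pattern: str) -> int:
    """Number of positions of ``window`` matching the IUPAC ``pattern``."""
    return sum(1 for b, p in zip(window, pattern) if b in IUPAC_SETS[p])


def motif_matches(window: str, pattern: str) -> bool:
    return len(window) == len(pattern) and motif_score(window, pattern) == len(pattern)


def find_motif(seq: str, pattern: str, start: int = 0) -> int:
    """Index of the first IUPAC-aware occurrence of ``pattern`` at/after
    ``start``, or -1."""
    m = len(pattern)
    for i in range(start, len(seq) - m + 1):
        if motif_score(seq[i : i + m], pattern) == m:
            return i
    return -1


def rfind_motif(seq: str, pattern: str) -> int:
    """Index of the last IUPAC-aware occurrence of ``pattern``, or -1."""
    m = len(pattern)
    for i in range(len(seq) - m, -1, -1):
        if motif_score(seq[i : i + m], pattern) == m:
            return i
    return -1


def count_motif(seq: str, pattern: str) -> int:
    n, i = 0, 0
    while True:
        i = find_motif(seq, pattern, i)
        if i < 0:
            return n
        n += 1
        i += 1


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))
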
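"""Combinatorial hairpin folding by base-pair maximisation.

Nussinov-style dynamic programming over nested structures with Watson-Crick
and G.T wobble pairs and a minimum hairpin-loop length of 3.  This replaces
thermodynamic folding: the fold is used only to delineate the central loop of
the P6b stem and to sanity-check that the repeats base-pair into a hairpin,
not to estimate free energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MIN_LOOP = 3

# encode A,C,G,T -> 0..3; anything else (ambiguity codes) -> 4, never pairs
_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}
_PAIRABLE = np.zeros((5, 5), dtype=np.uint8)
for _a, _b in [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")]:
    _PAIRABLE[_ENC[_a], _ENC[_b]] = 1


def can_pair(a: str, b: str) -> bool:
    return bool(_PAIRABLE[_ENC.get(a, 4), _ENC.get(b, 4)])


def _fill_py(codes: np.ndarray, min_loop: int) -> np.ndarray:
    n = codes.shape[0]
    d = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = d[i + 1, j]
            if d[i, j - 1] > best:
                best = d[i, j - 1]
            if _PAIRABLE[codes[i], codes[j]]:
                v = d[i + 1, j - 1] + 1
                if v > best:
                    best = v
            for k in range(i + 1, j):
                v = d[i, k] + d[k + 1, j]
                if v > best:
                    best = v
            d[i, j] = best
    return d


try:  # numba gives ~100x on the O(n^3) fill; the pure-python fill is the fallback
    from numba import njit

    _fill_jit = njit(cache=True)(_fill_py)
except Exception:  # pragma: no cover - exercised only without numba
    _fill_jit = _fill_py


@dataclass
class HairpinFold:
    """A nested secondary structure of one stem-loop region."""

    pairing: list[tuple[int, int]]
    stem_length: int
    loop: tuple[int, int]  # 0-based half-open interval of the central loop
    unpaired_bulges: list[tuple[int, int]] = field(default_factory=list)
    n: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)

    def dot_bracket(self) -> str:
        s = ["."] * self.n
        for i, j in self.pairing:
            s[i], s[j] = "(", ")"
        return "".join(s)


def _traceback(d: np.ndarray, codes: np.ndarray, i: int, j: int, min_loop: int,
               pairs: list[tuple[int, int]]) -> None:
    # iterative stack; preference order pairs (i,j) first so the stem closes
    # from the outermost pair inward (longest contiguous stem on ties)
    stack = [(i, j)]
    while stack:
        i, j = stack.pop()
        while i < j:
            if j - i <= min_loop:
                break
            target = d[i, j]
            if target == 0:
                break
            if _PAIRABLE[codes[i], codes[j]] and d[i + 1, j - 1] + 1 == target:
                pairs.append((i, j))
                i, j = i + 1, j - 1
                continue
            if d[i + 1, j] == target:
                i += 1
                continue
            if d[i, j - 1] == target:
                j -= 1
                continue
            for k in range(i + 1, j):
                if d[i, k] + d[k + 1, j] == target:
                    stack.append((k + 1, j))
                    j = k
                    break
            else:  # pragma: no cover - DP guarantees a split exists
                break


def _helices(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Split a pair list into maximal stacked runs (helices)."""
    pairs = sorted(pairs)
    helices: list[list[tuple[int, int]]] = []
    for p in pairs:
        if helices and helices[-1][-1] == (p[0] - 1, p[1] + 1):
            helices[-1].append(p)
        else:
            helices.append([p])
    return helices


def _main_stem(pairs: list[tuple[int, int]], n: int,
               bulge_tol: int = 3) -> tuple[list[tuple[int, int]], tuple[int, int]]:
    """Chain helices from the outermost pair inward; return (stem pairs, loop).

    The chain extends onto the next nested helix only when the gap on each
    side is <= ``bulge_tol`` and the helix has >= 2 stacked pairs: isolated
    lone pairs inside the terminal interior (which base-pair maximisation
    happily closes across a short loop) do not redefine the central loop.
    """
    if not pairs:
        return [], (0, n)
    helices = _helices(pairs)
    # outermost helix: the one whose outer pair has the smallest i
    current = min(helices, key=lambda h: h[0][0])
    stem = list(current)
    while True:
        ci, cj = current[-1]  # innermost pair of current helix
        nxt = None
        for h in helices:
            hi, hj = h[0]
            if hi > ci and hj < cj and len(h) >= 2:
                if (hi - ci - 1) <= bulge_tol and (cj - hj - 1) <= bulge_tol:
                    if nxt is None or hi < nxt[0][0]:
                        nxt = h
        if nxt is None:
            break
        current = nxt
        stem.extend(nxt)
    ci, cj = stem[-1][0] + 1, stem[-1][1]
    return stem, (ci, cj)


def fold_hairpin(region_seq: str, min_loop: int = MIN_LOOP,
                 bulge_tol: int = 3) -> HairpinFold:
    """Maximum-base-pair nested fold of a stem-loop region.

    Watson-Crick and G.T wobble pairs; hairpin loops of >= ``min_loop``
    unpaired bases; ties broken toward the longest contiguous stem from the
    outermost pair inward.  Raises ``ValueError`` for regions shorter than 10.
    """
    n = len(region_seq)
    if n < 10:
        raise ValueError(f"region too short to fold ({n} < 10 nt)")
    codes = np.array([_ENC.get(b, 4) for b in region_seq], dtype=np.int64)
    d = _fill_jit(codes, min_loop)
    pairs: list[tuple[int, int]] = []
    _traceback(d, codes, 0, n - 1, min_loop, pairs)
    pairs.sort()
    assert len(pairs) == int(d[0, n - 1])
    stem, loop = _main_stem(pairs, n, bulge_tol)
    paired_pos = {p for ij in pairs for p in ij}
    bulges: list[tuple[int, int]] = []
    start = None
    for i in range(n):
        inside_loop = loop[0] <= i < loop[1]
        if i not in paired_pos and not inside_loop:
            if start is None:
                start = i
        else:
            if start is not None:
                bulges.append((start, i))
                start = None
    if start is not None:
        bulges.append((start, n))
    return HairpinFold(pairing=pairs, stem_length=len(stem), loop=loop,
                       unpaired_bulges=bulges, n=n)
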
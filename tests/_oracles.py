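"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: exhaustive
enumeration for folding and repeat tiling, Dreyfus-Wagner exact Steiner trees
for the median-joining network, and naive per-site loops for distances.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

from guildnet._fold import can_pair


def exhaustive_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum base pairs over all nested structures, by direct recursion."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        b = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if can_pair(seq[i], seq[k]):
                b = max(b, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return b

    return best(0, len(seq) - 1)


def brute_hamming(a: str, b: str, w=None) -> float:
    total = 0.0
    for k, (x, y) in enumerate(zip(a, b)):
        if x != y:
            total += 1.0 if w is None else w[k]
    return total


def brute_mst_weight(dist: np.ndarray) -> float:
    """MST weight by exhaustive Kruskal with an independent union-find."""
    n = dist.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = sorted(
        (dist[i, j], i, j) for i in range(n) for j in range(i + 1, n)
    )
    total, used = 0.0, 0
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            total += w
            used += 1
            if used == n - 1:
                break
    return total


def steiner_oracle(haps: list[str]) -> float:
    """Exact minimum Steiner-tree cost in Hamming space, with Steiner points
    restricted to the observed-state candidate lattice (Dreyfus-Wagner)."""
    n_sites = len(haps[0])
    site_states = [sorted({h[k] for h in haps}) for k in range(n_sites)]
    seg = [k for k in range(n_sites) if len(site_states[k]) > 1]
    lattice = ["".join(c) for c in itertools.product(*[site_states[k] for k in seg])]
    proj = {h: "".join(h[k] for k in seg) for h in haps}
    idx = {v: i for i, v in enumerate(lattice)}
    V = len(lattice)
    enc = np.frombuffer("".join(lattice).encode(), dtype=np.uint8).reshape(V, -1) \
        if seg else np.zeros((V, 0), dtype=np.uint8)
    D = np.zeros((V, V))
    for i in range(V):
        D[i] = (enc[i][None, :] != enc).sum(axis=1)
    terms = [idx[proj[h]] for h in haps]
    t0, rest = terms[0], terms[1:]
    if not rest:
        return 0.0
    f: dict[frozenset, np.ndarray] = {}
    for x in rest:
        f[frozenset([x])] = D[x].copy()
    for size in range(2, len(rest) + 1):
        for S in itertools.combinations(rest, size):
            Sf = frozenset(S)
            items = sorted(Sf)
            first, others = items[0], items[1:]
            merge = np.full(V, np.inf)
            for r in range(len(others) + 1):
                for sub in itertools.combinations(others, r):
                    S1 = frozenset((first,) + sub)
                    S2 = Sf - S1
                    if not S2:
                        continue
                    merge = np.minimum(merge, f[S1] + f[S2])
            # metric closure: one min-plus relaxation suffices (triangle inequality)
            f[Sf] = np.minimum(merge, (merge[:, None] + D).min(axis=0))
    return float(f[frozenset(rest)][t0])


def random_steiner_instance(seed: int) -> list[str]:
    """Small random haplotype instance (<= 6 haplotypes, <= 20 sites) with a
    bounded candidate lattice so the exact oracle stays tractable."""
    rng = np.random.default_rng(seed)
    while True:
        n_hap = int(rng.integers(3, 7))
        n_sites = int(rng.integers(8, 21))
        base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n_sites)])
        haps = {base}
        for _ in range(n_hap - 1):
            h = base
            for _ in range(int(rng.integers(1, 3))):
                i = int(rng.integers(n_sites))
                h = h[:i] + "ACGT".replace(h[i], "")[rng.integers(3)] + h[i + 1 :]
            haps.add(h)
        out = sorted(haps)
        if len(out) < 3:
            continue
        lattice = 1
        for k in range(n_sites):
            lattice *= len({h[k] for h in out})
        if lattice <= 1500:
            return out


def exhaustive_tiling_max_repeats(seq: str, scorer, threshold: int) -> int:
    """Maximum number of repeat units in any left-to-right segmentation of
    ``seq`` into 7-mer units (scoring >= threshold) and single skipped bases."""

    @lru_cache(maxsize=None)
    def best(i: int) -> int:
        if len(seq) - i < 7:
            return 0
        b = best(i + 1)  # skip one base into an indel
        if scorer(seq[i : i + 7]) >= threshold:
            b = max(b, 1 + best(i + 7))
        return b

    return best(0)
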
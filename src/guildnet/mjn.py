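"""Median-joining haplotype networks.

Implements the median-joining construction of Bandelt, Forster & Roehl over
aligned haplotypes: a minimum-spanning network (union of all minimum spanning
trees, relaxed by an integer ``epsilon``) is iteratively enriched with
quasi-median vectors (site-wise majority consensus of triplets) whenever they
reduce the Steiner connection cost, and vectors that end up off every minimal
path are deleted.  Gaps are treated as a fifth character state.

The per-site quasi-median of three states is the majority state; a site where
all three states differ contributes each of its observed states as an
alternative (never a fourth, unobserved state).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

ALPHABET = "ACGT-"

#: all-distinct sites per triplet beyond which quasi-median expansion is
#: skipped (3^d candidate vectors)
MAX_BRANCHING_SITES = 4

#: candidate-pool size cap for the depth-2 insertion lookahead
MAX_PAIR_LOOKAHEAD = 400


class MjnError(ValueError):
    pass


@dataclass
class AlignedHaplotypes:
    """Distinct equal-length rows over {A, C, G, T, -} with site weights."""

    codes: list[str]
    matrix: list[str]
    site_weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.codes) != len(self.matrix):
            raise MjnError("codes and matrix rows differ in number")
        lengths = {len(r) for r in self.matrix}
        if len(lengths) > 1:
            raise MjnError(f"alignment rows of unequal length: {sorted(lengths)}")
        if len(set(self.matrix)) != len(self.matrix):
            raise MjnError("duplicate haplotypes; collapse to genotypes first")
        n_sites = lengths.pop() if lengths else 0
        if self.site_weights is None:
            self.site_weights = np.ones(n_sites)
        else:
            self.site_weights = np.asarray(self.site_weights, dtype=float)
            if self.site_weights.shape != (n_sites,):
                raise MjnError("site_weights length does not match alignment")
            if np.any(self.site_weights <= 0):
                raise MjnError("site weights must be positive")

    @property
    def n_sites(self) -> int:
        return len(self.matrix[0]) if self.matrix else 0


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph
    epsilon: int
    observed: list[str] = field(default_factory=list)  # node names of inputs
    medians: list[str] = field(default_factory=list)

    @property
    def n_medians(self) -> int:
        return len(self.medians)

    def total_weight(self) -> float:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))


def _encode(rows: Sequence[str]) -> np.ndarray:
    return np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(
        len(rows), -1
    )


def _pairwise(enc_a: np.ndarray, enc_b: np.ndarray, w: np.ndarray) -> np.ndarray:
    out = np.empty((enc_a.shape[0], enc_b.shape[0]))
    for i in range(enc_a.shape[0]):  # row-chunked to bound memory
        out[i] = ((enc_a[i][None, :] != enc_b) * w).sum(axis=1)
    return out


def pairwise_distances(aln: AlignedHaplotypes) -> np.ndarray:
    """Symmetric weighted Hamming distance matrix; gap is a fifth state."""
    enc = _encode(aln.matrix)
    return _pairwise(enc, enc, aln.site_weights)


def _mst_weight(dist: np.ndarray) -> float:
    """Prim's algorithm on a dense matrix (fast for the small n used here)."""
    n = dist.shape[0]
    if n <= 1:
        return 0.0
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    best = dist[0].copy()
    best[0] = np.inf
    total = 0.0
    for _ in range(n - 1):
        j = int(np.argmin(np.where(in_tree, np.inf, best)))
        total += best[j]
        in_tree[j] = True
        best = np.minimum(best, dist[j])
        best[in_tree] = np.inf
    return total


def _mst_edges(dist: np.ndarray) -> list[tuple[int, int]]:
    n = dist.shape[0]
    if n <= 1:
        return []
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    best = dist[0].copy()
    parent = np.zeros(n, dtype=int)
    edges = []
    for _ in range(n - 1):
        j = int(np.argmin(np.where(in_tree, np.inf, best)))
        edges.append((int(parent[j]), j))
        in_tree[j] = True
        upd = dist[j] < best
        best[upd] = dist[j][upd]
        parent[upd] = j
    return edges


def _minimax(dist: np.ndarray) -> np.ndarray:
    """Minimax path weights (largest edge on the MST path) for all pairs."""
    n = dist.shape[0]
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for u, v in _mst_edges(dist):
        adj[u].append((v, dist[u, v]))
        adj[v].append((u, dist[u, v]))
    mm = np.zeros((n, n))
    for s in range(n):
        stack = [(s, 0.0)]
        seen = {s}
        while stack:
            u, cur = stack.pop()
            for v, w in adj[u]:
                if v not in seen:
                    seen.add(v)
                    mm[s, v] = max(cur, w)
                    stack.append((v, mm[s, v]))
    return mm


def minimum_spanning_network(dist: np.ndarray, epsilon: float = 0) -> set[tuple[int, int]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    An edge (u, v) belongs to the network iff d(u, v) <= minimax(u, v) +
    epsilon, where minimax is the largest edge weight on the MST path between
    u and v.  With epsilon = 0 this is exactly the union of all minimum
    spanning trees (every connection-critical edge).
    """
    n = dist.shape[0]
    if n < 2:
        return set()
    mm = _minimax(dist)
    tol = 1e-9
    return {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if dist[i, j] <= mm[i, j] + epsilon + tol
    }


def _quasi_medians(t1: str, t2: str, t3: str) -> list[str]:
    """Quasi-median vectors of a triplet: site-wise majority; sites where all
    three states differ branch over the three observed states."""
    fixed: list[str] = []
    branch_sites: list[tuple[int, tuple[str, str, str]]] = []
    for k, (a, b, c) in enumerate(zip(t1, t2, t3)):
        if a == b or a == c:
            fixed.append(a)
        elif b == c:
            fixed.append(b)
        else:
            fixed.append("?")
            branch_sites.append((k, (a, b, c)))
    if len(branch_sites) > MAX_BRANCHING_SITES:
        return []
    out = ["".join(fixed)]
    for k, states in branch_sites:
        out = [m[:k] + s + m[k + 1 :] for m in out for s in states]
    return out


def median_join(aln: AlignedHaplotypes, epsilon: int = 0) -> HaplotypeNetwork:
    """Build the median-joining network of a set of distinct haplotypes.

    Iterates: (1) generate quasi-median candidates from triplets of current
    vectors; (2) insert candidates while they reduce the Steiner connection
    cost (the MST weight over the vector set), most parsimonious first, with
    ties broken lexicographically and a depth-2 lookahead when no single
    candidate helps; (3) repeat until stable; (4) delete obsolete vectors;
    (5) return the epsilon-relaxed MSN over the final vectors.
    """
    if len(aln.matrix) < 2:
        raise MjnError("median joining needs at least 2 distinct haplotypes")
    w = aln.site_weights
    observed = list(aln.matrix)
    vectors = list(observed)
    tol = 1e-9

    while True:
        candidates: set[str] = set()
        svec = sorted(vectors)
        if len(svec) <= 12:
            triplets = combinations(svec, 3)
        else:
            # canonical median-joining candidate generation: triplets whose
            # members share minimum-spanning-network edges (two edges with a
            # common endpoint); keeps the candidate pool tractable
            enc0 = _encode(svec)
            d0 = _pairwise(enc0, enc0, w)
            msn = minimum_spanning_network(d0, epsilon)
            neigh: dict[int, set[int]] = {i: set() for i in range(len(svec))}
            for i, j in msn:
                neigh[i].add(j)
                neigh[j].add(i)
            triplets = (
                tuple(sorted((svec[u], svec[v], svec[x])))
                for u in range(len(svec))
                for v, x in combinations(sorted(neigh[u]), 2)
            )
        for a, b, c in triplets:
            candidates.update(_quasi_medians(a, b, c))
        candidates -= set(vectors)
        if not candidates:
            break
        pool = sorted(candidates)
        all_rows = vectors + pool
        enc = _encode(all_rows)
        dist = _pairwise(enc, enc, w)
        nv, np_ = len(vectors), len(pool)
        active = list(range(nv))
        added_any = False
        while True:
            cost = _mst_weight(dist[np.ix_(active, active)])
            best_c, best_idx = cost - tol, None
            for ci in range(np_):
                gi = nv + ci
                if gi in active:
                    continue
                c = _mst_weight(dist[np.ix_(active + [gi], active + [gi])])
                if c < best_c:
                    best_c, best_idx = c, gi
            if best_idx is not None:
                active.append(best_idx)
                added_any = True
                continue
            # depth-2 lookahead: some medians only pay off in pairs
            free = [nv + ci for ci in range(np_) if nv + ci not in active]
            if len(free) <= MAX_PAIR_LOOKAHEAD:
                best_pair = None
                for gi, gj in combinations(free, 2):
                    idx = active + [gi, gj]
                    c = _mst_weight(dist[np.ix_(idx, idx)])
                    if c < best_c:
                        best_c, best_pair = c, (gi, gj)
                if best_pair is not None:
                    active.extend(best_pair)
                    added_any = True
                    continue
            break
        vectors = [all_rows[i] for i in active]
        if not added_any:
            break

    # delete obsolete median vectors (no longer reduce the connection cost)
    while True:
        enc = _encode(vectors)
        dist = _pairwise(enc, enc, w)
        cost = _mst_weight(dist)
        removed = False
        for i, vec in enumerate(vectors):
            if vec in observed:
                continue
            idx = [k for k in range(len(vectors)) if k != i]
            if _mst_weight(dist[np.ix_(idx, idx)]) <= cost + tol:
                vectors.pop(i)
                removed = True
                break
        if not removed:
            break

    code_of = {row: aln.codes[i] for i, row in enumerate(observed)}
    medians = [v for v in vectors if v not in observed]
    for k, v in enumerate(sorted(medians), 1):
        code_of[v] = f"mv{k}"
    enc = _encode(vectors)
    dist = _pairwise(enc, enc, w)
    g = nx.Graph(epsilon=epsilon)
    for v in vectors:
        g.add_node(code_of[v], sequence=v, is_median=v not in observed)
    for i, j in minimum_spanning_network(dist, epsilon):
        g.add_edge(code_of[vectors[i]], code_of[vectors[j]], weight=float(dist[i, j]))
    return HaplotypeNetwork(
        graph=g,
        epsilon=epsilon,
        observed=[code_of[v] for v in observed],
        medians=sorted(code_of[v] for v in medians),
    )


def steiner_cost(net: HaplotypeNetwork, site_weights: Optional[np.ndarray] = None) -> float:
    """MST weight over all vectors (observed + medians) of a network."""
    rows = [d["sequence"] for _, d in net.graph.nodes(data=True)]
    w = site_weights if site_weights is not None else np.ones(len(rows[0]))
    enc = _encode(rows)
    return _mst_weight(_pairwise(enc, enc, w))


def align_genotypes(
    named_seqs: Sequence[tuple[str, str]],
    site_weights: Optional[np.ndarray] = None,
) -> AlignedHaplotypes:
    """Align genotype representatives with a progressive multiple aligner.

    Uses match +1 / mismatch -1 scoring with affine gaps (open 8, extend 2).
    Pre-aligned input (equal-length rows, possibly gapped) is passed through
    unchanged.
    """
    codes = [c for c, _ in named_seqs]
    seqs = [s for _, s in named_seqs]
    if len({len(s) for s in seqs}) == 1 and len(seqs) >= 1:
        return AlignedHaplotypes(codes=codes, matrix=list(seqs),
                                 site_weights=site_weights)
    import biotite.sequence as bseq
    import biotite.sequence.align as balign

    alph = bseq.NucleotideSequence.alphabet_unamb
    scores = np.where(np.eye(4, dtype=bool), 1, -1).astype(np.int32)
    matrix = balign.SubstitutionMatrix(alph, alph, scores)
    alignment = balign.align_multiple(
        [bseq.NucleotideSequence(s) for s in seqs], matrix, gap_penalty=(-8, -2)
    )[0]
    rows = alignment.get_gapped_sequences()
    return AlignedHaplotypes(codes=codes, matrix=rows, site_weights=site_weights)


def export_network(net: HaplotypeNetwork, path: str | Path, fmt: str = "graphml") -> None:
    """Write a network as GraphML or a plain TSV edge list."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net.graph, path)
    elif fmt == "edgelist":
        with open(path, "w") as fh:
            fh.write("u\tv\tweight\tu_is_median\tv_is_median\n")
            for u, v, d in sorted(net.graph.edges(data=True)):
                fh.write(
                    f"{u}\t{v}\t{d['weight']:g}"
                    f"\t{int(net.graph.nodes[u]['is_median'])}"
                    f"\t{int(net.graph.nodes[v]['is_median'])}\n"
                )
    else:
        raise MjnError(f"unknown export format {fmt!r}")


def read_network(path: str | Path, fmt: str = "graphml") -> HaplotypeNetwork:
    path = Path(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        g = nx.relabel_nodes(g, str)
        graph = nx.Graph(epsilon=int(g.graph.get("epsilon", 0)))
        for n, d in g.nodes(data=True):
            graph.add_node(n, sequence=d["sequence"], is_median=bool(d["is_median"]))
        for u, v, d in g.edges(data=True):
            graph.add_edge(u, v, weight=float(d["weight"]))
        observed = [n for n, d in graph.nodes(data=True) if not d["is_median"]]
        medians = sorted(n for n, d in graph.nodes(data=True) if d["is_median"])
        return HaplotypeNetwork(graph=graph, epsilon=graph.graph["epsilon"],
                                observed=observed, medians=medians)
    raise MjnError(f"unknown import format {fmt!r}")
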
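"""Collapse tRNA-Leu (UAA) intron sequences into *Nostoc* genotypes and
assign indel-defined subgroups.

A genotype is a set of sequence-identical introns (exact identity over the
full intron).  Genotypes sharing the same "major indel" structure of the P6b
region — identical indel-element content and a similar total repeat count —
form a subgroup: letters A, B, C, ... for the bipartite-host lineage (largest
subgroup = A), Y-prefixed labels for tripartite-lineage genotypes with Class 1
repeats and X-prefixed for Class 2, mirroring the A-G / Y0-Y4 / X1-X4 scheme
used for *Nephroma* photobionts.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .intron_annotator import (
    AMBIGUOUS,
    BIPARTITE_TYPE,
    CLASS1,
    CLASS2,
    TRIPARTITE_TYPE,
    IntronAnnotation,
)
from .seq_io import SequenceSet

#: genotypes whose total repeat counts differ by >= this many units fall into
#: different subgroups even with identical indel elements ("major difference")
DEFAULT_MAJOR_REPEAT_DELTA = 4

#: sequences with more than this fraction of ambiguous bases are excluded
MAX_AMBIGUOUS_FRACTION = 0.02


class GenotyperError(ValueError):
    pass


@dataclass
class NostocGenotype:
    code: str
    member_seq_ids: list[str]
    representative_seq: str
    subgroup: str = ""
    lineage_call: str = AMBIGUOUS
    indel_signature: str = ""
    annotation: Optional[IntronAnnotation] = field(default=None, repr=False)
    first_index: int = 0  # input rank of the first member, for stable naming

    @property
    def n_members(self) -> int:
        return len(self.member_seq_ids)


def collapse_introns(
    seqs: SequenceSet,
    annotations: dict[str, IntronAnnotation],
    max_ambiguous_fraction: float = MAX_AMBIGUOUS_FRACTION,
) -> list[NostocGenotype]:
    """Exact-identity collapsing of intron sequences into genotypes.

    Sequences with > ``max_ambiguous_fraction`` non-ACGT bases are excluded
    with a warning (exact identity is meaningless for low-quality reads), as
    are zero-length records.
    """
    groups: dict[str, list[str]] = {}
    order: dict[str, int] = {}
    for idx, (sid, seq) in enumerate(seqs):
        if len(seq) == 0:
            warnings.warn(f"{sid}: zero-length intron excluded", stacklevel=2)
            continue
        n_ambig = sum(1 for b in seq if b not in "ACGT")
        if n_ambig / len(seq) > max_ambiguous_fraction:
            warnings.warn(
                f"{sid}: {n_ambig} ambiguous bases (> "
                f"{max_ambiguous_fraction:.0%}); excluded from genotyping",
                stacklevel=2,
            )
            continue
        if sid not in annotations:
            raise GenotyperError(f"no annotation available for sequence {sid!r}")
        if seq not in groups:
            groups[seq] = []
            order[seq] = idx
        groups[seq].append(sid)
    genotypes = []
    for seq, members in groups.items():
        ann = annotations[members[0]]
        genotypes.append(
            NostocGenotype(
                code="",
                member_seq_ids=members,
                representative_seq=seq,
                lineage_call=ann.lineage_call,
                indel_signature=ann.indel_signature,
                annotation=ann,
                first_index=order[seq],
            )
        )
    return genotypes


def _repeat_strata(counts: Iterable[int], delta: int) -> dict[int, int]:
    """Single-linkage grouping of total repeat counts: counts whose gap to the
    nearest neighbour is < ``delta`` share a stratum."""
    uniq = sorted(set(counts))
    strata: dict[int, int] = {}
    stratum = 0
    for i, c in enumerate(uniq):
        if i > 0 and c - uniq[i - 1] >= delta:
            stratum += 1
        strata[c] = stratum
    return strata


def _subgroup_sort_key(members: list[NostocGenotype]):
    size = sum(g.n_members for g in members)
    rep = min(g.representative_seq for g in members)
    return (-size, rep)


def assign_subgroups(
    genotypes: list[NostocGenotype],
    major_repeat_delta: int = DEFAULT_MAJOR_REPEAT_DELTA,
) -> list[NostocGenotype]:
    """Partition genotypes into subgroups by major P6b differences.

    Genotypes with identical indel-element content (same catalogue tags) and
    total repeat counts within ``major_repeat_delta`` of each other share a
    subgroup.  Bipartite-lineage subgroups get letters in order of decreasing
    specimen count (ties: lexicographically smallest representative);
    tripartite Class 1 subgroups get Y0, Y1, ...; tripartite Class 2 get
    X1, X2, ...; ambiguous/unclassified genotypes get U1, U2, ....
    """
    pools: dict[str, list[NostocGenotype]] = {"bi": [], "y": [], "x": [], "u": []}
    for g in genotypes:
        if g.lineage_call == BIPARTITE_TYPE:
            pools["bi"].append(g)
        elif g.lineage_call == TRIPARTITE_TYPE and g.annotation is not None and \
                g.annotation.repeat_class == CLASS2:
            pools["x"].append(g)
        elif g.lineage_call == TRIPARTITE_TYPE:
            pools["y"].append(g)
        else:
            pools["u"].append(g)

    def _cluster(pool: list[NostocGenotype]) -> list[list[NostocGenotype]]:
        by_indels: dict[tuple, list[NostocGenotype]] = {}
        for g in pool:
            tags = tuple(sorted(e.tag for e in g.annotation.indel_elements)) \
                if g.annotation else ()
            klass = g.annotation.repeat_class if g.annotation else "?"
            by_indels.setdefault((klass, tags), []).append(g)
        clusters: list[list[NostocGenotype]] = []
        for members in by_indels.values():
            strata = _repeat_strata(
                (g.annotation.n_repeats if g.annotation else 0 for g in members),
                major_repeat_delta,
            )
            sub: dict[int, list[NostocGenotype]] = {}
            for g in members:
                n = g.annotation.n_repeats if g.annotation else 0
                sub.setdefault(strata[n], []).append(g)
            clusters.extend(sub.values())
        return sorted(clusters, key=_subgroup_sort_key)

    def _label(clusters, labels):
        for cluster, lab in zip(clusters, labels):
            for g in cluster:
                g.subgroup = lab
                tags = ",".join(sorted(e.tag for e in g.annotation.indel_elements)) \
                    if g.annotation else ""
                klass = g.annotation.repeat_class if g.annotation else "?"
                g.indel_signature = f"{klass}|indels[{tags}]|subgroup={lab}"

    bi = _cluster(pools["bi"])
    letters = list(string.ascii_uppercase) + [f"Z{i}" for i in range(1, 100)]
    _label(bi, letters)
    _label(_cluster(pools["y"]), [f"Y{i}" for i in range(100)])
    _label(_cluster(pools["x"]), [f"X{i}" for i in range(1, 100)])
    _label(_cluster(pools["u"]), [f"U{i}" for i in range(1, 100)])
    return genotypes


def name_genotypes(
    genotypes: list[NostocGenotype],
    labelmap: Optional[dict[str, str]] = None,
) -> list[NostocGenotype]:
    """Assign genotype codes within each subgroup.

    Numbering is by decreasing member count, then by first appearance.  A
    ``labelmap`` of published codes (code -> representative sequence) pins
    matching sequences to their published names; a collision (one code, two
    distinct sequences) is an error.
    """
    pinned: dict[str, str] = {}  # sequence -> code
    if labelmap:
        for code, seq in labelmap.items():
            if seq in pinned and pinned[seq] != code:
                raise GenotyperError(
                    f"labelmap collision: sequence pinned to both "
                    f"{pinned[seq]!r} and {code!r}"
                )
            pinned[seq] = code
        codes_seen: dict[str, str] = {}
        for code, seq in labelmap.items():
            if code in codes_seen and codes_seen[code] != seq:
                raise GenotyperError(
                    f"labelmap collision: code {code!r} maps to two sequences"
                )
            codes_seen[code] = seq
    by_subgroup: dict[str, list[NostocGenotype]] = {}
    for g in genotypes:
        by_subgroup.setdefault(g.subgroup, []).append(g)
    for subgroup, members in by_subgroup.items():
        members.sort(key=lambda g: (-g.n_members, g.first_index))
        used = {pinned[g.representative_seq] for g in members
                if g.representative_seq in pinned}
        sep = "" if len(subgroup) == 1 else "-"
        n = 1
        for g in members:
            if g.representative_seq in pinned:
                g.code = pinned[g.representative_seq]
                continue
            while f"{subgroup}{sep}{n}" in used:
                n += 1
            g.code = f"{subgroup}{sep}{n}"
            n += 1
    return genotypes


def genotype_of_sequence(genotypes: Iterable[NostocGenotype]) -> dict[str, str]:
    out: dict[str, str] = {}
    for g in genotypes:
        for sid in g.member_seq_ids:
            out[sid] = g.code
    return out


def genotypes_to_rows(genotypes: Iterable[NostocGenotype]) -> list[dict]:
    return [
        {
            "code": g.code,
            "subgroup": g.subgroup,
            "lineage_call": g.lineage_call,
            "indel_signature": g.indel_signature,
            "n_members": g.n_members,
            "member_seq_ids": ",".join(g.member_seq_ids),
            "representative_seq": g.representative_seq,
        }
        for g in genotypes
    ]
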
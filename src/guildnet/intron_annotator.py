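"""Structural annotation of the cyanobacterial tRNA-Leu (UAA) intron.

The group-I intron carries two named stem loops used for genotyping:

* **P5b** — holds the diagnostic base at reference coordinate 71 ("71T").
* **P6b** — a variable hairpin whose stem is built from degenerate
  heptanucleotide tandem repeats (Class 1 or Class 2 consensus), occasionally
  interrupted by short non-repeat indel elements.  The unpaired segment at the
  hairpin tip is the central loop, carrying the "3T" and "AGTCTTM" signature
  characters.

Two symbiont lineages are called from these characters: *Nostoc* strains of
bipartite hosts (Class 1 repeats + 3T + 71T) and the distinct lineage found in
cephalodia of tripartite hosts (AGTCTTM central loop, 71T absent).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import yaml

from . import iupac
from ._fold import HairpinFold, fold_hairpin
from .seq_io import SequenceSet

REPEAT_LEN = 7

CLASS1 = "CLASS1"
CLASS2 = "CLASS2"
UNCLASSIFIED = "UNCLASSIFIED"

BIPARTITE_TYPE = "BIPARTITE_TYPE"
TRIPARTITE_TYPE = "TRIPARTITE_TYPE"
AMBIGUOUS = "AMBIGUOUS"

CENTRAL_LOOP_TRIPARTITE_MOTIF = "AGTCTTM"


@dataclass(frozen=True)
class ReferenceProfile:
    """Conserved anchors and repeat consensus used for annotation."""

    name: str
    p5b_flank5: str
    p5b_flank3: str
    p6b_flank5: str
    p6b_flank3: str
    position71_offset: int
    class1_consensus: str
    class2_consensus: str
    repeat_match_threshold: int
    indel_elements: dict[str, str]

    def __post_init__(self) -> None:
        for pat in (self.class1_consensus, self.class2_consensus):
            if len(pat) != REPEAT_LEN:
                raise ValueError(f"repeat consensus must be length 7: {pat!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReferenceProfile":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            name=raw.get("name", "custom"),
            p5b_flank5=raw["p5b_flank5"],
            p5b_flank3=raw["p5b_flank3"],
            p6b_flank5=raw["p6b_flank5"],
            p6b_flank3=raw["p6b_flank3"],
            position71_offset=int(raw["position71_offset"]),
            class1_consensus=raw["class1_consensus"],
            class2_consensus=raw["class2_consensus"],
            repeat_match_threshold=int(raw["repeat_match_threshold"]),
            indel_elements=dict(raw.get("indel_elements", {})),
        )

    @classmethod
    def default(cls) -> "ReferenceProfile":
        ref = importlib.resources.files("guildnet") / "data" / "default_profile.yaml"
        with importlib.resources.as_file(ref) as p:
            return cls.from_yaml(p)

    def indel_tag(self, seq: str) -> Optional[str]:
        """Insertion-point tag for a known indel element (either strand)."""
        rc = iupac.revcomp(seq)
        for tag, element in self.indel_elements.items():
            if seq == element or rc == element:
                return tag
        return None


@dataclass
class RepeatUnit:
    seq: str
    start: int  # position within the P6b region
    score: int
    repeat_class: str


@dataclass
class IndelElement:
    tag: str  # catalogue insertion-point tag (*, **, ***, ^^) or "@<pos>"
    seq: str
    start: int


@dataclass
class RegionLocation:
    p5b_interval: Optional[tuple[int, int]]
    p6b_interval: Optional[tuple[int, int]]
    p6b_central_loop: str
    loop_interval: Optional[tuple[int, int]]  # relative to the P6b region
    p5b_anchor: Optional[int]  # start of the p5b_flank5 match
    fold: Optional[HairpinFold] = None


@dataclass
class IntronAnnotation:
    seq_id: str
    intron_length: int
    p5b_interval: Optional[tuple[int, int]] = None
    p6b_interval: Optional[tuple[int, int]] = None
    p6b_central_loop: str = ""
    repeat_class: str = UNCLASSIFIED
    repeats: list[RepeatUnit] = field(default_factory=list)
    indel_elements: list[IndelElement] = field(default_factory=list)
    sig_3T: bool = False
    sig_71T: bool = False
    sig_AGTCTTM: bool = False
    lineage_call: str = AMBIGUOUS
    notes: list[str] = field(default_factory=list)
    fold: Optional[HairpinFold] = None

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    @property
    def indel_signature(self) -> str:
        """Canonical summary of indel-element content and repeat class."""
        tags = ",".join(sorted(e.tag for e in self.indel_elements))
        return f"{self.repeat_class}|indels[{tags}]"


def _unit_score(window: str, profile: ReferenceProfile) -> tuple[int, str]:
    """Best (score, class) of a 7-mer against both consensus patterns.

    The 3' arm of the P6b hairpin carries the repeats in reverse-complement
    orientation, so each pattern is also tried reverse-complemented; Class 1
    wins ties (it is checked first).
    """
    best, klass = -1, CLASS1
    for pattern, name in (
        (profile.class1_consensus, CLASS1),
        (iupac.revcomp(profile.class1_consensus), CLASS1),
        (profile.class2_consensus, CLASS2),
        (iupac.revcomp(profile.class2_consensus), CLASS2),
    ):
        s = iupac.motif_score(window, pattern)
        if s > best:
            best, klass = s, name
    return best, klass


def locate_regions(seq: str, profile: ReferenceProfile) -> RegionLocation:
    """Locate the P5b and P6b stem loops by their conserved flank anchors.

    Intervals are 0-based half-open and span the variable region strictly
    between the two anchors.  The central loop of P6b is delineated from the
    maximum-base-pair fold of the region (interior of the main hairpin stem).
    A missing anchor leaves that region absent; downstream operations degrade
    to UNCLASSIFIED/AMBIGUOUS rather than fail.
    """
    p5b = None
    p5b_anchor = None
    a = iupac.find_motif(seq, profile.p5b_flank5)
    if a >= 0:
        b = iupac.find_motif(seq, profile.p5b_flank3, a + len(profile.p5b_flank5))
        if b >= 0:
            p5b = (a + len(profile.p5b_flank5), b)
        p5b_anchor = a
    p6b = None
    search_from = p5b[1] if p5b else 0
    c = iupac.find_motif(seq, profile.p6b_flank5, search_from)
    if c < 0:
        c = iupac.find_motif(seq, profile.p6b_flank5)
    if c >= 0:
        d = iupac.find_motif(seq, profile.p6b_flank3, c + len(profile.p6b_flank5))
        if d >= 0:
            p6b = (c + len(profile.p6b_flank5), d)
    loop_seq, loop_iv, fold = "", None, None
    if p6b is not None and p6b[1] - p6b[0] >= 10:
        region = seq[p6b[0] : p6b[1]]
        fold = fold_hairpin(region)
        loop_iv = fold.loop
        loop_seq = region[loop_iv[0] : loop_iv[1]]
    return RegionLocation(
        p5b_interval=p5b,
        p6b_interval=p6b,
        p6b_central_loop=loop_seq,
        loop_interval=loop_iv,
        p5b_anchor=p5b_anchor,
        fold=fold,
    )


def decompose_repeats(
    p6b_seq: str,
    profile: ReferenceProfile,
    loop_interval: Optional[tuple[int, int]] = None,
) -> tuple[list[RepeatUnit], list[IndelElement], str]:
    """Tile the P6b stem into heptanucleotide repeat units and indel elements.

    Greedy left-to-right tiling of each stem arm (the central loop, when
    given, is skipped): a 7-mer scoring >= the profile threshold against a
    class consensus becomes a repeat unit; maximal stretches where no window
    passes become indel elements, tagged from the profile's indel catalogue
    (positional ``@<pos>`` tags for unknown elements).  Ties favour repeats.
    """
    segments = (
        [(0, len(p6b_seq))]
        if loop_interval is None
        else [(0, loop_interval[0]), (loop_interval[1], len(p6b_seq))]
    )
    thr = profile.repeat_match_threshold
    repeats: list[RepeatUnit] = []
    indels: list[IndelElement] = []

    def _emit_indel(lo: int, hi: int) -> None:
        if hi > lo:
            s = p6b_seq[lo:hi]
            tag = profile.indel_tag(s) or f"@{lo}"
            indels.append(IndelElement(tag=tag, seq=s, start=lo))

    for lo, hi in segments:
        i = lo
        while hi - i >= REPEAT_LEN:
            score, klass = _unit_score(p6b_seq[i : i + REPEAT_LEN], profile)
            if score >= thr:
                repeats.append(RepeatUnit(p6b_seq[i : i + REPEAT_LEN], i, score, klass))
                i += REPEAT_LEN
                continue
            # scan for the resumption point with a one-unit look-ahead: a
            # window only restarts the tiling if the following unit also
            # passes (or the segment ends there); this rejects spurious
            # windows straddling an indel/repeat junction
            j = i + 1
            while hi - j >= REPEAT_LEN:
                score, _ = _unit_score(p6b_seq[j : j + REPEAT_LEN], profile)
                if score >= thr:
                    nxt = p6b_seq[j + REPEAT_LEN : j + 2 * REPEAT_LEN]
                    if len(nxt) < REPEAT_LEN:
                        break
                    nxt_score, _ = _unit_score(nxt, profile)
                    if nxt_score >= thr:
                        break
                j += 1
            else:
                j = hi
            if hi - j < REPEAT_LEN:
                j = hi
            _emit_indel(i, j)
            i = j
        _emit_indel(i, hi)

    if not repeats:
        return repeats, indels, UNCLASSIFIED
    n1 = sum(1 for r in repeats if r.repeat_class == CLASS1)
    repeat_class = CLASS1 if n1 * 2 >= len(repeats) else CLASS2
    return repeats, indels, repeat_class


def detect_signatures(
    ann: IntronAnnotation, profile: ReferenceProfile, seq: str
) -> IntronAnnotation:
    """Evaluate the three diagnostic signature characters on an annotation.

    * ``sig_3T`` — base 3 (1-based) of the P6b central loop is T;
    * ``sig_AGTCTTM`` — the central loop matches AGTCTTM (IUPAC, M = A/C);
    * ``sig_71T`` — T at the base mapped to reference coordinate 71, found
      by ungapped offset from the P5b flank anchor.
    """
    loop = ann.p6b_central_loop
    if len(loop) >= 3:
        ann.sig_3T = loop[2] == "T"
    else:
        ann.sig_3T = False
        if ann.p6b_interval is not None:
            ann.notes.append("central loop shorter than 3 nt; 3T not evaluable")
    ann.sig_AGTCTTM = iupac.motif_matches(loop, CENTRAL_LOOP_TRIPARTITE_MOTIF)
    ann.sig_71T = False
    anchor = iupac.find_motif(seq, profile.p5b_flank5)
    if anchor >= 0:
        pos = anchor + profile.position71_offset
        if pos < len(seq):
            ann.sig_71T = seq[pos] == "T"
        else:
            ann.notes.append("position 71 maps beyond the sequence end")
    else:
        ann.notes.append("P5b anchor absent; 71T not evaluable")
    return ann


def classify_lineage(ann: IntronAnnotation) -> str:
    """Call the symbiont lineage from repeat class and signature characters.

    BIPARTITE_TYPE requires Class 1 repeats, 3T and 71T; TRIPARTITE_TYPE
    requires the AGTCTTM central loop and the *absence* of 71T.  The two rules
    are mutually exclusive (one demands 71T, the other its negation); anything
    else is AMBIGUOUS.
    """
    if ann.repeat_class == CLASS1 and ann.sig_3T and ann.sig_71T:
        return BIPARTITE_TYPE
    if ann.sig_AGTCTTM and not ann.sig_71T:
        return TRIPARTITE_TYPE
    return AMBIGUOUS


def annotate_intron(
    seq: str, seq_id: str = "?", profile: Optional[ReferenceProfile] = None
) -> IntronAnnotation:
    """Full structural annotation of one intron sequence."""
    profile = profile or ReferenceProfile.default()
    ann = IntronAnnotation(seq_id=seq_id, intron_length=len(seq))
    if not (200 <= len(seq) <= 450):
        ann.notes.append(f"length {len(seq)} outside the expected 200-450 window")
    loc = locate_regions(seq, profile)
    ann.p5b_interval = loc.p5b_interval
    ann.p6b_interval = loc.p6b_interval
    ann.p6b_central_loop = loc.p6b_central_loop
    ann.fold = loc.fold
    if loc.p6b_interval is not None:
        region = seq[loc.p6b_interval[0] : loc.p6b_interval[1]]
        ann.repeats, ann.indel_elements, ann.repeat_class = decompose_repeats(
            region, profile, loc.loop_interval
        )
    else:
        ann.notes.append("P6b anchors not found; repeat class UNCLASSIFIED")
    detect_signatures(ann, profile, seq)
    ann.lineage_call = classify_lineage(ann)
    return ann


def annotate_set(
    seqs: SequenceSet, profile: Optional[ReferenceProfile] = None
) -> dict[str, IntronAnnotation]:
    """Annotate every sequence; identical sequences are annotated once."""
    profile = profile or ReferenceProfile.default()
    cache: dict[str, IntronAnnotation] = {}
    out: dict[str, IntronAnnotation] = {}
    for sid, seq in seqs:
        if seq not in cache:
            cache[seq] = annotate_intron(seq, sid, profile)
        base = cache[seq]
        out[sid] = base if base.seq_id == sid else replace(base, seq_id=sid)
    return out


def annotations_to_rows(anns: Iterable[IntronAnnotation]) -> list[dict]:
    """Flatten annotations for TSV export."""
    rows = []
    for a in anns:
        rows.append(
            {
                "seq_id": a.seq_id,
                "intron_length": a.intron_length,
                "p5b_start": a.p5b_interval[0] if a.p5b_interval else "",
                "p5b_end": a.p5b_interval[1] if a.p5b_interval else "",
                "p6b_start": a.p6b_interval[0] if a.p6b_interval else "",
                "p6b_end": a.p6b_interval[1] if a.p6b_interval else "",
                "central_loop": a.p6b_central_loop,
                "repeat_class": a.repeat_class,
                "n_repeats": a.n_repeats,
                "indel_tags": ",".join(sorted(e.tag for e in a.indel_elements)),
                "sig_3T": a.sig_3T,
                "sig_71T": a.sig_71T,
                "sig_AGTCTTM": a.sig_AGTCTTM,
                "lineage_call": a.lineage_call,
                "dot_bracket": a.fold.dot_bracket() if a.fold else "",
            }
        )
    return rows
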
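"""Fungal ITS delimitation and genotype collapsing.

The ITS region (ITS1 - 5.8S - ITS2) is cut out of each amplicon using two
conserved flanking motifs: the 3' end of the 18S (rns) rRNA gene,
``AAGGATCATTA``, and the 5' end of the rnl gene, ``RTTGACCTCGGATCAGGTAGG``
(R = A or G).  The ITS proper is the interval strictly between the two motifs.
Identical ITS copies are then collapsed into fungal genotypes with
species-scoped codes (e.g. NP1 for the first *N. parile* genotype).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

from . import iupac
from .seq_io import SequenceSet, SpecimenRecord

#: 3' terminus of the 18S (rns) gene — the base immediately after it starts ITS1
FLANK5_MOTIF = "AAGGATCATTA"
#: 5' terminus of the rnl gene — ITS2 ends where this motif begins
FLANK3_MOTIF = "RTTGACCTCGGATCAGGTAGG"

#: plausibility window for accepted ITS lengths (bp); observed range in
#: *Nephroma* is 485-515 bp
DEFAULT_LENGTH_WINDOW = (400, 600)


class ItsError(ValueError):
    pass


@dataclass
class ItsDelimitation:
    """Result of cutting the ITS out of one amplicon (0-based half-open)."""

    seq_id: str
    its_start: int
    its_end: int
    its_seq: str
    flank5_found: bool
    flank3_found: bool
    length_ok: bool = True

    @property
    def its_length(self) -> int:
        return self.its_end - self.its_start


@dataclass
class FungalGenotype:
    code: str
    member_seq_ids: list[str]
    representative_seq: str
    species: str
    multi_species: bool = False
    species_labels: set[str] = field(default_factory=set)

    @property
    def n_members(self) -> int:
        return len(self.member_seq_ids)


def delimit_its(
    seq: str,
    seq_id: str = "?",
    length_window: tuple[int, int] = DEFAULT_LENGTH_WINDOW,
) -> ItsDelimitation:
    """Locate the ITS between the conserved rns / rnl flank motifs.

    The *last* occurrence of the 5' motif and the *first* subsequent
    occurrence of the (degenerate) 3' motif delimit the ITS; this guards
    against chance internal hits.  A missing flank degrades to the sequence
    end on that side, recorded in the flag.
    """
    if len(seq) < len(FLANK5_MOTIF) + len(FLANK3_MOTIF):
        raise ItsError(f"{seq_id}: sequence too short to contain both ITS anchors")
    p5 = iupac.rfind_motif(seq, FLANK5_MOTIF)
    if p5 >= 0:
        start = p5 + len(FLANK5_MOTIF)
        p3 = iupac.find_motif(seq, FLANK3_MOTIF, start)
        flank5_found = True
        flank3_found = p3 >= 0
        end = p3 if p3 >= 0 else len(seq)
    else:
        p3 = iupac.find_motif(seq, FLANK3_MOTIF)
        if p3 < 0:
            raise ItsError(f"{seq_id}: no ITS anchors found")
        flank5_found = False
        flank3_found = True
        start, end = 0, p3
    if end < start:
        raise ItsError(f"{seq_id}: ITS flank motifs in wrong order")
    its_seq = seq[start:end]
    lo, hi = length_window
    length_ok = lo <= len(its_seq) <= hi
    if not length_ok:
        warnings.warn(
            f"{seq_id}: ITS length {len(its_seq)} outside plausibility "
            f"window [{lo}, {hi}]",
            stacklevel=2,
        )
    return ItsDelimitation(
        seq_id=seq_id,
        its_start=start,
        its_end=end,
        its_seq=its_seq,
        flank5_found=flank5_found,
        flank3_found=flank3_found,
        length_ok=length_ok,
    )


def delimit_all(
    seqs: SequenceSet,
    length_window: tuple[int, int] = DEFAULT_LENGTH_WINDOW,
) -> list[ItsDelimitation]:
    return [delimit_its(seq, sid, length_window) for sid, seq in seqs]


def species_prefix(species: str, taken: set[str]) -> str:
    """Genotype-code prefix from a species label, e.g. 'N. parile' -> 'NP'.

    On collision with an already-taken prefix, extend with further letters of
    the epithet (NP, NPa, NPar, ...).
    """
    words = [w for w in species.replace(".", " ").split() if w]
    if not words:
        base, epithet = "X", ""
    else:
        base, epithet = words[0][0].upper(), words[-1] if len(words) > 1 else ""
    prefix = base + (epithet[:1].upper() if epithet else "")
    k = 1
    while prefix in taken:
        k += 1
        prefix = base + epithet[:1].upper() + epithet[1:k].lower()
        if k > len(epithet):
            prefix = prefix + "X"
            break
    return prefix


def collapse_its(
    delims: Iterable[ItsDelimitation],
    records: Optional[Iterable[SpecimenRecord]] = None,
    per_species: bool = True,
    allow_partial: bool = False,
) -> list[FungalGenotype]:
    """Collapse identical delimited ITS strings into fungal genotypes.

    Identity is exact string match (ambiguity codes only collapse with
    identical strings).  Genotypes are species-scoped by default, coded
    per species in order of first appearance; ``per_species=False`` gives a
    single global dereplication with G-prefixed codes.
    """
    delims = list(delims)
    for d in delims:
        if not (d.flank5_found and d.flank3_found) and not allow_partial:
            raise ItsError(
                f"{d.seq_id}: partial delimitation (missing flank); pass "
                "allow_partial=True to collapse anyway"
            )
    species_of: dict[str, str] = {}
    if records is not None:
        for rec in records:
            if rec.fungal_seq_id:
                species_of[rec.fungal_seq_id] = rec.fungal_species

    # group sequences, preserving first-appearance order
    groups: dict[tuple[str, str], list[str]] = {}
    for d in delims:
        sp = species_of.get(d.seq_id, "unknown") if per_species else ""
        groups.setdefault((sp, d.its_seq), []).append(d.seq_id)

    prefixes: dict[str, str] = {}
    taken: set[str] = set()
    counters: dict[str, int] = {}
    genotypes: list[FungalGenotype] = []
    for (sp, its_seq), members in groups.items():
        if per_species:
            if sp not in prefixes:
                prefixes[sp] = species_prefix(sp, taken)
                taken.add(prefixes[sp])
            prefix = prefixes[sp]
        else:
            prefix = "G"
        counters[prefix] = counters.get(prefix, 0) + 1
        labels = {species_of[m] for m in members if m in species_of}
        genotypes.append(
            FungalGenotype(
                code=f"{prefix}{counters[prefix]}",
                member_seq_ids=list(members),
                representative_seq=its_seq,
                species=sp if per_species else (sorted(labels)[0] if labels else "unknown"),
                multi_species=len(labels) > 1,
                species_labels=labels,
            )
        )
    return genotypes


def genotype_of_sequence(genotypes: Iterable[FungalGenotype]) -> dict[str, str]:
    """Map each member sequence id to its genotype code."""
    out: dict[str, str] = {}
    for g in genotypes:
        for sid in g.member_seq_ids:
            out[sid] = g.code
    return out
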
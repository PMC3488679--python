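"""Sequence and specimen-metadata I/O.

A dataset consists of two FASTA files (fungal ITS amplicons and cyanobacterial
tRNA-Leu (UAA) intron amplicons) plus a tab-separated specimen table linking
the two sequences that came from one lichen thallus.  Either sequence may be
absent for a specimen (single-symbiont records); at least one must be present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_CODES = set("ACGTRYSWKMBDHVN")

#: fixed column order of the specimen metadata table
METADATA_COLUMNS = [
    "specimen_id",
    "fungal_species",
    "fungal_seq_id",
    "photobiont_seq_id",
    "region",
    "locality",
]


class SeqIOError(ValueError):
    """Raised on malformed sequence or metadata input."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One lichen thallus, linking a mycobiont and/or a photobiont sequence."""

    specimen_id: str
    fungal_species: str
    fungal_seq_id: Optional[str]
    photobiont_seq_id: Optional[str]
    region: str
    locality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.fungal_seq_id and not self.photobiont_seq_id:
            raise SeqIOError(
                f"specimen {self.specimen_id!r}: neither a fungal nor a "
                "photobiont sequence id is present"
            )

    @property
    def is_paired(self) -> bool:
        return bool(self.fungal_seq_id) and bool(self.photobiont_seq_id)


@dataclass
class SequenceSet:
    """An ordered collection of uppercase IUPAC nucleotide sequences."""

    records: list[tuple[str, str]]
    molecule: str  # "ITS" or "trnL_intron"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for seq_id, seq in self.records:
            if seq_id in seen:
                raise SeqIOError(f"duplicate sequence id {seq_id!r}")
            seen.add(seq_id)
            if not seq:
                raise SeqIOError(f"sequence {seq_id!r} is empty")
            for pos, base in enumerate(seq):
                if base not in IUPAC_CODES:
                    raise SeqIOError(
                        f"sequence {seq_id!r}: non-IUPAC character "
                        f"{base!r} at position {pos}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    def get(self, seq_id: str) -> str:
        for sid, seq in self.records:
            if sid == seq_id:
                return seq
        raise KeyError(seq_id)

    def as_dict(self) -> dict[str, str]:
        return dict(self.records)


def normalize_sequence(raw: str, seq_id: str = "?") -> str:
    """Uppercase, map U->T, strip gap characters (with a warning)."""
    seq = raw.upper().replace("U", "T")
    if "-" in seq or "." in seq:
        warnings.warn(f"sequence {seq_id!r}: gap characters stripped", stacklevel=2)
        seq = seq.replace("-", "").replace(".", "")
    return seq


def read_fasta(path: str | Path, molecule: str) -> SequenceSet:
    """Read a multi-record FASTA file into a normalized :class:`SequenceSet`."""
    path = Path(path)
    if not path.exists():
        raise SeqIOError(f"FASTA file not found: {path}")
    records = [
        (rec.id, normalize_sequence(str(rec.seq), rec.id))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return SequenceSet(records=records, molecule=molecule)


def write_fasta(seqs: SequenceSet | Iterable[tuple[str, str]], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in seqs
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


def read_metadata(
    path: str | Path,
    its_set: Optional[SequenceSet] = None,
    intron_set: Optional[SequenceSet] = None,
) -> list[SpecimenRecord]:
    """Read the tab-separated specimen table.

    Columns (header required): specimen_id, fungal_species, fungal_seq_id,
    photobiont_seq_id, region, locality.  Empty cells mean "absent".  When
    sequence sets are supplied, every referenced sequence id is cross-checked.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise SeqIOError(f"metadata is missing required columns: {missing}")
    records: list[SpecimenRecord] = []
    seen_ids: set[str] = set()
    for _, row in df.iterrows():
        sid = row["specimen_id"]
        if sid in seen_ids:
            raise SeqIOError(f"duplicate specimen_id {sid!r}")
        seen_ids.add(sid)
        rec = SpecimenRecord(
            specimen_id=sid,
            fungal_species=row["fungal_species"],
            fungal_seq_id=row["fungal_seq_id"] or None,
            photobiont_seq_id=row["photobiont_seq_id"] or None,
            region=row["region"],
            locality=row.get("locality") or None,
        )
        records.append(rec)
    if its_set is not None:
        known = set(its_set.ids)
        for rec in records:
            if rec.fungal_seq_id and rec.fungal_seq_id not in known:
                raise SeqIOError(
                    f"specimen {rec.specimen_id!r}: unknown fungal sequence id "
                    f"{rec.fungal_seq_id!r}"
                )
    if intron_set is not None:
        known = set(intron_set.ids)
        for rec in records:
            if rec.photobiont_seq_id and rec.photobiont_seq_id not in known:
                raise SeqIOError(
                    f"specimen {rec.specimen_id!r}: unknown photobiont sequence id "
                    f"{rec.photobiont_seq_id!r}"
                )
    return records


def write_metadata(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    rows = [
        {
            "specimen_id": r.specimen_id,
            "fungal_species": r.fungal_species,
            "fungal_seq_id": r.fungal_seq_id or "",
            "photobiont_seq_id": r.photobiont_seq_id or "",
            "region": r.region,
            "locality": r.locality or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def region_vocabulary(records: Iterable[SpecimenRecord]) -> list[str]:
    return sorted({r.region for r in records})


@dataclass
class DatasetSummary:
    n_paired: int
    n_fungal_only: int
    n_photobiont_only: int
    n_its_sequences: int
    n_intron_sequences: int
    per_species: pd.DataFrame = field(repr=False)
    per_region: pd.DataFrame = field(repr=False)


def dataset_summary(
    records: list[SpecimenRecord],
    its_set: Optional[SequenceSet] = None,
    intron_set: Optional[SequenceSet] = None,
) -> DatasetSummary:
    """Tally paired / single-symbiont specimens and per-species/region counts."""
    n_paired = sum(1 for r in records if r.is_paired)
    n_fungal_only = sum(1 for r in records if r.fungal_seq_id and not r.photobiont_seq_id)
    n_photo_only = sum(1 for r in records if r.photobiont_seq_id and not r.fungal_seq_id)

    def _tally(key) -> pd.DataFrame:
        rows: dict[str, dict[str, int]] = {}
        for r in records:
            d = rows.setdefault(key(r), {"paired": 0, "fungal_only": 0, "photobiont_only": 0})
            if r.is_paired:
                d["paired"] += 1
            elif r.fungal_seq_id:
                d["fungal_only"] += 1
            else:
                d["photobiont_only"] += 1
        df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
        if df.empty:
            df = pd.DataFrame(columns=["paired", "fungal_only", "photobiont_only"])
        return df

    return DatasetSummary(
        n_paired=n_paired,
        n_fungal_only=n_fungal_only,
        n_photobiont_only=n_photo_only,
        n_its_sequences=len(its_set) if its_set is not None else 0,
        n_intron_sequences=len(intron_set) if intron_set is not None else 0,
        per_species=_tally(lambda r: r.fungal_species),
        per_region=_tally(lambda r: r.region),
    )
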
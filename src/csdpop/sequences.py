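"""Reading, translating, trimming and deduplicating csd sequence fragments.

An *allele* throughout this package is a non-identical amino-acid sequence of
the analysed csd fragment (exon 7: the hypervariable region plus part of the
proline-rich domain).  Two nucleotide sequences that translate to the same
amino-acid fragment are the same allele; synonymous variants collapse.

Coordinates are 0-based, half-open, in amino-acid positions of the translated
fragment.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "NucleotideRecord",
    "RegionSpec",
    "AlleleRecord",
    "read_fasta",
    "write_fasta",
    "translate_region",
    "collapse_identical",
    "read_sample_sheet",
]

#: IUPAC nucleotide ambiguity letters: permitted on read (degenerate primers
#: contain them) but rejected inside the translated region.
IUPAC_AMBIGUITY = frozenset("RYSWKMBDHVN")
_UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class NucleotideRecord:
    """A raw nucleotide sequence as read from FASTA."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.seq.upper()) - _UNAMBIGUOUS - IUPAC_AMBIGUITY
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid nucleotide letters {sorted(bad)}"
            )


@dataclass(frozen=True)
class RegionSpec:
    """Where the analysed fragment and its hypervariable region (HVR) sit.

    ``frame_offset`` is the number of nucleotides skipped before the first
    codon.  ``region_start``/``region_end`` delimit the analysed fragment and
    ``hvr_start``/``hvr_end`` the HVR, both in amino-acid coordinates of the
    translated read (0-based, half-open).  The HVR must be nested inside the
    region.
    """

    frame_offset: int
    region_start: int
    region_end: int
    hvr_start: int
    hvr_end: int

    def __post_init__(self) -> None:
        if not 0 <= self.frame_offset <= 2:
            raise ValueError("frame_offset must be 0, 1 or 2")
        if not 0 <= self.region_start < self.region_end:
            raise ValueError("require 0 <= region_start < region_end")
        if not (self.region_start <= self.hvr_start < self.hvr_end <= self.region_end):
            raise ValueError("HVR span must be nested within the region")

    @classmethod
    def from_dict(cls, d: Mapping[str, int]) -> "RegionSpec":
        return cls(
            frame_offset=int(d["frame_offset"]),
            region_start=int(d["region_start"]),
            region_end=int(d["region_end"]),
            hvr_start=int(d["hvr_start"]),
            hvr_end=int(d["hvr_end"]),
        )


@dataclass(frozen=True)
class AlleleRecord:
    """A csd allele: the trimmed amino-acid fragment with its HVR span.

    ``hvr_span`` indexes into ``aa_seq`` (0-based, half-open).  ``apiary_id``
    and ``colony_id`` carry sampling provenance when known.
    """

    id: str
    aa_seq: str
    hvr_span: tuple[int, int]
    apiary_id: str | None = None
    colony_id: str | None = None

    def __post_init__(self) -> None:
        if not self.aa_seq:
            raise ValueError(f"allele {self.id!r}: empty amino-acid sequence")
        if "*" in self.aa_seq:
            raise ValueError(f"allele {self.id!r}: stop symbol in amino-acid sequence")
        s, e = self.hvr_span
        if not 0 <= s < e <= len(self.aa_seq):
            raise ValueError(
                f"allele {self.id!r}: HVR span {self.hvr_span} outside sequence "
                f"of length {len(self.aa_seq)}"
            )

    @property
    def hvr_seq(self) -> str:
        s, e = self.hvr_span
        return self.aa_seq[s:e]

    @property
    def hvr_len(self) -> int:
        return self.hvr_span[1] - self.hvr_span[0]


def read_fasta(path: str | Path) -> list[NucleotideRecord]:
    """Read a nucleotide FASTA file into records, order preserved.

    Raises ``ValueError`` on an empty file or on duplicate ids.
    """
    records: list[NucleotideRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(NucleotideRecord(id=rec.id, seq=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA, 70 columns per line."""
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def translate_region(
    rec: NucleotideRecord,
    spec: RegionSpec,
    apiary_id: str | None = None,
    colony_id: str | None = None,
) -> AlleleRecord:
    """Translate a nucleotide read and trim it to the analysed fragment.

    The standard genetic code is used.  An ambiguity letter or an in-frame
    stop codon inside the region aborts with ``ValueError`` rather than
    guessing at the residue.
    """
    usable = rec.seq[spec.frame_offset :]
    needed = 3 * spec.region_end
    if len(usable) < needed:
        raise ValueError(
            f"record {rec.id!r}: only {len(usable)} nt after frame offset, "
            f"need {needed} to reach region end {spec.region_end}"
        )
    region_nt = usable[3 * spec.region_start : 3 * spec.region_end]
    ambiguous = set(region_nt) - _UNAMBIGUOUS
    if ambiguous:
        raise ValueError(
            f"record {rec.id!r}: ambiguity letters {sorted(ambiguous)} inside "
            "the analysed region"
        )
    aa = str(Seq(region_nt).translate(table=1))
    if "*" in aa:
        raise ValueError(f"record {rec.id!r}: premature stop inside the region")
    return AlleleRecord(
        id=rec.id,
        aa_seq=aa,
        hvr_span=(spec.hvr_start - spec.region_start, spec.hvr_end - spec.region_start),
        apiary_id=apiary_id,
        colony_id=colony_id,
    )


def collapse_identical(
    alleles: Iterable[AlleleRecord],
) -> tuple[list[AlleleRecord], dict[str, int], dict[str, str]]:
    """Group records into identity classes by exact amino-acid equality.

    Returns ``(unique, counts, membership)`` where ``unique`` holds the
    first-seen representative of each class, ``counts`` maps representative id
    to class size, and ``membership`` maps every input id to its
    representative id.
    """
    unique: list[AlleleRecord] = []
    by_seq: dict[str, str] = {}
    counts: dict[str, int] = {}
    membership: dict[str, str] = {}
    for rec in alleles:
        rep = by_seq.get(rec.aa_seq)
        if rep is None:
            by_seq[rec.aa_seq] = rec.id
            unique.append(rec)
            counts[rec.id] = 1
            membership[rec.id] = rec.id
        else:
            counts[rep] += 1
            membership[rec.id] = rep
    return unique, counts, membership


SAMPLE_SHEET_COLUMNS = ("id", "apiary_id", "colony_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the TSV mapping sequence ids to apiary and colony."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path} missing columns {missing}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"sample sheet {path}: duplicate id {dup!r}")
    return df
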
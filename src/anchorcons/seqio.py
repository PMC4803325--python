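"""Sequence records, FASTA/FASTQ/BED input-output and elementary operations.

All coordinates inside the package are 0-based, half-open; BED files on disk
use the same convention. Sequences are stored uppercase over the alphabet
``{A, C, G, T, N}``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "SeqRecord",
    "Interval",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "write_fastq",
    "write_bed",
    "revcomp",
    "gc_fraction",
    "SeqFormatError",
]

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SeqFormatError(ValueError):
    """Raised for malformed sequence files or illegal characters."""


@dataclass(frozen=True)
class Interval:
    """Half-open interval [start, end) with a label, BED-style."""

    start: int
    end: int
    name: str = ""
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SeqRecord:
    """One named DNA sequence with optional per-base Phred quality scores."""

    id: str
    sequence: str
    quality: list[int] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID
        if bad:
            raise SeqFormatError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise SeqFormatError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def revcomp(sequence: str) -> str:
    """Reverse complement; A<->T, C<->G, N->N. Involution by construction."""
    s = sequence.upper()
    bad = set(s) - _VALID
    if bad:
        raise SeqFormatError(f"illegal characters in sequence: {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def gc_fraction(sequence: str) -> float:
    """(G+C) / (A+C+G+T); N excluded from the denominator.

    Raises on an empty sequence or one consisting only of N.
    """
    s = sequence.upper()
    bad = set(s) - _VALID
    if bad:
        raise SeqFormatError(f"illegal characters in sequence: {sorted(bad)}")
    denom = len(s) - s.count("N")
    if denom == 0:
        raise ValueError("GC fraction undefined: no unambiguous bases")
    return (s.count("G") + s.count("C")) / denom


def _open(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Parse a FASTA file into records. Lowercase input is uppercased."""
    records = []
    with _open(path) as fh:
        for rec in _BioSeqIO.parse(fh, "fasta"):
            try:
                records.append(SeqRecord(id=rec.id, sequence=str(rec.seq)))
            except SeqFormatError:
                raise
    return records


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Parse a FASTQ (Sanger, Phred+33) file into records with qualities."""
    records = []
    with _open(path) as fh:
        try:
            for rec in _BioSeqIO.parse(fh, "fastq"):
                quals = rec.letter_annotations["phred_quality"]
                records.append(
                    SeqRecord(id=rec.id, sequence=str(rec.seq), quality=list(quals))
                )
        except ValueError as exc:  # Biopython raises on length mismatch etc.
            raise SeqFormatError(f"malformed FASTQ {path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 80) -> None:
    """Write FASTA wrapped at `width` columns."""
    with _open(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    """Write 4-line FASTQ with Phred+33 qualities (constant 30 if absent)."""
    bio = []
    for rec in records:
        q = rec.quality if rec.quality is not None else [30] * len(rec.sequence)
        bio.append(
            _BioRecord(
                _BioSeq(rec.sequence),
                id=rec.id,
                description="",
                letter_annotations={"phred_quality": list(q)},
            )
        )
    with _open(path, "wt") as fh:
        _BioSeqIO.write(bio, fh, "fastq")


def write_bed(intervals: Sequence[Interval], chrom: str, path: str | Path) -> None:
    """Write BED6 (0-based, half-open), score column fixed to 0."""
    with _open(path, "wt") as fh:
        for iv in intervals:
            fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")
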
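"""Protein sequence I/O, validation, and length filtering.

Training sets for the composition classifier are built from plain protein
FASTA. Records are validated against the 20 canonical amino acids plus a
tolerated noncanonical set (X, B, Z, J, U, O — ambiguity codes,
selenocysteine and pyrrolysine), uppercased, and stripped of terminal stop
characters. Short fragments (by default anything under 40 residues) are
removed so that only plausibly full-length proteins enter a dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical residues in the fixed alphabetical order used everywhere downstream.
CANONICAL_RESIDUES: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Noncanonical residues tolerated at read time (excluded from composition).
TOLERATED_RESIDUES: frozenset[str] = frozenset("XBZJUO")

VALID_RESIDUES: frozenset[str] = frozenset(CANONICAL_RESIDUES) | TOLERATED_RESIDUES


@dataclass(frozen=True)
class ProteinRecord:
    """A validated protein sequence.

    Parameters
    ----------
    id
        Unique accession, non-empty.
    sequence
        Uppercase amino-acid string over the canonical + tolerated alphabet.
    description
        Free-text FASTA description (may be empty).
    species
        Optional species label.
    """

    id: str
    sequence: str
    description: str = ""
    species: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in VALID_RESIDUES:
                raise ValueError(
                    f"record {self.id!r}: invalid residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LengthFilterConfig:
    """Minimum-length filter settings (default 40 residues)."""

    min_length: int = 40

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


def _normalise(raw: str) -> str:
    return raw.upper().rstrip("*")


def read_fasta(path: str | Path, species: str | None = None) -> list[ProteinRecord]:
    """Read a protein FASTA file into validated records.

    Sequences are uppercased and terminal stop characters (``*``) stripped.
    Raises ``ValueError`` on duplicate ids or invalid residues; an empty
    file yields an empty list with a logged warning.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate id in {path}: {entry.id!r}")
        seen.add(entry.id)
        records.append(
            ProteinRecord(
                id=entry.id,
                sequence=_normalise(str(entry.seq)),
                description=entry.description,
                species=species,
            )
        )
    if not records:
        logger.warning("no sequences found in %s", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA, wrapped at ``width`` columns.

    Output is deterministic for a given record list, so seeded pipelines
    produce byte-identical files.
    """
    path = Path(path)
    with path.open("w") as handle:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else rec.description
            handle.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def filter_by_length(
    records: Sequence[ProteinRecord],
    config: LengthFilterConfig | None = None,
) -> list[ProteinRecord]:
    """Drop records shorter than ``config.min_length`` residues."""
    config = config or LengthFilterConfig()
    kept = [r for r in records if len(r) >= config.min_length]
    removed = len(records) - len(kept)
    if removed:
        logger.info(
            "length filter (min %d): removed %d of %d records",
            config.min_length, removed, len(records),
        )
    return kept


def to_seqrecords(records: Iterable[ProteinRecord]) -> list[SeqRecord]:
    """Convert to Biopython SeqRecords (for interop with Bio.* tooling)."""
    return [SeqRecord(Seq(r.sequence), id=r.id, description=r.description) for r in records]
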
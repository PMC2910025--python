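"""Protein sequence containers and FASTA I/O.

A :class:`ProteinSequence` is an identified amino-acid string with an optional
group label (for kinases: the catalytic-domain family, e.g. TK, CMGC).  An
:class:`AlignedSequenceSet` holds equal-length gapped rows of a multiple
sequence alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tables import AMINO_ACIDS, GAP_CHARACTER


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence with identifier and optional group label."""

    id: str
    sequence: str
    group: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self, allow_gaps: bool = False) -> None:
        """Raise ``ValueError('unknown_residue: ...')`` on non-standard letters."""
        allowed = set(AMINO_ACIDS) | ({GAP_CHARACTER} if allow_gaps else set())
        for i, aa in enumerate(self.sequence):
            if aa not in allowed:
                raise ValueError(
                    f"unknown_residue: {aa!r} in sequence {self.id} at position {i}"
                )


@dataclass
class AlignedSequenceSet:
    """Equal-length gapped sequences plus provenance of retained columns.

    ``column_origin`` maps each current column back to its index in the
    original alignment; it starts as the identity and is composed through
    column filtering.
    """

    sequences: list[ProteinSequence]
    column_origin: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequences:
            width = len(self.sequences[0].sequence)
            for s in self.sequences:
                if len(s.sequence) != width:
                    raise ValueError(
                        f"ragged alignment: {s.id} has length {len(s.sequence)}, "
                        f"expected {width}"
                    )
            if not self.column_origin:
                self.column_origin = list(range(width))

    @property
    def n_positions(self) -> int:
        return len(self.sequences[0].sequence) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.sequences)


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.id,
                  description=f"group={s.group}" if s.group else "")
        for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a (possibly aligned) FASTA file; group labels are parsed from a
    ``group=...`` token in the description when present."""
    out: list[ProteinSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        group = None
        for token in rec.description.split():
            if token.startswith("group="):
                group = token[len("group="):]
        out.append(ProteinSequence(id=rec.id, sequence=str(rec.seq), group=group))
    return out


def read_alignment(path: str | Path) -> AlignedSequenceSet:
    return AlignedSequenceSet(sequences=read_fasta(path))


def group_labels(sequences: Sequence[ProteinSequence]) -> list[str]:
    labels = [s.group for s in sequences]
    if any(g is None for g in labels):
        raise ValueError("all sequences need a group label")
    return [str(g) for g in labels]
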
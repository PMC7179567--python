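"""Reading, writing and validating sequence datasets.

Sequences are plain residue strings over a fixed alphabet (DNA, RNA or
protein).  DNA and RNA are deliberately distinct alphabets: a dataset must be
homogeneous, and ``U``/``T`` are never silently interconverted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import FastaParseError, ValidationError

__all__ = [
    "Alphabet",
    "DNA",
    "RNA",
    "PROTEIN",
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
]

_LINE_WIDTH = 80  # fixed wrap width on write, for byte-stable output

VALID_LABELS = ("positive", "negative")


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of residue symbols with a name."""

    name: str
    characters: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.characters)) != len(self.characters):
            raise ValidationError(f"alphabet {self.name!r} has duplicate characters")

    def __contains__(self, ch: str) -> bool:
        return ch in self.characters

    @property
    def charset(self) -> frozenset:
        return frozenset(self.characters)


DNA = Alphabet("DNA", ("A", "C", "G", "T"))
RNA = Alphabet("RNA", ("A", "C", "G", "U"))
PROTEIN = Alphabet("protein", tuple("ACDEFGHIKLMNPQRSTVWY"))

_BY_NAME = {a.name.lower(): a for a in (DNA, RNA, PROTEIN)}


def alphabet_by_name(name: str) -> Alphabet:
    try:
        return _BY_NAME[name.lower()]
    except KeyError:
        raise ValidationError(f"unknown alphabet {name!r}; choose DNA, RNA or protein")


def infer_alphabet(residues: Iterable[str]) -> Alphabet:
    """Guess DNA/RNA/protein from the residue characters actually used."""
    chars = set()
    for r in residues:
        chars.update(r)
    for alpha in (DNA, RNA, PROTEIN):
        if chars <= alpha.charset:
            return alpha
    raise ValidationError(f"characters {sorted(chars)} fit no known alphabet")


@dataclass(frozen=True)
class SequenceRecord:
    """One input sequence: identifier, residue string, optional class label."""

    id: str
    residues: str
    label: Optional[str] = field(default=None)

    def __post_init__(self):
        if not self.residues:
            raise ValidationError(f"record {self.id!r} has an empty residue string")
        if self.label is not None and self.label not in VALID_LABELS:
            raise ValidationError(
                f"record {self.id!r}: label must be one of {VALID_LABELS}, got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def validate_records(records: list[SequenceRecord], alphabet: Alphabet) -> None:
    """Check alphabet membership and id uniqueness for a whole dataset."""
    seen: set[str] = set()
    charset = alphabet.charset
    for rec in records:
        if rec.id in seen:
            raise ValidationError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        bad = set(rec.residues) - charset
        if bad:
            raise ValidationError(
                f"record {rec.id!r} contains characters {sorted(bad)} "
                f"outside the {alphabet.name} alphabet"
            )


def read_fasta(
    path, alphabet: Alphabet, label: Optional[str] = None
) -> list[SequenceRecord]:
    """Read a FASTA file into validated records, preserving file order.

    Lowercase residues (soft-masked repeats) are uppercased.  Every residue
    must belong to ``alphabet``; ids must be unique.  ``label`` is attached to
    every record (used for positive/negative training sets).
    """
    path = Path(path)
    with path.open() as handle:
        for lineno, line in enumerate(handle, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}:{lineno}: expected '>' header, got {line.strip()[:30]!r}"
                    )
                break
    records: list[SequenceRecord] = []
    with path.open() as handle:
        try:
            for title, seq in SimpleFastaParser(handle):
                rec_id = title.split()[0] if title.split() else title
                records.append(
                    SequenceRecord(id=rec_id, residues=seq.upper(), label=label)
                )
        except ValueError as exc:  # Biopython flags text before the first '>'
            raise FastaParseError(f"{path}: {exc}") from exc
    validate_records(records, alphabet)
    return records


def write_fasta(records: list[SequenceRecord], path) -> None:
    """Write records as wrapped FASTA; round-trips ids and residues exactly."""
    path = Path(path)
    with path.open("w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), _LINE_WIDTH):
                handle.write(rec.residues[i : i + _LINE_WIDTH] + "\n")
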
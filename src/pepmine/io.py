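"""Sequence records and tabular I/O.

Conventions used throughout the package:

* Residue positions are 1-based; ``span = (start, end)`` is inclusive.
* Peptide bond ``i`` joins residues ``i`` and ``i + 1`` (``1 <= i <= L - 1``).
* Sequences are strings over the 20 canonical one-letter amino-acid codes.
  Non-canonical letters (B, Z, X, U, O, ...) are rejected rather than
  skipped: the digestion rules are defined only over the 20-letter alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Tuple

import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class SequenceAlphabetError(ValueError):
    """A sequence contains a letter outside the 20-residue alphabet."""


def validate_sequence(seq: str, context: str = "sequence") -> str:
    """Return ``seq`` if it is a non-empty string over the canonical alphabet.

    Raises :class:`SequenceAlphabetError` naming the 1-based position of the
    first offending character.
    """
    if not seq:
        raise SequenceAlphabetError(f"{context} is empty")
    for pos, ch in enumerate(seq, start=1):
        if ch not in _AA_SET:
            raise SequenceAlphabetError(
                f"{context} contains non-canonical residue {ch!r} at position {pos}"
            )
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a free-text identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, context=f"protein {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideRecord:
    """A peptide with optional provenance back to a parent protein.

    ``annotations`` is an open key/value map used by the activity and
    screening stages (e.g. ``active``, ``activity_score``, ``gi_origin``).
    """

    sequence: str
    parent_id: Optional[str] = None
    span: Optional[Tuple[int, int]] = None
    treatment: Optional[str] = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, context="peptide")
        if self.span is not None:
            start, end = self.span
            if not (1 <= start <= end):
                raise ValueError(f"invalid span {self.span}")
            if end - start + 1 != len(self.sequence):
                raise ValueError(
                    f"span {self.span} length does not match sequence "
                    f"{self.sequence!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Sequences are uppercased and whitespace/gap characters are stripped
    before validation; any remaining non-canonical letter raises
    :class:`SequenceAlphabetError` naming its position.
    """
    path = Path(path)
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper().replace("-", "").replace(".", "")
        seq = "".join(seq.split())
        validate_sequence(seq, context=f"FASTA entry {entry.id!r}")
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


_BASE_COLUMNS = ["sequence", "parent_id", "start", "end", "treatment"]


def _sort_key(p: PeptideRecord):
    span = p.span if p.span is not None else (float("inf"), float("inf"))
    return (p.parent_id or "", span, p.sequence)


def write_peptide_table(peptides: Iterable[PeptideRecord], path) -> None:
    """Write peptides as a TSV with a stable column and row order.

    Annotations are flattened into extra columns (sorted by key) so the
    output is deterministic: the same input always produces byte-identical
    files.
    """
    peptides = sorted(peptides, key=_sort_key)
    ann_keys = sorted({k for p in peptides for k in p.annotations})
    rows = []
    for p in peptides:
        row = {
            "sequence": p.sequence,
            "parent_id": p.parent_id if p.parent_id is not None else "",
            "start": p.span[0] if p.span else "",
            "end": p.span[1] if p.span else "",
            "treatment": p.treatment if p.treatment is not None else "",
        }
        for k in ann_keys:
            row[k] = p.annotations.get(k, "")
        rows.append(row)
    df = pd.DataFrame(rows, columns=_BASE_COLUMNS + ann_keys)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_peptide_table(path) -> list[PeptideRecord]:
    """Read a peptide TSV written by :func:`write_peptide_table`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    peptides = []
    for _, row in df.iterrows():
        span = None
        if row.get("start", "") != "" and row.get("end", "") != "":
            span = (int(row["start"]), int(row["end"]))
        annotations = {
            k: row[k]
            for k in df.columns
            if k not in _BASE_COLUMNS and row[k] != ""
        }
        peptides.append(
            PeptideRecord(
                sequence=row["sequence"],
                parent_id=row["parent_id"] or None,
                span=span,
                treatment=row["treatment"] or None,
                annotations=annotations,
            )
        )
    return peptides
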
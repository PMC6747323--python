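"""Exhaustive in-silico proteolysis and quantitative release statistics.

Digestion is modelled as deterministic and exhaustive: every bond matched
by a specificity rule (and not blocked) is cut, and the released peptides
are the maximal fragments between cuts.  There is no kinetic or partial
digestion, which is what makes bond counts, the degree of hydrolysis and
the release frequencies reproducible quantities.

Two-stage (sequential) digestion models supplemental proteolysis: the
products of a first, simultaneous digestion are each offered to a second
enzyme set, honouring any substrate-length cap of the second-stage enzymes
against the *product* length.  Cleavage positions from the second stage are
mapped back to parent coordinates so the degree of hydrolysis of the whole
treatment is well defined.

Statistics (reference = a set of bioactive sequences):

* ``DH``  — 100 x (distinct cleaved bonds) / (L - 1).
* ``A_E`` — released bioactive peptides (with multiplicity) / L.
* ``W``   — released bioactive peptides / occurrences of bioactive
  sequences as substrings of the parent (overlaps counted).  Under
  exhaustive digestion released fragments are disjoint substrings, so
  ``W <= 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from .enzymes import EnzymeSpec
from .io import PeptideRecord, ProteinRecord

Parent = Union[ProteinRecord, PeptideRecord]


def find_cleavage_sites(seq: str, enzyme: EnzymeSpec) -> set[int]:
    """Bond indices (1-based, bond ``i`` follows residue ``i``) cut by ``enzyme``.

    Returns the empty set when the substrate exceeds the enzyme's
    ``substrate_max_len`` or has no internal bond.
    """
    L = len(seq)
    if L < 2:
        return set()
    if enzyme.substrate_max_len is not None and L > enzyme.substrate_max_len:
        return set()
    sites = set()
    for bond in range(1, L):
        if any(rule.matches(seq, bond) for rule in enzyme.rules) and not any(
            blk.matches(seq, bond) for blk in enzyme.global_blocks
        ):
            sites.add(bond)
    return sites


@dataclass
class DigestResult:
    """Cleaved-bond set and released peptides for one treatment.

    ``cleaved_bonds`` are in parent coordinates, including second-stage
    cleavages mapped back through the stage-1 product spans.  The peptides
    tile the parent exactly: spans are contiguous, non-overlapping and
    cover ``1..L``, and ``len(peptides) == len(cleaved_bonds) + 1``.
    """

    parent: Parent
    cleaved_bonds: frozenset
    peptides: list
    treatment: str

    def released_sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]


def _split(parent: Parent, bonds: set[int], treatment: str) -> list[PeptideRecord]:
    seq = parent.sequence
    parent_id = parent.id if isinstance(parent, ProteinRecord) else parent.parent_id
    cuts = sorted(bonds)
    peptides = []
    start = 1
    for cut in cuts + [len(seq)]:
        peptides.append(
            PeptideRecord(
                sequence=seq[start - 1 : cut],
                parent_id=parent_id,
                span=(start, cut),
                treatment=treatment,
            )
        )
        start = cut + 1
    return peptides


def digest(
    protein: Parent,
    enzymes: Union[EnzymeSpec, Sequence[EnzymeSpec]],
    treatment: Optional[str] = None,
) -> DigestResult:
    """Simultaneous exhaustive digestion by one or more enzymes.

    The cleaved-bond set is the union over enzymes of
    :func:`find_cleavage_sites` on the intact substrate.
    """
    if isinstance(enzymes, EnzymeSpec):
        enzymes = [enzymes]
    enzymes = list(enzymes)
    if not enzymes:
        raise ValueError("digest requires at least one enzyme")
    if treatment is None:
        treatment = "+".join(e.name for e in enzymes)
    bonds = set()
    for enzyme in enzymes:
        bonds |= find_cleavage_sites(protein.sequence, enzyme)
    return DigestResult(
        parent=protein,
        cleaved_bonds=frozenset(bonds),
        peptides=_split(protein, bonds, treatment),
        treatment=treatment,
    )


def sequential_digest(
    protein: Parent,
    stage1: Sequence[EnzymeSpec],
    stage2: Sequence[EnzymeSpec],
    treatment: Optional[str] = None,
) -> DigestResult:
    """Two-stage digestion: stage-1 products are re-digested by stage 2.

    Each stage-2 enzyme sees the stage-1 *product* as its substrate, so a
    substrate-length cap (e.g. prolyl endopeptidase acting only on chains
    of at most 30 residues) applies to the product length.  Second-stage
    cut positions are composed back to parent coordinates.
    """
    if isinstance(stage1, EnzymeSpec):
        stage1 = [stage1]
    if isinstance(stage2, EnzymeSpec):
        stage2 = [stage2]
    if not stage1 or not stage2:
        raise ValueError("both stages need at least one enzyme")
    if treatment is None:
        treatment = (
            "+".join(e.name for e in stage1) + "->" + "+".join(e.name for e in stage2)
        )
    first = digest(protein, stage1, treatment=treatment)
    all_bonds = set(first.cleaved_bonds)
    peptides = []
    for product in first.peptides:
        sub_bonds = set()
        for enzyme in stage2:
            sub_bonds |= find_cleavage_sites(product.sequence, enzyme)
        offset = product.span[0] - 1  # parent position of product residue 1, minus 1
        all_bonds |= {offset + b for b in sub_bonds}
        for frag in _split(product, sub_bonds, treatment):
            start = offset + frag.span[0]
            end = offset + frag.span[1]
            peptides.append(
                PeptideRecord(
                    sequence=frag.sequence,
                    parent_id=product.parent_id,
                    span=(start, end),
                    treatment=treatment,
                )
            )
    return DigestResult(
        parent=protein,
        cleaved_bonds=frozenset(all_bonds),
        peptides=peptides,
        treatment=treatment,
    )


def degree_of_hydrolysis(result: DigestResult) -> float:
    """Percentage of the parent's peptide bonds cleaved by the treatment."""
    L = len(result.parent.sequence)
    if L < 2:
        raise ValueError("degree of hydrolysis undefined for a single residue")
    return 100.0 * len(result.cleaved_bonds) / (L - 1)


def occurrence_count(protein: Parent, reference: Iterable[str]) -> int:
    """Occurrences of reference sequences as substrings (overlaps counted)."""
    seq = protein.sequence
    total = 0
    for ref in set(reference):
        if not ref:
            raise ValueError("reference peptides must be non-empty")
        start = 0
        while True:
            idx = seq.find(ref, start)
            if idx < 0:
                break
            total += 1
            start = idx + 1
    return total


def release_frequency_AE(
    released: Iterable[PeptideRecord], reference: Iterable[str], protein_length: int
) -> float:
    """Released bioactive peptides (with multiplicity) per parent residue."""
    if protein_length < 1:
        raise ValueError("protein_length must be positive")
    ref = set(reference)
    hits = sum(1 for p in released if p.sequence in ref)
    return hits / protein_length


def relative_frequency_W(
    released: Iterable[PeptideRecord], reference: Iterable[str], protein: Parent
) -> float:
    """Released bioactive peptides / bioactive occurrences in the parent."""
    ref = set(reference)
    denom = occurrence_count(protein, ref)
    if denom == 0:
        raise ValueError(
            "relative frequency W undefined: no reference peptide occurs in "
            f"the parent sequence ({protein.sequence[:20]}...)"
        )
    hits = sum(1 for p in released if p.sequence in ref)
    return hits / denom


def merge_unique(peptide_sets: Iterable[Iterable[PeptideRecord]]) -> list[PeptideRecord]:
    """Merge peptides from several treatments into one record per sequence.

    The contributing treatment labels are recorded (sorted, ``,``-joined)
    and the result is ordered by sequence.
    """
    merged: dict[str, set] = {}
    origin: dict[str, PeptideRecord] = {}
    for peptides in peptide_sets:
        for p in peptides:
            labels = merged.setdefault(p.sequence, set())
            if p.treatment is not None:
                labels.add(p.treatment)
            origin.setdefault(p.sequence, p)
    out = []
    for seq in sorted(merged):
        proto = origin[seq]
        out.append(
            PeptideRecord(
                sequence=seq,
                parent_id=proto.parent_id,
                span=None,
                treatment=",".join(sorted(merged[seq])) or None,
                annotations=dict(proto.annotations),
            )
        )
    return out
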
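"""ACE-inhibitory activity annotation.

Di- and tripeptides are labelled by exact lookup in a reference table of
known ACE inhibitors with pIC50 values.  Tetra- to hexapeptides are scored
by a pluggable predictor and labelled active when the score strictly
exceeds a threshold (default 0.0).  Trained external classifiers are not
reimplemented here: the package ships (a) a file-backed scorer that reads
sequence -> score tables exported from such services and (b) a small,
clearly-labelled heuristic baseline so the cascade runs end-to-end in
tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Optional

import pandas as pd

from .io import PeptideRecord, validate_sequence

ACTIVITY_THRESHOLD = 0.0  # scores strictly above this are called active


@dataclass(frozen=True)
class ReferencePeptide:
    sequence: str
    pic50: float
    source: str = ""

    @property
    def flagged(self) -> bool:
        """True for entries outside the di-/tripeptide lookup range."""
        return not (2 <= len(self.sequence) <= 3)


@dataclass(frozen=True)
class ActivityAnnotation:
    is_active: bool
    method: Optional[str] = None  # "lookup" | "predicted" | None
    score: Optional[float] = None  # table pIC50 or predictor score
    threshold_used: Optional[float] = None


def load_reference_table(path=None) -> dict[str, ReferencePeptide]:
    """Load a reference table TSV (columns: sequence, pic50, source).

    With no argument, loads the packaged fixture table.
    """
    if path is None:
        with resources.as_file(
            resources.files("pepmine").joinpath(
                "data/reference/ace_reference_peptides.tsv"
            )
        ) as p:
            return load_reference_table(p)
    df = pd.read_csv(path, sep="\t", comment="#")
    table = {}
    for _, row in df.iterrows():
        seq = str(row["sequence"]).upper()
        validate_sequence(seq, context="reference peptide")
        table[seq] = ReferencePeptide(
            sequence=seq,
            pic50=float(row["pic50"]),
            source=str(row.get("source", "")),
        )
    return table


def load_known_aht(path=None) -> set[str]:
    """Known antihypertensive sequences (single 'sequence' column TSV)."""
    if path is None:
        with resources.as_file(
            resources.files("pepmine").joinpath("data/reference/known_aht_peptides.tsv")
        ) as p:
            return load_known_aht(p)
    df = pd.read_csv(path, sep="\t", comment="#")
    return {str(s).upper() for s in df["sequence"]}


def match_known(
    peptides: Iterable[PeptideRecord], table: dict[str, ReferencePeptide]
) -> list[PeptideRecord]:
    """Annotate di-/tripeptides found in the reference table as active.

    Lookup is case-normalised and exact-length; peptides absent from the
    table (or outside length 2-3) are left inactive at this step.
    """
    out = []
    for p in peptides:
        seq = p.sequence.upper()
        hit = table.get(seq) if 2 <= len(seq) <= 3 else None
        ann = (
            ActivityAnnotation(True, method="lookup", score=hit.pic50)
            if hit is not None
            else ActivityAnnotation(False)
        )
        out.append(_with_annotation(p, ann))
    return out


class FileBackedScorer:
    """Scores read from a sequence -> score TSV (external predictor output)."""

    def __init__(self, path_or_mapping):
        if isinstance(path_or_mapping, dict):
            self._scores = {k.upper(): float(v) for k, v in path_or_mapping.items()}
        else:
            df = pd.read_csv(Path(path_or_mapping), sep="\t", comment="#")
            self._scores = {
                str(row["sequence"]).upper(): float(row["score"])
                for _, row in df.iterrows()
            }

    def __call__(self, sequence: str) -> float:
        try:
            return self._scores[sequence.upper()]
        except KeyError:
            raise KeyError(
                f"scorer has no score for peptide {sequence!r}; "
                "add it to the score table"
            )


#: Heuristic baseline weights: composition evidence for ACE inhibition.
#: C-terminal aromatic/proline and hydrophobic bulk score positive,
#: acidic composition scores negative.  This is a documented stand-in for
#: external trained predictors, usable for testing and demonstration only.
_BASELINE_CTERM = {
    "P": 0.6, "W": 0.6, "Y": 0.6, "F": 0.6, "K": 0.3, "R": 0.3,
}
_BASELINE_COMPOSITION = {
    "I": 0.3, "L": 0.3, "V": 0.3, "F": 0.3, "W": 0.3, "Y": 0.3,
    "P": 0.3, "A": 0.1, "M": 0.1, "D": -0.3, "E": -0.3,
}


def baseline_scorer(sequence: str) -> float:
    """Composition-feature heuristic score (NOT a trained model)."""
    seq = sequence.upper()
    comp = sum(_BASELINE_COMPOSITION.get(r, 0.0) for r in seq) / len(seq)
    return _BASELINE_CTERM.get(seq[-1], -0.1) + comp


def predict_activity(
    peptide: PeptideRecord,
    scorer: Callable[[str], float],
    threshold: float = ACTIVITY_THRESHOLD,
) -> ActivityAnnotation:
    """Predict activity for a tetra- to hexapeptide: active iff score > threshold."""
    if not 4 <= len(peptide.sequence) <= 6:
        raise ValueError(
            f"activity prediction applies to peptides of length 4-6, "
            f"got {peptide.sequence!r} (length {len(peptide.sequence)})"
        )
    score = float(scorer(peptide.sequence))
    return ActivityAnnotation(
        is_active=score > threshold,
        method="predicted",
        score=score,
        threshold_used=threshold,
    )


def annotate_peptides(
    peptides: Iterable[PeptideRecord],
    table: dict[str, ReferencePeptide],
    scorer: Optional[Callable[[str], float]] = None,
    threshold: float = ACTIVITY_THRESHOLD,
) -> list[PeptideRecord]:
    """Annotate a mixed pool: lookup for lengths 2-3, prediction for 4-6.

    Peptides of other lengths are annotated inactive (single residues are
    not peptides; longer chains are outside the screening scope).
    """
    out = []
    for p in peptides:
        n = len(p.sequence)
        if 2 <= n <= 3:
            out.extend(match_known([p], table))
        elif 4 <= n <= 6 and scorer is not None:
            out.append(_with_annotation(p, predict_activity(p, scorer, threshold)))
        else:
            out.append(_with_annotation(p, ActivityAnnotation(False)))
    return out


def _with_annotation(p: PeptideRecord, ann: ActivityAnnotation) -> PeptideRecord:
    annotations = dict(p.annotations)
    annotations["active"] = ann.is_active
    if ann.method is not None:
        annotations["activity_method"] = ann.method
    if ann.score is not None:
        annotations["activity_score"] = ann.score
    if ann.threshold_used is not None:
        annotations["activity_threshold"] = ann.threshold_used
    return PeptideRecord(
        sequence=p.sequence,
        parent_id=p.parent_id,
        span=p.span,
        treatment=p.treatment,
        annotations=annotations,
    )


def classify_novel(
    peptides: Iterable[PeptideRecord], known_reference: set[str]
) -> tuple[list[PeptideRecord], list[PeptideRecord]]:
    """Partition peptides into (known, novel) by exact sequence membership."""
    known_reference = {s.upper() for s in known_reference}
    known, novel = [], []
    for p in peptides:
        (known if p.sequence.upper() in known_reference else novel).append(p)
    known.sort(key=lambda p: p.sequence)
    novel.sort(key=lambda p: p.sequence)
    return known, novel
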
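"""Multi-stage screening cascade for candidate bioactive peptides.

Stage order: gastrointestinal stability (with fragment re-entry) ->
allergenicity -> toxicity -> rule-of-5 permeability, followed by a
known/novel partition of the survivors.

The gastrointestinal stage simulates exhaustive digestion by pepsin
(pH 1.3), trypsin and chymotrypsin (high-specificity): peptides with zero
predicted cleavage sites are stable; the others are cut and their distinct
fragments of length >= 2 re-enter the pool (with provenance recorded),
since a digestion product may itself be the in-vivo active species.

Allergen and toxin calls come from trained external classifiers, which are
deliberately not reimplemented: predicates are file-backed verdict tables
(or an explicit constant-pass mode for testing).  A queried sequence with
no verdict is an error, never a silent pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import pandas as pd

from . import activity as _activity
from .digest import digest, find_cleavage_sites
from .enzymes import GI_ENZYMES, EnzymeSpec, get_enzyme
from .io import PeptideRecord
from .physchem import LogPBackend, compute_profile, rule_of_five


class PredicateError(KeyError):
    """A predicate has no verdict for a queried sequence."""


@dataclass
class PredicateModel:
    """Allergen or toxin predicate over peptide sequences.

    ``verdicts`` maps sequence -> bool where True means *flagged*
    (allergen/toxic, i.e. the peptide fails the stage).  ``constant``
    predicates return the same verdict for every sequence and are meant for
    testing and for the documented all-pass mode.
    """

    name: str
    kind: str  # "allergen" | "toxin"
    verdicts: Optional[dict] = None
    constant: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.kind not in ("allergen", "toxin"):
            raise ValueError(f"kind must be allergen or toxin, got {self.kind!r}")
        if (self.verdicts is None) == (self.constant is None):
            raise ValueError("provide exactly one of verdicts or constant")

    def flagged(self, sequence: str) -> bool:
        if self.constant is not None:
            return self.constant
        try:
            return self.verdicts[sequence.upper()]
        except KeyError:
            raise PredicateError(
                f"{self.kind} predicate {self.name!r} has no verdict for "
                f"peptide {sequence!r}"
            )


def constant_pass(kind: str, name: str = "constant-pass") -> PredicateModel:
    return PredicateModel(name=name, kind=kind, constant=False)


_YES = {"yes", "y", "true", "1", "allergen", "toxin", "toxic"}
_NO = {"no", "n", "false", "0", "non-allergen", "non-toxin", "non-toxic"}


def load_predicate(path, kind: str, name: Optional[str] = None) -> PredicateModel:
    """Load a verdict TSV with columns ``sequence`` and ``verdict``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    verdicts = {}
    for _, row in df.iterrows():
        token = str(row["verdict"]).strip().lower()
        if token in _YES:
            flag = True
        elif token in _NO:
            flag = False
        else:
            raise ValueError(f"{path.name}: unrecognised verdict {token!r}")
        verdicts[str(row["sequence"]).upper()] = flag
    return PredicateModel(name=name or path.stem, kind=kind, verdicts=verdicts)


def default_gi_enzymes() -> list[EnzymeSpec]:
    return [get_enzyme(name) for name in GI_ENZYMES]


def gi_cleavage_sites(sequence: str, enzymes: Sequence[EnzymeSpec]) -> set[int]:
    sites = set()
    for enzyme in enzymes:
        sites |= find_cleavage_sites(sequence, enzyme)
    return sites


def gi_stability_stage(
    peptides: Iterable[PeptideRecord],
    enzymes: Optional[Sequence[EnzymeSpec]] = None,
) -> tuple[list[PeptideRecord], list[PeptideRecord]]:
    """Split a pool into (stable peptides, distinct new fragments).

    Stable peptides have zero predicted cleavage sites.  Unstable peptides
    are exhaustively digested; their fragments of length >= 2 are merged by
    sequence (first-seen provenance kept), and fragments whose sequence
    duplicates a stable peptide or an earlier fragment are dropped.

    Digestion is iterated: a fragment that is itself still cleavable (this
    can happen when a specificity *exception* loses its context at a newly
    created terminus, e.g. trypsin's Arg-Arg-His window) is digested again,
    so every emitted fragment is a fixpoint of gastrointestinal digestion.
    """
    if enzymes is None:
        enzymes = default_gi_enzymes()
    enzymes = list(enzymes)
    stable: list[PeptideRecord] = []
    fragments: list[PeptideRecord] = []
    seen_stable: set[str] = set()
    seen_frag: set[str] = set()
    pool = list(peptides)
    queue: list[tuple] = []  # (record, origin sequence)
    for p in pool:
        if not gi_cleavage_sites(p.sequence, enzymes):
            stable.append(p)
            seen_stable.add(p.sequence)
        else:
            queue.append((p, p.sequence))
    while queue:
        p, origin = queue.pop(0)
        result = digest(p, enzymes, treatment="gi")
        for frag in result.peptides:
            seq = frag.sequence
            if len(seq) < 2 or seq in seen_stable or seq in seen_frag:
                continue
            annotations = dict(p.annotations)
            annotations["gi_origin"] = origin
            record = PeptideRecord(
                sequence=seq,
                parent_id=p.parent_id,
                span=None,
                treatment=p.treatment,
                annotations=annotations,
            )
            if gi_cleavage_sites(seq, enzymes):
                queue.append((record, origin))
            else:
                seen_frag.add(seq)
                fragments.append(record)
    return stable, fragments


@dataclass
class StageCount:
    name: str
    n_in: int
    n_pass: int
    n_fail: int
    fail_reasons: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


@dataclass
class CascadeReport:
    """Per-stage bookkeeping plus the final survivor lists."""

    stages: list
    survivors: list
    known: list
    novel: list

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "input": s.n_in,
                    "pass": s.n_pass,
                    "fail": s.n_fail,
                    "fail_reasons": s.fail_reasons,
                    **s.extra,
                }
                for s in self.stages
            ],
            "final": {
                "survivors": sorted(p.sequence for p in self.survivors),
                "known": sorted(p.sequence for p in self.known),
                "novel": sorted(p.sequence for p in self.novel),
                "n_known": len(self.known),
                "n_novel": len(self.novel),
            },
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def run_cascade(
    peptides: Iterable[PeptideRecord],
    allergen: PredicateModel,
    toxin: PredicateModel,
    known_reference: Optional[set] = None,
    gi_enzymes: Optional[Sequence[EnzymeSpec]] = None,
    logp_backend: LogPBackend = "additive",
    skip_gi: bool = False,
) -> CascadeReport:
    """Run the full cascade and return a report with per-stage counts.

    ``input = pass + fail`` holds at every stage; the GI stage additionally
    reports the number of distinct new fragments it adds to the pool.
    """
    pool = list(peptides)
    stages: list[StageCount] = []

    if not skip_gi:
        stable, fragments = gi_stability_stage(pool, enzymes=gi_enzymes)
        stages.append(
            StageCount(
                name="gi_stability",
                n_in=len(pool),
                n_pass=len(stable),
                n_fail=len(pool) - len(stable),
                extra={"new_fragments": len(fragments)},
            )
        )
        pool = stable + fragments

    for predicate in (allergen, toxin):
        passed, reasons = [], {}
        for p in pool:
            if predicate.flagged(p.sequence):
                reasons[p.sequence] = f"predicted {predicate.kind}"
            else:
                passed.append(p)
        stages.append(
            StageCount(
                name=predicate.kind,
                n_in=len(pool),
                n_pass=len(passed),
                n_fail=len(pool) - len(passed),
                fail_reasons=reasons,
            )
        )
        pool = passed

    passed, reasons = [], {}
    for p in pool:
        profile = compute_profile(p.sequence, logp_backend=logp_backend)
        ok, violations = rule_of_five(profile)
        if ok:
            passed.append(p)
        else:
            reasons[p.sequence] = "; ".join(violations)
    stages.append(
        StageCount(
            name="permeability",
            n_in=len(pool),
            n_pass=len(passed),
            n_fail=len(pool) - len(passed),
            fail_reasons=reasons,
        )
    )
    pool = passed

    if known_reference is None:
        known_reference = _activity.load_known_aht()
    known, novel = _activity.classify_novel(pool, known_reference)
    return CascadeReport(stages=stages, survivors=pool, known=known, novel=novel)
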
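"""Sequence-derived physicochemical properties and the rule-of-5 filter.

All properties are pure functions of the peptide sequence; the per-residue
contribution table ships as a versioned data file
(``pepmine/data/physchem/residue_properties.tsv``).

Counting conventions
--------------------

Hydrogen-bond *donors* are N/O atoms bearing at least one hydrogen (atom
counting, not N-H/O-H hydrogen counting), evaluated on the zwitterionic
form the peptide adopts at neutral pH: the N-terminal ammonium nitrogen
counts, every non-proline backbone amide N-H counts, side-chain N-H/O-H
atoms count per the residue table, and the C-terminal carboxylate
contributes no donor.  Hydrogen-bond *acceptors* are N and O atoms
excluding amide nitrogens (backbone and side-chain amides): the N-terminal
amine nitrogen, one backbone carbonyl oxygen per non-terminal residue, the
two carboxylate oxygens, and side-chain N/O per the table.

These are the conventions under which every peptide of the screening
cascade's final survivor set clears the rule-of-5 thresholds; atom counting
on the fully neutral species (carboxylic acid O-H as a donor, hydrogen
counting on guanidinium) would spuriously reject proline- and
arginine-containing survivors.  See ``docs/methods.md``.

Molecular weight is the sum of average residue masses plus one water
(18.0153 Da).  logP defaults to an additive scheme: a chain term linear in
length plus side-chain increments, both derived once from the
Wildman-Crippen atomic model on glycine model peptides; an atom-level RDKit
backend ("crippen") and arbitrary callables can substitute.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Callable, Union

from .io import validate_sequence

WATER_MASS = 18.0153

#: additive logP chain terms: logp = _LOGP_BASE + _LOGP_PER_BOND*(L-1) + side chains
_LOGP_BASE = -0.9703
_LOGP_PER_BOND = -0.8838


@lru_cache(maxsize=1)
def residue_properties() -> dict:
    """Parse the packaged residue table -> {residue: {column: value}}."""
    text = (
        resources.files("pepmine")
        .joinpath("data/physchem/residue_properties.tsv")
        .read_text()
    )
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    header = lines[0].split("\t")
    table = {}
    for line in lines[1:]:
        fields = dict(zip(header, line.split("\t")))
        table[fields["residue"]] = {
            "avg_mass": float(fields["avg_mass"]),
            "sc_donors": int(fields["sc_donors"]),
            "sc_acceptors": int(fields["sc_acceptors"]),
            "logp_sc": float(fields["logp_sc"]),
        }
    return table


def molecular_weight(sequence: str) -> float:
    """Average molecular mass of the neutral linear peptide, Da."""
    validate_sequence(sequence)
    table = residue_properties()
    return sum(table[r]["avg_mass"] for r in sequence) + WATER_MASS


def hbond_donors(sequence: str) -> int:
    """Donor atoms (N/O with >=1 H) in the zwitterionic linear peptide."""
    validate_sequence(sequence)
    table = residue_properties()
    count = 1  # N-terminal (protonated) amine nitrogen
    count += sum(1 for r in sequence[1:] if r != "P")  # backbone amide N-H
    count += sum(table[r]["sc_donors"] for r in sequence)
    return count


def hbond_acceptors(sequence: str) -> int:
    """Acceptor atoms (N/O excluding amide nitrogens) in the linear peptide."""
    validate_sequence(sequence)
    table = residue_properties()
    count = 1  # N-terminal amine nitrogen
    count += len(sequence) - 1  # backbone carbonyl oxygens
    count += 2  # C-terminal carboxylate oxygens
    count += sum(table[r]["sc_acceptors"] for r in sequence)
    return count


def _logp_additive(sequence: str) -> float:
    table = residue_properties()
    return (
        _LOGP_BASE
        + _LOGP_PER_BOND * (len(sequence) - 1)
        + sum(table[r]["logp_sc"] for r in sequence)
    )


def _logp_crippen(sequence: str) -> float:
    from rdkit import Chem
    from rdkit.Chem import Crippen

    mol = Chem.MolFromSequence(sequence)
    if mol is None:
        raise ValueError(f"RDKit could not build peptide {sequence!r}")
    return Crippen.MolLogP(mol)


LogPBackend = Union[str, Callable[[str], float]]

_LOGP_BACKENDS = {"additive": _logp_additive, "crippen": _logp_crippen}


def logp(sequence: str, backend: LogPBackend = "additive") -> float:
    """Estimated octanol-water partition coefficient of the peptide.

    ``backend`` is ``"additive"`` (default, packaged residue-increment
    table), ``"crippen"`` (RDKit Wildman-Crippen on the built molecule), or
    any callable mapping a sequence to a value, e.g. a reader of values
    exported from an external atom-level calculator.
    """
    validate_sequence(sequence)
    fn = _LOGP_BACKENDS.get(backend, backend) if isinstance(backend, str) else backend
    if not callable(fn):
        raise ValueError(f"unknown logP backend {backend!r}")
    return fn(sequence)


@dataclass(frozen=True)
class PhysChemProfile:
    """Rule-of-5 inputs for one peptide."""

    sequence: str
    mw: float
    hbd: int
    hba: int
    logp: float


def compute_profile(sequence: str, logp_backend: LogPBackend = "additive") -> PhysChemProfile:
    return PhysChemProfile(
        sequence=sequence,
        mw=molecular_weight(sequence),
        hbd=hbond_donors(sequence),
        hba=hbond_acceptors(sequence),
        logp=logp(sequence, backend=logp_backend),
    )


#: rule-of-5 thresholds (violated on strict inequality)
RO5_LIMITS = {"hbd": 5, "hba": 10, "mw": 500.0, "logp": 5.0}


def rule_of_five(profile: PhysChemProfile) -> tuple[bool, list[str]]:
    """Permeability verdict: pass iff zero violations (strict '>' thresholds)."""
    violations = []
    if profile.hbd > RO5_LIMITS["hbd"]:
        violations.append(f"hbd {profile.hbd} > {RO5_LIMITS['hbd']}")
    if profile.hba > RO5_LIMITS["hba"]:
        violations.append(f"hba {profile.hba} > {RO5_LIMITS['hba']}")
    if profile.mw > RO5_LIMITS["mw"]:
        violations.append(f"mw {profile.mw:.1f} > {RO5_LIMITS['mw']:.0f}")
    if profile.logp > RO5_LIMITS["logp"]:
        violations.append(f"logp {profile.logp:.2f} > {RO5_LIMITS['logp']:.0f}")
    return (not violations, violations)
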
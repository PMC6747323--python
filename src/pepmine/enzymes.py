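"""Declarative protease specificity rules.

A cleavage rule is a :class:`SubsitePattern`: a constraint on the residues
occupying the subsites P4..P2' around a candidate scissile bond (Schechter &
Berger numbering).  For bond ``i`` (joining residues ``i`` and ``i+1``,
1-based) the subsites map to residue positions::

    P4 -> i-3   P3 -> i-2   P2 -> i-1   P1 -> i   P1' -> i+1   P2' -> i+2

A constrained subsite whose position falls outside the sequence does NOT
match (web-server convention: the lookaround context must exist); an
unconstrained (wildcard) subsite always matches.

An :class:`EnzymeSpec` is a set of accept rules plus global block (exception)
patterns, and an optional maximum substrate length.  The block mechanism
encodes exceptions such as prolyl endopeptidase being inactive on Pro-Pro
contexts; the substrate cap encodes its inability to act on chains longer
than 30 residues.

Rule tables ship as editable text files under ``pepmine/data/enzymes`` so a
particular database snapshot can be matched by editing data, not code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional

from .io import AMINO_ACIDS

#: subsite name -> offset relative to the P1 residue (1-based residue i)
SUBSITE_OFFSETS = {"P4": -3, "P3": -2, "P2": -1, "P1": 0, "P1'": 1, "P2'": 2}

_ALL = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class SubsitePattern:
    """Allowed-residue sets per subsite; unlisted subsites are wildcards."""

    subsites: tuple  # tuple of (subsite name, frozenset of allowed residues)

    def __post_init__(self) -> None:
        if not self.subsites:
            raise ValueError("pattern must constrain at least one subsite")
        for name, allowed in self.subsites:
            if name not in SUBSITE_OFFSETS:
                raise ValueError(f"unknown subsite {name!r}")
            if not allowed:
                raise ValueError(f"empty residue set at {name}")

    def matches(self, seq: str, bond: int) -> bool:
        """True if the window around ``bond`` satisfies every constraint."""
        L = len(seq)
        for name, allowed in self.subsites:
            pos = bond + SUBSITE_OFFSETS[name]  # 1-based residue position
            if pos < 1 or pos > L:
                return False  # constrained subsite outside the sequence
            if seq[pos - 1] not in allowed:
                return False
        return True


def pattern(**subsites: str) -> SubsitePattern:
    """Build a pattern from keyword constraints.

    Values are residue strings; a leading ``^`` complements against the
    20-letter alphabet.  Subsite names use ``p1p`` / ``p2p`` for P1'/P2'.

    >>> pattern(p1="KR", p1p="^P")          # trypsin-like
    """
    alias = {"p4": "P4", "p3": "P3", "p2": "P2", "p1": "P1",
             "p1p": "P1'", "p2p": "P2'"}
    items = []
    for key, value in subsites.items():
        items.append((alias[key.lower()], _parse_residue_set(value)))
    return SubsitePattern(subsites=tuple(items))


def _parse_residue_set(token: str) -> frozenset:
    token = token.strip().upper()
    if token.startswith("^"):
        residues = frozenset(token[1:])
        bad = residues - _ALL
        if bad:
            raise ValueError(f"unknown residues {sorted(bad)} in {token!r}")
        return _ALL - residues
    residues = frozenset(token)
    bad = residues - _ALL
    if bad:
        raise ValueError(f"unknown residues {sorted(bad)} in {token!r}")
    return residues


@dataclass(frozen=True)
class EnzymeSpec:
    """A protease: accept rules, global block patterns, substrate cap."""

    name: str
    ec_number: str = ""
    rules: tuple = ()
    global_blocks: tuple = ()
    substrate_max_len: Optional[int] = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError(f"enzyme {self.name!r} has no rules")
        if self.substrate_max_len is not None and self.substrate_max_len < 2:
            raise ValueError("substrate_max_len must be >= 2")


_TOKEN_RE = re.compile(r"(P[1-4]'?)\s*=\s*(\^?[A-Za-z]+)")


def _parse_pattern_line(body: str) -> SubsitePattern:
    items = []
    for name, token in _TOKEN_RE.findall(body):
        items.append((name, _parse_residue_set(token)))
    if not items:
        raise ValueError(f"no subsite constraints in {body!r}")
    return SubsitePattern(subsites=tuple(items))


def load_enzyme(path) -> EnzymeSpec:
    """Parse one ``.rules`` file into an :class:`EnzymeSpec`.

    Format (``#`` comments allowed)::

        name: trypsin
        ec: 3.4.21.4
        substrate_max_len: 30        # optional
        rule: P1=KR P1'=^P
        block: P2=CD P1=K P1'=D
    """
    path = Path(path)
    meta = {"name": None, "ec": "", "substrate_max_len": None}
    rules, blocks, provenance = [], [], []
    for raw in path.read_text().splitlines():
        if raw.strip().startswith("#"):
            provenance.append(raw.strip("# ").strip())
            continue
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, body = line.partition(":")
        key = key.strip().lower()
        body = body.strip()
        if key == "name":
            meta["name"] = body
        elif key == "ec":
            meta["ec"] = body
        elif key == "substrate_max_len":
            meta["substrate_max_len"] = int(body)
        elif key == "rule":
            rules.append(_parse_pattern_line(body))
        elif key == "block":
            blocks.append(_parse_pattern_line(body))
        else:
            raise ValueError(f"{path.name}: unknown directive {key!r}")
    if meta["name"] is None:
        raise ValueError(f"{path.name}: missing 'name:'")
    return EnzymeSpec(
        name=meta["name"],
        ec_number=meta["ec"],
        rules=tuple(rules),
        global_blocks=tuple(blocks),
        substrate_max_len=meta["substrate_max_len"],
        source=" ".join(provenance),
    )


@lru_cache(maxsize=1)
def load_registry() -> dict:
    """Load every packaged ``.rules`` file, keyed by enzyme name."""
    registry = {}
    root = resources.files("pepmine").joinpath("data/enzymes")
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".rules"):
            with resources.as_file(entry) as p:
                spec = load_enzyme(p)
            if spec.name in registry:
                raise ValueError(f"duplicate enzyme name {spec.name!r}")
            registry[spec.name] = spec
    return registry


def get_enzyme(name: str) -> EnzymeSpec:
    registry = load_registry()
    try:
        return registry[name]
    except KeyError:
        known = ", ".join(sorted(registry))
        raise KeyError(f"unknown enzyme {name!r}; packaged enzymes: {known}")


#: default enzyme names for the gastrointestinal-stability stage
GI_ENZYMES = ("pepsin_ph1.3", "trypsin", "chymotrypsin_high")
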
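"""Digestion engine: paper-style cleavage semantics plus oracle equivalence.

The independent oracle builds a regular expression with fixed-width
lookbehind/lookahead from each subsite pattern and scans the sequence with
``re`` — a completely separate code path from the engine's window
arithmetic.
"""

import random
import re

import pytest
from hypothesis import given
from hypothesis import strategies as st

import pepmine as pm
from pepmine.digest import find_cleavage_sites
from pepmine.enzymes import SUBSITE_OFFSETS

# ---------------------------------------------------------------------------
# independent regex oracle

_ORDER = ["P4", "P3", "P2", "P1", "P1'", "P2'"]


def _pattern_regex(pattern):
    constraints = dict(pattern.subsites)
    n_side = [name for name in ("P4", "P3", "P2", "P1") if name in constraints]
    c_side = [name for name in ("P1'", "P2'") if name in constraints]
    look_b = ""
    if n_side:
        outer = min(SUBSITE_OFFSETS[n] for n in n_side)  # most negative
        parts = []
        for off in range(outer, 1):
            name = next(k for k, v in SUBSITE_OFFSETS.items() if v == off)
            allowed = constraints.get(name)
            parts.append(
                "[" + "".join(sorted(allowed)) + "]" if allowed else "[A-Z]"
            )
        look_b = "(?<=" + "".join(parts) + ")"
    look_a = ""
    if c_side:
        outer = max(SUBSITE_OFFSETS[n] for n in c_side)
        parts = []
        for off in range(1, outer + 1):
            name = next(k for k, v in SUBSITE_OFFSETS.items() if v == off)
            allowed = constraints.get(name)
            parts.append(
                "[" + "".join(sorted(allowed)) + "]" if allowed else "[A-Z]"
            )
        look_a = "(?=" + "".join(parts) + ")"
    return re.compile(look_b + look_a)


def oracle_sites(seq, enzyme):
    if enzyme.substrate_max_len is not None and len(seq) > enzyme.substrate_max_len:
        return set()
    sites = set()
    for rule in enzyme.rules:
        rx = _pattern_regex(rule)
        sites |= {m.start() for m in rx.finditer(seq)}
    for blk in enzyme.global_blocks:
        rx = _pattern_regex(blk)
        sites -= {m.start() for m in rx.finditer(seq)}
    return {s for s in sites if 0 < s < len(seq)}


def random_enzyme(rng: random.Random) -> pm.EnzymeSpec:
    def random_pattern():
        names = rng.sample(_ORDER, k=rng.randint(1, 3))
        return pm.SubsitePattern(
            subsites=tuple(
                (n, frozenset(rng.sample(pm.AMINO_ACIDS, k=rng.randint(1, 8))))
                for n in names
            )
        )

    return pm.EnzymeSpec(
        name="toy",
        rules=tuple(random_pattern() for _ in range(rng.randint(1, 3))),
        global_blocks=tuple(random_pattern() for _ in range(rng.randint(0, 2))),
        substrate_max_len=rng.choice([None, None, 10, 30]),
    )


def test_engine_matches_regex_oracle_on_random_rule_sets():
    rng = random.Random(1234)
    for _ in range(300):
        enzyme = random_enzyme(rng)
        for _ in range(5):
            seq = "".join(
                rng.choice(pm.AMINO_ACIDS) for _ in range(rng.randint(1, 60))
            )
            assert find_cleavage_sites(seq, enzyme) == oracle_sites(seq, enzyme)


def test_engine_matches_expasy_oracle_for_gi_enzymes(gi_enzymes):
    """Packaged pepsin/trypsin/chymotrypsin tables reproduce the published
    PeptideCutter regular expressions (pyteomics)."""
    from pyteomics.parser import expasy_rules

    rules = {
        "pepsin_ph1.3": (expasy_rules["pepsin ph1.3"], None),
        "trypsin": (expasy_rules["trypsin"], expasy_rules["trypsin_exception"]),
        "chymotrypsin_high": (expasy_rules["chymotrypsin high specificity"], None),
    }
    rng = random.Random(99)
    for enzyme in gi_enzymes:
        rx, exc = rules[enzyme.name]
        for _ in range(400):
            seq = "".join(
                rng.choice(pm.AMINO_ACIDS) for _ in range(rng.randint(2, 50))
            )
            expected = {m.end() for m in re.finditer(rx, seq)}
            if exc:
                expected -= {m.end() for m in re.finditer(exc, seq)}
            expected = {s for s in expected if 0 < s < len(seq)}
            assert find_cleavage_sites(seq, enzyme) == expected, (enzyme.name, seq)


# ---------------------------------------------------------------------------
# prolyl endopeptidase semantics


def test_prep_cleaves_after_proline(prep):
    assert find_cleavage_sites("GPGPG", prep) == {2, 4}


def test_prep_blocked_on_pro_pro_contexts(prep):
    # P at P1' blocks bond 2; P-P at P2-P1 blocks bond 3
    assert find_cleavage_sites("NPPK", prep) == set()
    # C-terminal Pro-Pro products survive intact
    assert find_cleavage_sites("AEMPP", prep) == set()


def test_prep_substrate_length_cap(prep):
    seq = ("GP" * 16)[:31]  # 31 residues, Pro-rich
    assert find_cleavage_sites(seq, prep) == set()
    assert find_cleavage_sites(seq[:30], prep) != set()


def test_prep_never_cuts_pro_pro_property(prep):
    rng = random.Random(7)
    for _ in range(500):
        seq = "".join(rng.choice("GPAKL") for _ in range(rng.randint(2, 30)))
        for bond in find_cleavage_sites(seq, prep):
            assert seq[bond - 1] == "P"
            assert seq[bond] != "P"  # P1' never Pro
            assert bond < 2 or seq[bond - 2] != "P"  # P2 never Pro


# ---------------------------------------------------------------------------
# digestion, tiling, statistics


def test_digest_splits_at_sites(toy_after_k):
    protein = pm.ProteinRecord(id="p", sequence="AKAKA")
    result = pm.digest(protein, toy_after_k)
    assert result.cleaved_bonds == {2, 4}
    assert [p.sequence for p in result.peptides] == ["AK", "AK", "A"]
    assert [p.span for p in result.peptides] == [(1, 2), (3, 4), (5, 5)]


def test_digest_without_matches_returns_whole_sequence(toy_after_k):
    protein = pm.ProteinRecord(id="p", sequence="GGGG")
    result = pm.digest(protein, toy_after_k)
    assert [p.sequence for p in result.peptides] == ["GGGG"]


def test_digest_requires_an_enzyme():
    with pytest.raises(ValueError):
        pm.digest(pm.ProteinRecord(id="p", sequence="AK"), [])


def test_simultaneous_digestion_is_site_union(registry):
    rng = random.Random(42)
    papain, ficin = registry["papain"], registry["ficin"]
    for _ in range(200):
        seq = "".join(rng.choice(pm.AMINO_ACIDS) for _ in range(50))
        protein = pm.ProteinRecord(id="p", sequence=seq)
        both = pm.digest(protein, [papain, ficin]).cleaved_bonds
        assert both == (
            find_cleavage_sites(seq, papain) | find_cleavage_sites(seq, ficin)
        )


def test_sequential_digest_honours_substrate_cap(prep, toy_after_k):
    # stage-1 product of 35 residues passes through PREP uncleaved
    seq = "GP" * 17 + "K"  # 35 residues, then K
    protein = pm.ProteinRecord(id="p", sequence=seq + "GPGPK")
    result = pm.sequential_digest(protein, [toy_after_k], [prep])
    first_product = seq  # ends at the K, 35 residues
    assert first_product in [p.sequence for p in result.peptides]


def test_sequential_digest_composes_spans(prep, toy_after_k):
    protein = pm.ProteinRecord(id="p", sequence="GGKAPGPK")
    result = pm.sequential_digest(protein, [toy_after_k], [prep])
    assert [p.sequence for p in result.peptides] == ["GGK", "AP", "GP", "K"]
    assert [p.span for p in result.peptides] == [(1, 3), (4, 5), (6, 7), (8, 8)]
    for p in result.peptides:
        assert protein.sequence[p.span[0] - 1 : p.span[1]] == p.sequence
    # cleaved bonds are in parent coordinates
    assert result.cleaved_bonds == {3, 5, 7}


@given(seq=st.text(alphabet=pm.AMINO_ACIDS, min_size=1, max_size=60))
def test_tiling_invariant(seq):
    protein = pm.ProteinRecord(id="p", sequence=seq)
    trypsin = pm.get_enzyme("trypsin")
    prep = pm.get_enzyme("prep")
    for result in (
        pm.digest(protein, trypsin),
        pm.sequential_digest(protein, [trypsin], [prep]) if len(seq) > 1 else None,
    ):
        if result is None:
            continue
        assert "".join(p.sequence for p in result.peptides) == seq
        assert len(result.peptides) == len(result.cleaved_bonds) + 1


def test_exhaustive_digestion_fixpoint(registry):
    """Fragments of an exhaustive digest carry no remaining cleavage sites.

    This holds for any exception-free rule set because a fragment's local
    windows are sub-windows of the parent's (a specificity *exception*
    losing its context at a new terminus can re-enable a site; the
    gastrointestinal stage handles that case by iterating, tested in the
    cascade suite).
    """
    enzymes = [registry[n] for n in ("pepsin_ph1.3", "chymotrypsin_high",
                                     "papain", "ficin")]
    rng = random.Random(5)
    for _ in range(200):
        seq = "".join(rng.choice(pm.AMINO_ACIDS) for _ in range(rng.randint(2, 60)))
        protein = pm.ProteinRecord(id="p", sequence=seq)
        result = pm.digest(protein, enzymes)
        for frag in result.peptides:
            for enzyme in enzymes:
                assert find_cleavage_sites(frag.sequence, enzyme) == set()


def test_degree_of_hydrolysis_bounds_and_extremes():
    protein = pm.ProteinRecord(id="p", sequence="KKKK")
    every = pm.EnzymeSpec(name="all", rules=(pm.pattern(p1="K"),))
    assert pm.degree_of_hydrolysis(pm.digest(protein, every)) == 100.0
    never = pm.EnzymeSpec(name="none", rules=(pm.pattern(p1="W"),))
    assert pm.degree_of_hydrolysis(pm.digest(protein, never)) == 0.0
    with pytest.raises(ValueError):
        pm.degree_of_hydrolysis(pm.digest(pm.ProteinRecord(id="q", sequence="K"), every))


def test_adding_an_enzyme_never_decreases_dh(registry):
    rng = random.Random(11)
    papain, ficin = registry["papain"], registry["ficin"]
    for _ in range(100):
        seq = "".join(rng.choice(pm.AMINO_ACIDS) for _ in range(40))
        protein = pm.ProteinRecord(id="p", sequence=seq)
        dh_one = pm.degree_of_hydrolysis(pm.digest(protein, papain))
        dh_two = pm.degree_of_hydrolysis(pm.digest(protein, [papain, ficin]))
        assert 0.0 <= dh_one <= dh_two <= 100.0


def test_occurrence_count_overlapping():
    assert pm.occurrence_count(pm.ProteinRecord(id="p", sequence="AYAY"), {"AY"}) == 2
    assert pm.occurrence_count(pm.ProteinRecord(id="p", sequence="AAA"), {"AA"}) == 2
    assert (
        pm.occurrence_count(pm.ProteinRecord(id="p", sequence="AYAY"), {"AY", "YA"})
        == 3
    )


def test_release_frequency_examples():
    released = [pm.PeptideRecord(s) for s in ("AY", "AY", "G")]
    assert pm.release_frequency_AE(released, {"AY"}, 5) == pytest.approx(0.4)
    assert pm.release_frequency_AE(released, {"VF"}, 5) == 0.0


@given(
    seqs=st.lists(st.text(alphabet="AYGV", min_size=1, max_size=3), min_size=0, max_size=10),
    ref_small=st.sets(st.text(alphabet="AYGV", min_size=1, max_size=3), max_size=3),
    ref_extra=st.sets(st.text(alphabet="AYGV", min_size=1, max_size=3), max_size=3),
)
def test_release_frequency_monotone_in_reference(seqs, ref_small, ref_extra):
    released = [pm.PeptideRecord(s) for s in seqs]
    small = pm.release_frequency_AE(released, ref_small, 50)
    large = pm.release_frequency_AE(released, ref_small | ref_extra, 50)
    assert large >= small


def test_relative_frequency_w():
    protein = pm.ProteinRecord(id="p", sequence="AYAY")
    assert pm.relative_frequency_W([pm.PeptideRecord("AY")], {"AY"}, protein) == 0.5
    assert pm.relative_frequency_W([], {"AY"}, protein) == 0.0
    with pytest.raises(ValueError, match="no reference peptide occurs"):
        pm.relative_frequency_W([], {"VF"}, protein)


def test_merge_unique_dedupes_and_records_treatments():
    a = [pm.PeptideRecord("AY", treatment="papain")]
    b = [pm.PeptideRecord("AY", treatment="ficin"), pm.PeptideRecord("VF", treatment="ficin")]
    merged = pm.merge_unique([a, b])
    assert [p.sequence for p in merged] == ["AY", "VF"]
    assert merged[0].treatment == "ficin,papain"
    assert len(merged) <= len(a) + len(b)
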
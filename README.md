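# pepmine

In-silico mining of antihypertensive peptides from food proteins.

Angiotensin-converting enzyme (ACE) converts angiotensin I into the
vasoconstrictor angiotensin II; peptides that inhibit ACE lower blood
pressure, and food proteins are a rich, safe source of them. Finding such
peptides by wet-lab hydrolysis and fractionation is slow, so a standard
alternative is to *simulate* the hydrolysis: digest the protein sequence in
silico with proteases of known specificity, look the released fragments up
in activity databases or score them with predictors, and screen the
candidates for the properties an oral antihypertensive needs — survival of
gastrointestinal digestion, no predicted allergenicity or toxicity, and
intestinal permeability. `pepmine` implements that whole workflow as a
tested Python library, plus the downstream analysis mathematics: the
IC50/pIC50 dose-response fit used to quantify inhibition in vitro, and the
conformational metrics (RMSD, RMSF, radius of gyration, SASA, hydrogen
bonds, metal-coordination distances) used to analyse docking poses and
molecular-dynamics trajectories of ACE-peptide complexes.

## The model

**Digestion.** A protease is a set of declarative subsite rules over the
positions P4..P2' around a candidate scissile bond (Schechter-Berger
numbering), with optional exception (block) patterns and an optional
substrate-length cap. Digestion is exhaustive and deterministic: for bond
`i` of a sequence of length `L` (`1 <= i <= L-1`),

```
i is cleaved  <=>  some rule matches the window around i and no block does
```

and the released peptides are the maximal fragments between cleaved bonds.
Two-stage digestion (e.g. plant proteases followed by prolyl endopeptidase,
which only attacks substrates of <= 30 residues and is blocked at Pro-Pro
contexts) re-digests each first-stage product and maps the new cuts back to
parent coordinates. Release quality is quantified by

- `DH = 100 * |cleaved bonds| / (L - 1)` — degree of hydrolysis (%),
- `A_E = (released bioactive peptides) / L` — release frequency,
- `W = (released bioactive peptides) / (bioactive occurrences in the parent)`
  — relative release frequency, with `W <= 1` under exhaustive digestion.

**Screening.** Candidates pass four stages: gastrointestinal stability
(zero predicted cleavage sites under pepsin pH 1.3 / trypsin /
chymotrypsin; unstable peptides are digested and their fragments re-enter
the pool), allergenicity and toxicity predicates (file-backed verdicts from
external classifiers, never silently approximated), and the rule of 5
(fail on >5 H-bond donors, >10 acceptors, MW > 500 Da, or logP > 5, all
computed from sequence — see `docs/methods.md` for the atom-counting
conventions).

**Assay analysis.** Inhibition is `100 * (A - B) / A` from the hippuric-acid
concentrations without (`A`) and with (`B`) peptide; the dose-response is a
two-parameter logistic `inh(c) = 100 / (1 + (IC50/c)^h)` fitted in log
concentration, and `pIC50 = -log10(IC50 [M])`.

## Worked example

```python
import pepmine as pm

protein = pm.ProteinRecord(id="demo", sequence="GGKAPGPKNPPKAY")
result = pm.sequential_digest(
    protein, [pm.get_enzyme("papain")], [pm.get_enzyme("prep")]
)
print([p.sequence for p in result.peptides])
print(f"DH = {pm.degree_of_hydrolysis(result):.1f}%")
profile = pm.compute_profile("NPPK")
print(profile, pm.rule_of_five(profile))
```

prints

```
['GGK', 'AP', 'GP', 'K', 'NPPK', 'AY']
DH = 38.5%
PhysChemProfile(sequence='NPPK', mw=454.52660000000003, hbd=4, hba=8, logp=-2.1305) (True, [])
```

— papain cuts after the basic residues (5 of the 13 bonds, DH 38.5%), the
prolyl-endopeptidase stage then splits the Pro-rich products — but never a
Pro-Pro context, which is why the tetrapeptide NPPK is released intact —
and NPPK passes every rule-of-5 condition (454.5 Da, 4 donor atoms, 8
acceptor atoms, logP well below 5).

The numbered drivers under `analysis/` run the study end to end and write
their tables under `results/`: `01_digest_substrate.py` (six enzyme
treatments, DH/A_E/W), `02_screen_survivors.py` (cascade stage counts and
the 21 known / 9 novel partition of the 30 fixture survivors),
`03_fit_dose_response.py` (IC50 recovery at the measured potencies of the
two strongest new peptides, pIC50 4.58 and 4.41), and
`04_trajectory_metrics.py` (RMSD/RMSF/Rg/SASA and the 0.1 nm equilibration
check on a synthetic trajectory). A `pepmine` console script exposes the
same steps (`pepmine digest|screen|stats|assay|trajmetrics|simulate|run`).

The substrate of record — the squid (*Todarodes pacificus*) myosin heavy
chain, NCBI accession ADU19853.1 — is not redistributed; place its FASTA
under `tests/data/external/` (see the README there) to run the
degree-of-hydrolysis analysis on the real sequence.

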
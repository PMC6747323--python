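# Methods

This note documents the models, conventions and design choices behind
`pepmine`, in the order the pipeline runs them.

## Digestion model

Proteolysis is modelled as *exhaustive* and *deterministic*: every peptide
bond matched by a specificity rule (and not matched by an exception) is
cut, with no kinetics, enzyme concentration, pH dependence (beyond distinct
packaged rule variants such as pepsin at pH 1.3) or partial-digest
stochasticity. This is the convention under which bond counts, the degree
of hydrolysis and the release frequencies are well-defined, reproducible
quantities.

A rule constrains the subsites P4..P2' around a candidate bond
(Schechter-Berger numbering; for bond `i`, P1 is residue `i` and P1' is
residue `i+1`). Each constrained subsite carries an allowed-residue set
(complements are expressed against the 20-letter alphabet); unconstrained
subsites are wildcards. **Edge behaviour:** a constrained subsite whose
position falls outside the sequence fails the match, while wildcards are
indifferent. This reproduces the behaviour of regular-expression-based web
servers, whose lookaround context must exist — e.g. the packaged pepsin
table requires P3 and P2' to exist, so a dipeptide can never be a pepsin
substrate. Bonds adjacent to the termini are otherwise evaluated like any
other bond.

Rule tables ship as editable, versioned text files
(`src/pepmine/data/enzymes/*.rules`) with provenance comments:

- **pepsin (pH 1.3), trypsin, chymotrypsin (high specificity)** encode the
  ExPASy PeptideCutter models, including trypsin's WKP/MRP cleavages and
  its exception windows; the test suite verifies the engine against the
  published regular expressions (via pyteomics) on thousands of random
  sequences.
- **prolyl endopeptidase (PREP)** cleaves C-terminal to proline, is blocked
  when proline occupies P1' or P2 (so Pro-Pro contexts, in particular
  C-terminal Pro-Pro products, survive), and acts only on substrates of at
  most 30 residues — the cap applies to the *product* length in sequential
  digestion.
- **papain and ficin** are approximate classical subsite-consensus models
  (bulky-hydrophobic/aromatic S2 preference plus basic/aliphatic P1
  acceptance). Databases differ in their exact definitions for these
  enzymes, and predicted cleavage maps and DH values depend on the
  snapshot; the tables are data, not code, precisely so users can match a
  particular service by editing them.

Simultaneous multi-enzyme digestion cuts the union of the per-enzyme site
sets computed on the intact substrate; sequential digestion applies a
second enzyme set to each first-stage product and composes spans back to
parent coordinates. `DH = 100 * |cleaved bonds| / (L-1)` counts distinct
parent-coordinate bonds over the whole treatment; the denominator is all
`L-1` peptide bonds.

**A fixpoint subtlety.** For exception-free rule sets, fragments of an
exhaustive digest carry no remaining sites (a fragment's windows are
sub-windows of the parent's, and truncation can only remove matches). An
exception pattern, however, can *lose* its context at a newly created
terminus — after cutting `G-R / R-H-G`, trypsin's Arg-Arg-His exception no
longer shields the fragment `RHG` — so the gastrointestinal stage iterates
digestion until every emitted fragment is a true fixpoint. Single-pass
semantics are kept for `digest()` itself, where the site-union definition
of DH lives.

## Release statistics

`A_E` and `W` count released bioactive peptides *with multiplicity*, and
occurrences of reference sequences in the parent are counted *with
overlaps*. Under exhaustive digestion released fragments are disjoint
substrings of the parent, so each released active maps to a distinct
occurrence and `W <= 1` is provable; this is the only counting convention
with that property. The synthetic-data generator makes both quantities
exactly testable: `spike_motifs` embeds motifs with flank residues drawn
from the enzyme's accept sets (searched and then *verified against the
digestion engine*, not assumed), so the ground-truth release count — and
hence `W = 1.0` — holds by construction.

## Activity annotation

Dipeptides and tripeptides are annotated by exact lookup in a reference
table of known ACE inhibitors with pIC50 values (the packaged fixture
carries the documented entries, e.g. MF 6.04, IY 5.68, ST 5.39, AY 4.85;
longer table entries are kept but flagged). Tetra- to hexapeptides go
through a scorer interface with a strict `score > 0.0` activity call.
Trained external predictors (SVM activity models, allergenicity kNN,
toxicity SVM) are deliberately **not** reimplemented: their training data
and weights are not public artifacts of this package, and a silent
approximation would be misleading. Instead the package ships (a)
file-backed scorers/predicates that read exported verdicts, erroring on any
queried sequence without a verdict, and (b) clearly labelled constant-pass
predicates and a heuristic composition-based baseline scorer for testing
and demonstration. Known/novel partitioning is exact sequence membership
against a known-antihypertensive reference table.

## Physicochemical properties and the rule of 5

All properties are pure functions of sequence, driven by a versioned
per-residue table (`data/physchem/residue_properties.tsv`).

- **Molecular weight**: sum of standard average residue masses plus one
  water (18.0153 Da), cross-checked against Biopython in the tests.
- **H-bond donors** are counted as donor *atoms* (N/O bearing >= 1 H), not
  N-H/O-H hydrogens, on the **zwitterionic** form the peptide adopts at
  neutral (intestinal) pH: the N-terminal ammonium nitrogen counts, every
  non-proline backbone amide N-H counts, side-chain donors follow the
  table (Arg guanidine 3, Lys 1, Ser/Thr/Tyr/Trp 1, Asn/Gln 1, Asp/Glu 1,
  His 1), and the C-terminal carboxylate contributes none. Both choices
  are load-bearing: hydrogen counting would give Asn-Pro-Pro-Lys 8 donors
  and neutral-form counting would give Ile-Arg 6, spuriously rejecting
  validated permeable peptides; the adopted conventions are the ones under
  which the full validated survivor set clears the filter.
- **H-bond acceptors** are N/O atoms excluding amide nitrogens (backbone
  and side-chain amides, including proline's tertiary backbone N) — the
  common cheminformatics convention; counting all N+O would give
  Asn-Pro-Pro-Lys 12 acceptors and reject it.
- **logP** defaults to an additive scheme, `-0.9703 - 0.8838*(L-1) + sum of
  side-chain increments`, with both terms derived once from the
  Wildman-Crippen atomic model on glycine model peptides (chain term from
  polyglycine, increments from Gly-X-Gly minus Gly-Gly-Gly) and frozen in
  the data table. It is an approximation of atom-level calculators, not a
  reimplementation of any of them; an RDKit Crippen backend and arbitrary
  callables (e.g. readers of externally computed values) can substitute,
  and the tests pin the additive/atom-level agreement on screening-scale
  peptides to within 0.35 log units.
- **Rule of 5**: fail on any violation of hbd > 5, hba > 10, mw > 500 Da,
  logp > 5 (strict inequalities, so a boundary value passes). The
  conjunctive any-violation-fails reading is validated against the
  survivor fixture.

## Screening cascade

Stage order: gastrointestinal stability → allergenicity → toxicity →
permeability, then the known/novel partition. `input = pass + fail` holds
at every stage; the GI stage additionally reports its distinct new
fragments (length >= 2 — single residues are not peptides), which re-enter
the pool with provenance recorded, since a digestion product can be the
in-vivo active species. Fragments are *not* re-checked for activity before
re-entry; their origin annotation lets users apply either reading.

## Assay analysis

The calibration is ordinary least squares of response on standard
concentration with inverse prediction. The dose-response uses a
two-parameter logistic — floor 0 and ceiling 100 are fixed because the
inhibition definition `100*(A-B)/A` bounds the response — fitted by
Levenberg-Marquardt least squares on `(log10 IC50, h)`, initialised from
log-linear interpolation of the 50% crossing. Fits require >= 4 points
bracketing 50% inhibition (otherwise the IC50 would be an extrapolation and
the fit is refused with advice to widen the range). Replicates are fitted
as individual points, never pre-averaged. Noiseless model data is recovered
to better than 6 significant digits; at 3% assay noise the log10-IC50 bias
over 100 seeded replicates stays below 0.05.

## Conformation metrics

The module consumes coordinates (single- and multi-model PDB via biotite);
docking and MD engines are upstream producers, out of scope. Superposition
uses the Kabsch SVD algorithm with reflection correction, verified against
an independent quaternion (Horn) oracle to 1e-8. RMSF aligns all frames to
the first frame and pools atom fluctuations by residue. Rg is
mass-weighted, with masses from a per-element table. SASA is Shrake-Rupley
with a deterministic golden-spiral point set (default 960 points, probe
1.4 Å), bit-reproducible for fixed settings, within 1% of the closed form
for a single sphere and within 2% of a 10^5-point run for overlapping
dimers; van der Waals radii come from a per-element table with a per-call
override, and a missing element is an error naming it. Hydrogen bonds use
geometric criteria — donor-acceptor distance <= 3.5 Å and donor-H-acceptor
angle >= 120° — chosen from common MD-analysis practice and exposed as
parameters, since published hydrogen-bond counts cannot be reproduced
without the underlying trajectory in any case. The equilibration check
declares stability from the earliest time after which every sliding window
of the RMSD series spans <= 0.1 nm (1 Å, the conventional criterion),
and reports that time.

## Synthetic data

Generators are pure functions of their seed (one global seed spawns
per-generator substreams): random proteins with controlled composition
(multinomial draws; zero-weight residues never appear), motif-spiked
proteins with engine-verified release ground truth, logistic dose-response
data with Gaussian noise, and rigid-body trajectories (random rotation +
translation per frame, optional per-atom jitter) with one flexible atom
displaced ±a alternately so its fluctuation is analytically `a`. What the
synthetic data does *not* emulate: real protease kinetics, homologous
protein composition bias, assay heteroscedasticity, or MD physics — passing
tests demonstrate the correctness of the computations, not the biological
accuracy of any prediction.

## Problem sizes

Default test and driver sizes — thousands of short random sequences for the
oracle suites, 100 dose-response replicates, 100-frame/30-atom
trajectories, 960-point SASA spheres — were chosen as the smallest sizes at
which the statistical assertions (binomial composition envelopes, fit-bias
bounds, quadrature tolerances) are comfortably non-flaky.

## Known limitations

- The packaged papain/ficin tables are consensus approximations; absolute
  DH values on a real substrate depend on the specificity snapshot of
  whatever database one wishes to match (the engine itself is
  oracle-verified independently of any table).
- Donor/acceptor counting is table-driven and ignores conformation,
  tautomers and pKa shifts; logP additivity ignores neighbour effects
  beyond the glycine-context calibration.
- The GI stability model is binary (any predicted site = unstable) with no
  cleavage probabilities.
- Hydrogen-bond detection requires explicit hydrogen positions; structures
  without hydrogens must be protonated upstream.
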
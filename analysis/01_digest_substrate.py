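#!/usr/bin/env python
"""Simulated hydrolysis of a substrate protein by six enzyme treatments.

Digests the substrate with papain, ficin and their combination, each with
and without supplemental prolyl-endopeptidase digestion, and tabulates the
degree of hydrolysis and the bioactive release frequencies (A_E, W against
the packaged reference table).

Uses the user-supplied myosin heavy chain FASTA
(tests/data/external/ADU19853.1.fasta) when present; otherwise falls back
to a seeded synthetic substrate so the driver always runs.
"""

import argparse
from pathlib import Path

import pandas as pd

import pepmine as pm
from pepmine.synthetic import random_protein

ROOT = Path(__file__).resolve().parents[1]
TREATMENTS = [
    ("papain", ["papain"], None),
    ("ficin", ["ficin"], None),
    ("papain+ficin", ["papain", "ficin"], None),
    ("papain->prep", ["papain"], ["prep"]),
    ("ficin->prep", ["ficin"], ["prep"]),
    ("papain+ficin->prep", ["papain", "ficin"], ["prep"]),
]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "digestion_stats.csv")
    args = parser.parse_args()

    fasta = ROOT / "tests" / "data" / "external" / "ADU19853.1.fasta"
    if fasta.exists():
        protein = pm.read_fasta(fasta)[0]
        print(f"substrate: {protein.id} ({len(protein.sequence)} residues)")
    else:
        protein = random_protein(1500, rng=args.seed, id=f"synthetic_{args.seed}")
        print(
            f"substrate FASTA not found at {fasta}; using a seeded synthetic "
            f"1500-residue protein instead"
        )

    reference = set(pm.load_reference_table())
    rows = []
    for label, stage1_names, stage2_names in TREATMENTS:
        stage1 = [pm.get_enzyme(n) for n in stage1_names]
        if stage2_names:
            result = pm.sequential_digest(
                protein, stage1, [pm.get_enzyme(n) for n in stage2_names],
                treatment=label,
            )
        else:
            result = pm.digest(protein, stage1, treatment=label)
        row = {
            "treatment": label,
            "n_cleaved_bonds": len(result.cleaved_bonds),
            "n_peptides": len(result.peptides),
            "dh_percent": round(pm.degree_of_hydrolysis(result), 2),
            "release_frequency_AE": round(
                pm.release_frequency_AE(
                    result.peptides, reference, len(protein.sequence)
                ),
                5,
            ),
        }
        try:
            row["relative_frequency_W"] = round(
                pm.relative_frequency_W(result.peptides, reference, protein), 4
            )
        except ValueError:
            row["relative_frequency_W"] = None
        rows.append(row)
        print(
            f"  {label:22s} DH {row['dh_percent']:6.2f}%  "
            f"{row['n_peptides']:4d} peptides  A_E {row['release_frequency_AE']}"
        )

    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)
    print(f"wrote {args.out}")
    print(
        "supplemental prolyl-endopeptidase digestion increases DH for every "
        "treatment (second-stage cuts only add bonds)."
    )


if __name__ == "__main__":
    main()
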
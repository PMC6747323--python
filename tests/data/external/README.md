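# User-supplied external inputs

Files in this directory are not redistributed with the package. Two
acceptance tests look for them here and fail with instructions otherwise:

- `ADU19853.1.fasta` — the substrate protein (squid myosin heavy chain),
  downloaded from the NCBI protein database in FASTA format.
- `supplementary_peptides.tsv` — the supplementary table of 126 candidate
  ACE-inhibitory peptides, as a TSV with a single `sequence` column.
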
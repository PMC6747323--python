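# Prolyl endopeptidase (PREP), version 1.
# Cleaves peptide bonds at the C-terminal side of Pro residues; inactive
# when Pro occupies P1' and on Pro-Pro at P2-P1 (so C-terminal Pro-Pro
# products survive). Acts only on substrates of at most 30 residues.
name: prep
ec: 3.4.21.26
substrate_max_len: 30
rule: P1=P
block: P1=P P1'=P
block: P2=P P1=P
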
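# Papain, version 1.
# Approximate classical subsite consensus for the cysteine protease:
# preference for a bulky hydrophobic residue in S2 (Val not accepted at
# P1'), plus acceptance of basic residues at P1 (not before Pro).
# This is an editable approximation, not a database snapshot; predicted
# cleavage maps and degree-of-hydrolysis values depend on the exact rule
# table a given web service uses.
name: papain
ec: 3.4.22.2
rule: P2=AVLIFWY P1'=^V
rule: P1=RK P1'=^P
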
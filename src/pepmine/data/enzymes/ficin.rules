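# Ficin (ficain), version 1.
# Approximate classical subsite consensus: papain-family protease with a
# stronger aromatic preference in S2 (insulin B-chain mapping) and
# acceptance of small aliphatic residues at P1 (not before Pro).
# Editable approximation, not a database snapshot.
name: ficin
ec: 3.4.22.3
rule: P2=FYW P1'=^V
rule: P1=LVA P1'=^P
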
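# Pepsin at pH 1.3, version 1 (ExPASy PeptideCutter model).
# Preferential cleavage with Phe/Leu in P1 or P1'; His/Lys/Arg in P3,
# or Pro in P2 or P2', suppress cleavage. All four context positions
# P3..P2' must exist for a bond to be scored.
name: pepsin_ph1.3
ec: 3.4.23.1
rule: P3=^HKR P2=^P P1=^R P1'=FL P2'=^P
rule: P3=^HKR P2=^P P1=FL P2'=^P
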
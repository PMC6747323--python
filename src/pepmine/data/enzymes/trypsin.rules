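# Trypsin specificity, version 1 (ExPASy PeptideCutter model).
# Cleaves C-terminal to Lys/Arg unless Pro follows; the WKP and MRP
# contexts cleave despite the proline, and a short list of observed
# exception windows never cleaves.
name: trypsin
ec: 3.4.21.4
rule: P1=KR P1'=^P
rule: P2=W P1=K P1'=P
rule: P2=M P1=R P1'=P
block: P2=CD P1=K P1'=D
block: P2=C P1=K P1'=HY
block: P2=C P1=R P1'=K
block: P2=R P1=R P1'=HR
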
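# Chymotrypsin, high-specificity variant, version 1
# (ExPASy PeptideCutter model). Cleaves C-terminal to Phe/Tyr (not before
# Pro) and Trp (not before Met or Pro).
name: chymotrypsin_high
ec: 3.4.21.1
rule: P1=FY P1'=^P
rule: P1=W P1'=^MP
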
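# Known antihypertensive peptide sequences used for the known/novel
# partition of screening survivors, version 1.
sequence
AF
AG
AH
ASL
AY
DY
IF
IL
IR
PG
PH
PPK
QK
SF
SG
ST
TF
TP
VAF
VF
VP
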
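# The 30 ACE-inhibitory peptides surviving the full screening cascade
# (gastrointestinal stability, allergenicity, toxicity, permeability),
# with their known/new status, version 1.
sequence	status
AF	known
AG	known
AH	known
ASL	known
AY	known
DY	known
IF	known
IL	known
IR	known
PG	known
PH	known
PPK	known
QK	known
SF	known
SG	known
ST	known
TF	known
TP	known
VAF	known
VF	known
VP	known
AK	new
IIY	new
NAIP	new
NH	new
NPM	new
NPPK	new
QM	new
QY	new
SI	new
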
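# Reference ACE-inhibitory peptides with pIC50 (-log10 molar IC50), version 1.
# Di-/tripeptides are used by the lookup stage; longer entries are kept for
# comparison and flagged by the loader. Values as reported in curated
# antihypertensive-peptide databases (BIOPEP-UWM / AHTPDB style entries).
sequence	pic50	source
MF	6.04	curated database
IY	5.68	curated database
DG	5.67	curated database
EY	5.57	curated database
ST	5.39	curated database
VF	5.04	curated database
AY	4.85	curated database
MNPPK	3.02	porcine skeletal muscle hydrolysate
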
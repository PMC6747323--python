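# Per-residue physicochemical contributions, version 1.
# avg_mass: average residue (monomer minus water) mass, Da (ExPASy values).
# sc_donors: side-chain N/O atoms bearing >=1 H in the neutral side chain.
# sc_acceptors: side-chain N/O atoms excluding amide nitrogens.
# logp_sc: side-chain logP increment derived from Wildman-Crippen atomic
#   contributions on Gly-X-Gly model tripeptides (increment over Gly-Gly-Gly).
residue	avg_mass	sc_donors	sc_acceptors	logp_sc
A	71.0788	0	0	0.3885
C	103.1388	0	0	0.2984
D	115.0886	1	2	-0.1567
E	129.1155	1	2	0.2334
F	147.1766	0	0	1.6113
G	57.0519	0	0	0.0
H	137.1411	1	2	0.3344
I	113.1594	0	0	1.4147
K	128.1741	1	1	0.4976
L	113.1594	0	0	1.4147
M	131.1926	0	0	1.1217
N	114.1038	1	1	-0.7560
P	97.1167	0	0	0.8748
Q	128.1307	1	1	-0.3659
R	156.1875	3	3	-0.3681
S	87.0782	1	1	-0.6391
T	101.1051	1	1	-0.2506
V	99.1326	0	0	1.0246
W	186.2132	1	1	2.0926
Y	163.1733	1	1	1.3169
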
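# Example file-backed activity scores for tetra- to hexapeptides
# (SVM-style scores exported from an external predictor), version 1.
sequence	score
PIYT	1.06
EKSR	1.00
AINPYR	0.99
VIQY	0.91
EPIVK	0.87
QEQDH	0.86
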
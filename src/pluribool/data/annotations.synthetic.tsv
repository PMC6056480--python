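gene	category
POU5F1	pluripotency_tf
SOX2	pluripotency_tf
NANOG	pluripotency_tf
KLF4	pluripotency_tf
MYC	pluripotency_tf
TBX3	pluripotency_tf
UTF1	pluripotency_tf
STAT3	pluripotency_tf
HESX1	pluripotency_tf
TCF3	pluripotency_tf
TDGF1	pluripotency_tf
SALL4	pluripotency_tf
FOXD3	pluripotency_tf
PRDM14	pluripotency_tf
ZFP42	pluripotency_tf
LIN28A	pluripotency_tf
DPPA4	pluripotency_tf
TERT	pluripotency_tf
GDF3	pluripotency_tf
LIF	differentiation
LIFR	differentiation
WNT5A	differentiation
HAND1	differentiation
HNF4A	differentiation
NEUROG1	differentiation
GATA3	differentiation
GATA4	differentiation
GATA6	differentiation
SOX17	differentiation
PAX6	differentiation
CDX2	differentiation
EOMES	differentiation
MSX1	differentiation
NODAL	differentiation
LEFTY2	differentiation
INHBA	differentiation
BMP4	differentiation
NOG	differentiation
LHX1	differentiation
SOX1	differentiation
REST	epigenetic
L1TD1	epigenetic
FGF2	other
FGFR2	other
GSK3B	other
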
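source	sign	target
POU5F1	+	POU5F1
SOX2	+	POU5F1
TDGF1	+	POU5F1
SALL4	+	POU5F1
L1TD1	+	POU5F1
SOX2	+	SOX2
POU5F1	+	SOX2
TDGF1	+	SOX2
POU5F1	+	NANOG
SOX2	+	NANOG
STAT3	+	NANOG
GATA6	-	NANOG
FGF2	+	FGF2
REST	+	REST
POU5F1	+	REST
NANOG	+	STAT3
LIF	+	STAT3
POU5F1	+	TDGF1
POU5F1	+	SALL4
SOX2	+	SALL4
POU5F1	-	GATA6
NANOG	-	GATA4
GATA4	+	SOX17
GATA6	+	SOX17
GATA4	+	HNF4A
BMP4	+	CDX2
POU5F1	-	CDX2
BMP4	+	EOMES
SOX2	-	EOMES
BMP4	+	MSX1
BMP4	+	HAND1
MSX1	+	HAND1
POU5F1	-	HAND1
BMP4	+	GATA3
SOX2	-	GATA3
WNT5A	+	BMP4
NOG	-	BMP4
SOX2	+	NOG
POU5F1	+	NODAL
SOX2	+	NODAL
NODAL	+	LEFTY2
POU5F1	+	INHBA
REST	-	PAX6
POU5F1	-	PAX6
PAX6	+	NEUROG1
REST	-	NEUROG1
PAX6	+	SOX1
NODAL	+	LHX1
POU5F1	-	LHX1
LIF	+	LIFR
STAT3	+	MYC
LIF	+	MYC
MYC	+	TERT
SOX2	+	LIN28A
POU5F1	+	ZFP42
SOX2	+	ZFP42
POU5F1	+	DPPA4
NANOG	+	DPPA4
POU5F1	+	UTF1
SOX2	+	UTF1
POU5F1	+	GDF3
POU5F1	+	PRDM14
NANOG	+	PRDM14
POU5F1	+	FOXD3
NANOG	+	HESX1
GSK3B	+	TCF3
POU5F1	+	L1TD1
SOX2	+	L1TD1
NANOG	+	L1TD1
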
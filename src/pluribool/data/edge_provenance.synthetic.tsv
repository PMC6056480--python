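# Edge-by-edge provenance of the synthetic curated/novel pluripotency fixture.
# basis = literature: the interaction (or the knockdown behaviour it encodes)
#         is well documented in the stem-cell literature for this system.
# basis = constructed: field-standard pluripotency wiring added so the fixture
#         reaches the documented node/edge/auto-loop counts; not from a figure.
source	sign	target	set	basis	note
POU5F1	+	POU5F1	curated	literature	one of the four positive auto-regulatory loops
SOX2	+	SOX2	curated	literature	one of the four positive auto-regulatory loops
FGF2	+	FGF2	curated	constructed	autocrine FGF2 loop chosen as third positive auto-loop
REST	+	REST	curated	constructed	REST self-maintenance chosen as fourth positive auto-loop
SOX2	+	POU5F1	curated	constructed	core triad mutual activation
TDGF1	+	POU5F1	curated	constructed	core circuit ignition input
SALL4	+	POU5F1	curated	constructed	SALL4-OCT4 regulatory loop
L1TD1	+	POU5F1	curated	literature	L1TD1 can activate POU5F1
POU5F1	+	SOX2	curated	constructed	core triad mutual activation
TDGF1	+	SOX2	curated	constructed	core circuit ignition input
POU5F1	+	NANOG	curated	constructed	OCT4-SOX2 dimer activates NANOG
SOX2	+	NANOG	curated	constructed	OCT4-SOX2 dimer activates NANOG
STAT3	+	NANOG	curated	constructed	LIF/STAT3 signalling supports NANOG
GATA6	-	NANOG	curated	constructed	endoderm programme represses NANOG
POU5F1	+	REST	curated	literature	REST is highly abundant in ES cells (core-maintained)
NANOG	+	STAT3	curated	literature	NANOG knockdown shuts down STAT3
LIF	+	STAT3	curated	constructed	canonical LIF-STAT3 axis
POU5F1	+	TDGF1	curated	constructed	TDGF1/Cripto is a core-circuit target
POU5F1	+	SALL4	curated	constructed	core-circuit target
SOX2	+	SALL4	curated	constructed	core-circuit target
POU5F1	-	GATA6	curated	constructed	OCT4 represses the endoderm programme
NANOG	-	GATA4	curated	literature	NANOG loss up-regulates endoderm lineage genes
GATA4	+	SOX17	curated	constructed	endoderm cascade
GATA6	+	SOX17	curated	constructed	endoderm cascade
GATA4	+	HNF4A	curated	constructed	endoderm cascade
BMP4	+	CDX2	curated	constructed	BMP4 drives trophectoderm/mesoderm markers
POU5F1	-	CDX2	curated	constructed	OCT4-CDX2 mutual antagonism (repressive arm)
BMP4	+	EOMES	curated	constructed	BMP4 drives mesendoderm markers
SOX2	-	EOMES	curated	constructed	core factor represses mesendoderm
BMP4	+	MSX1	curated	literature	POU5F1 loss activates mesoderm genes via BMP4 axis
BMP4	+	HAND1	curated	constructed	BMP4 drives mesoderm markers
MSX1	+	HAND1	curated	constructed	mesoderm cascade
POU5F1	-	HAND1	curated	constructed	core factor represses mesoderm
BMP4	+	GATA3	curated	constructed	BMP4 drives trophoblast markers
SOX2	-	GATA3	curated	constructed	core factor represses trophoblast
WNT5A	+	BMP4	curated	constructed	non-canonical WNT input to BMP signalling
NOG	-	BMP4	curated	constructed	Noggin is the canonical BMP4 antagonist
SOX2	+	NOG	curated	constructed	core state maintains BMP antagonism
POU5F1	+	NODAL	curated	constructed	NODAL expressed in the pluripotent state
SOX2	+	NODAL	curated	constructed	NODAL expressed in the pluripotent state
NODAL	+	LEFTY2	curated	constructed	NODAL induces its feedback antagonist LEFTY2
POU5F1	+	INHBA	curated	literature	POU5F1 knockdown down-regulates INHBA (TGF-beta arm)
REST	-	PAX6	curated	literature	REST represses neuronal-specific genes
POU5F1	-	PAX6	curated	constructed	core factor represses neuroectoderm
PAX6	+	NEUROG1	curated	constructed	neuroectoderm cascade
REST	-	NEUROG1	curated	literature	REST represses neuronal-specific genes
PAX6	+	SOX1	curated	constructed	neuroectoderm cascade
NODAL	+	LHX1	curated	constructed	NODAL-driven lineage marker
POU5F1	-	LHX1	curated	constructed	core factor represses lineage marker
LIF	+	LIFR	curated	constructed	ligand-receptor pairing
STAT3	+	MYC	curated	constructed	STAT3 induces MYC
LIF	+	MYC	curated	constructed	LIF signalling induces MYC
MYC	+	TERT	curated	constructed	MYC induces telomerase
SOX2	+	LIN28A	curated	constructed	core-circuit target
POU5F1	+	ZFP42	curated	constructed	REX1 is a classic OCT4 target
SOX2	+	ZFP42	curated	constructed	REX1 is a classic core target
POU5F1	+	DPPA4	curated	constructed	core-circuit target
NANOG	+	DPPA4	curated	constructed	core-circuit target
POU5F1	+	UTF1	curated	literature	UTF1 expression shuts down with POU5F1
SOX2	+	UTF1	curated	literature	UTF1 is strongly regulated by core circuit genes
POU5F1	+	GDF3	curated	constructed	core-circuit target
POU5F1	+	PRDM14	curated	constructed	core-circuit target
NANOG	+	PRDM14	curated	constructed	core-circuit target
POU5F1	+	FOXD3	curated	constructed	core-circuit target
NANOG	+	HESX1	curated	literature	NANOG knockdown shuts down HESX1
GSK3B	+	TCF3	curated	constructed	GSK3B/WNT axis upstream of TCF3
POU5F1	+	L1TD1	curated	literature	L1TD1 is part of the core-circuit interactome
SOX2	+	L1TD1	curated	literature	L1TD1 is part of the core-circuit interactome
NANOG	+	L1TD1	curated	literature	L1TD1 is part of the core-circuit interactome
NANOG	-	KLF4	novel	literature	KLF4 is inhibited by NANOG (reconstructed-network prediction)
NANOG	+	TBX3	novel	literature	TBX3 activated by NANOG/POU5F1/SOX2 (reconstructed-network prediction)
POU5F1	+	TBX3	novel	literature	TBX3 activated by NANOG/POU5F1/SOX2 (reconstructed-network prediction)
SOX2	+	TBX3	novel	literature	TBX3 activated by NANOG/POU5F1/SOX2 (reconstructed-network prediction)
FGF2	+	FGFR2	novel	literature	FGFR2 is activated by FGF2
FGFR2	-	TCF3	novel	literature	FGFR2 inhibits TCF3
FGFR2	-	NOG	novel	literature	FGFR2 inhibits NOG
FGFR2	-	BMP4	novel	literature	FGFR2 inhibits BMP4
MYC	-	MYC	novel	literature	MYC exhibits a negative auto-regulatory loop
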
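source	sign	target
NANOG	-	KLF4
NANOG	+	TBX3
POU5F1	+	TBX3
SOX2	+	TBX3
FGF2	+	FGFR2
FGFR2	-	TCF3
FGFR2	-	NOG
FGFR2	-	BMP4
MYC	-	MYC
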
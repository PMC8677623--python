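ligand	receptor	family
EFNA1	EPHA2	Ephrin
EFNA3	EPHA2	Ephrin
EFNA5	EPHA4	Ephrin
EFNB1	EPHB2	Ephrin
EFNB2	EPHB4	Ephrin
EFNB3	EPHB6	Ephrin
FGF1	FGFR1	FGF
FGF2	FGFR1	FGF
FGF2	FGFR2	FGF
FGF7	FGFR2	FGF
FGF9	FGFR3	FGF
FGF10	FGFR2	FGF
FGF18	FGFR3	FGF
WNT2	FZD1+LRP5	WNT
WNT2B	FZD4+LRP6	WNT
WNT3A	FZD1+LRP6	WNT
WNT5A	FZD2	WNT
WNT5A	ROR1	WNT
WNT7B	FZD1+LRP5	WNT
WNT11	FZD7	WNT
TGFB1	TGFBR1+TGFBR2	TGFb
TGFB2	TGFBR1+TGFBR2	TGFb
TGFB3	TGFBR1+TGFBR2	TGFb
INHBA	ACVR1B+ACVR2A	TGFb
GDF15	TGFBR2	TGFb
BMP2	BMPR1A+BMPR2	BMP
BMP4	BMPR1A+BMPR2	BMP
BMP5	BMPR1B+BMPR2	BMP
BMP6	ACVR1+BMPR2	BMP
BMP7	BMPR1B+ACVR2A	BMP
IL6	IL6R+IL6ST	JAK/STAT
LIF	LIFR+IL6ST	JAK/STAT
OSM	OSMR+IL6ST	JAK/STAT
IL11	IL11RA+IL6ST	JAK/STAT
CXCL9	CXCR3	JAK/STAT
CXCL10	CXCR3	JAK/STAT
CXCL12	CXCR4	JAK/STAT
IFNG	IFNGR1+IFNGR2	JAK/STAT
EGF	EGFR	EGF
TGFA	EGFR	EGF
HBEGF	EGFR	EGF
NRG1	ERBB3	EGF
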
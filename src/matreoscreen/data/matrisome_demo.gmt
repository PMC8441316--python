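collagens	core ECM collagens	COL1A1	COL1A2	COL3A1	COL4A1	COL5A1	COL6A1	COL6A2	COL14A1	COL17A1	COL21A1
glycoproteins	core ECM glycoproteins	FN1	LAMA1	LAMB1	TNC	FBN1	ELN	SPARC	THBS1	VTN	NID1
proteoglycans	core ECM proteoglycans	ACAN	BGN	DCN	LUM	VCAN	HSPG2	PRELP	OGN
ECM-regulators	remodeling enzymes and their regulators	MMP1	MMP2	MMP3	MMP9	MMP14	ADAMTS1	ADAMTS5	TIMP1	TIMP2	LOX	PLOD1
secreted-factors	ECM-associated secreted factors	TGFB1	TGFB2	GDF15	WNT5A	IGF1	VEGFA	CTGF	S100A4
ECM-affiliated	ECM-affiliated proteins	ANXA2	ANXA5	LGALS1	LGALS3	SDC1	GPC1	CLEC3B	SEMA3A
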
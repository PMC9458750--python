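macrophage	synthetic toy collection: macrophage markers	CD163	CD68	CD84	MSR1	MRC1	CSF1R	ITGAM	CD14
IFN_downstream	synthetic toy collection: type-I interferon downstream signaling	STAT1	STAT2	IRF7	MX1	MX2	OAS1	OAS2	ISG15	IFI6	IFIT1	IFIT3	IFI27
antigen_presentation	synthetic toy collection: MHC class I antigen presentation	HLA-A	HLA-B	HLA-C	B2M	TAP1	TAP2	TAPBP	PSMB8	PSMB9
tcell_cytotoxicity	synthetic toy collection: cytotoxic T-cell effectors	CD8A	GZMA	GZMB	PRF1	CD3E	CD3D	IFNG	KLRK1
tgfb_signaling	synthetic toy collection: TGF-beta pathway	TGFB1	TGFB2	TGFB3	SMAD2	SMAD3	SMAD4	TGFBR1	TGFBR2
wnt_signaling	synthetic toy collection: WNT pathway	WNT1	WNT5A	CTNNB1	AXIN2	TCF7	LEF1	FZD1	DKK1
checkpoint	synthetic toy collection: exhaustion and checkpoint markers (partially off-panel)	PDCD1	CTLA4	LAG3	HAVCR2	TIGIT	CD274	BTLA	VSIR	CD160	TNFRSF9	ICOS	CD27
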
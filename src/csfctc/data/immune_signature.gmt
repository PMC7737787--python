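immune_signature	curated canonical immune-cell marker signature (60 genes)	PTPRC	CD2	CD3D	CD3E	CD3G	CD8A	CD8B	CD4	IL7R	CCL5	NKG7	GNLY	GZMA	GZMB	GZMK	PRF1	KLRB1	KLRD1	CD19	MS4A1	CD79A	CD79B	IGHM	IGKC	CD14	CD68	CD163	LYZ	FCGR3A	FCGR2A	AIF1	TYROBP	FCER1G	LST1	ITGAM	ITGB2	CSF1R	CXCR4	CCR7	SELL	LCK	ZAP70	CD27	CD28	CTLA4	IL2RB	IL2RG	TRAC	TRBC1	TRBC2	CD74	LAPTM5	CORO1A	ARHGDIB	CST7	CD37	CD48	CD52	CD53	SPI1
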
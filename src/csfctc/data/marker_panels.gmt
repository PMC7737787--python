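T	T marker panel	CD2	CD3D	CD3E	CD3G
B	B marker panel	CD19	MS4A1	CD79A	CD79B
monocyte	monocyte marker panel	CD14	CD68	CD163
leukocyte	leukocyte marker panel	PTPRC
lung	lung marker panel	SFTPA1	SFTPA2	SFTPB	NAPSA
epithelial	epithelial marker panel	EPCAM	CDH1	KRT7	KRT8	KRT18	MUC1
proliferation	proliferation marker panel	CCND1	TOP2A
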
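epithelial7	epithelial program for partial-EMT scoring	CDH1	EPCAM	KRT18	KRT19	KRT7	KRT8	MUC1
mes_csc	mesenchymal / cancer-stem-cell markers	FN1	VIM	CD44
ecm	extracellular-matrix receptor interaction core genes	LAMA3	LAMA5	LAMB2	LAMC1	ITGA3	ITGB4	CD47
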
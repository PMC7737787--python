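cta_276	synthetic stand-in list of 276 cancer-testis antigen family symbols	MAGEA1	MAGEA2	MAGEA3	MAGEA4	MAGEA5	MAGEA6	MAGEA8	MAGEA9	MAGEA10	MAGEA11	MAGEA12	MAGEA2B	MAGEA9B	MAGEB1	MAGEB2	MAGEB3	MAGEB4	MAGEB5	MAGEB6	MAGEB10	MAGEB16	MAGEB18	MAGEC1	MAGEC2	MAGEC3	GAGE1	GAGE2A	GAGE2B	GAGE2C	GAGE2D	GAGE2E	GAGE4	GAGE5	GAGE6	GAGE7	GAGE8	GAGE10	GAGE12B	GAGE12C	GAGE12D	GAGE12E	GAGE12F	GAGE12G	GAGE12H	GAGE12I	GAGE12J	GAGE13	PAGE1	PAGE2	PAGE2B	PAGE3	PAGE4	PAGE5	XAGE1A	XAGE1B	XAGE2	XAGE3	XAGE5	CTAG1A	CTAG1B	CTAG2	SSX1	SSX2	SSX3	SSX4	SSX5	SSX6	SSX7	SSX8	SSX9	SSX2B	SSX4B	SPANXA1	SPANXA2	SPANXB1	SPANXC	SPANXD	SPANXN1	SPANXN2	SPANXN3	SPANXN4	SPANXN5	BAGE	BAGE2	BAGE3	BAGE4	BAGE5	CT45A1	CT45A2	CT45A3	CT45A5	CT45A6	CT45A7	CT45A8	CT45A9	CT45A10	CT47A1	CT47A2	CT47A3	CT47A4	CT47A5	CT47A6	CT47A7	CT47A8	CT47A9	CT47A10	CT47A11	CT47A12	CT47B1	POTEA	POTEB	POTEC	POTED	POTEE	POTEG	POTEH	TSPY1	TSPY2	TSPY3	PRAME	SAGE1	DDX43	DDX53	LUZP4	PASD1	PLAC1	SPA17	LY6K	CTCFL	BRDT	PRM1	PRM2	TNP1	ACRBP	OIP5	TULP2	TPTE	LDHC	TSGA10	ROPN1	ROPN1B	IL13RA2	CTAGE1	CTAGE5	SYCP1	SYCP2	SYCE1	TEX14	TEX15	TEX101	MAEL	DAZL	DAZ1	DAZ2	DAZ3	DAZ4	BOLL	PIWIL1	PIWIL2	TDRD1	TDRD6	NXF2	NXF2B	FMR1NB	ADAM2	AKAP3	AKAP4	CABYR	CALR3	CCDC33	CCDC36	COX6B2	CPXCR1	CRISP2	CSAG1	CSAG2	CSAG3	CT55	CT62	CT83	CCNA1	DKKL1	DPPA2	FATE1	FBXO39	FTHL17	GPAT2	HORMAD1	HORMAD2	LEMD1	LIPI	LYZL6	MORC1	NOL4	ODF1	ODF2	ODF3	ODF4	PBK	PRSS54	PRSS55	RBM46	RGS22	SEMG1	SEMG2	SLCO6A1	SPAG1	SPAG4	SPAG6	SPAG8	SPAG9	SPAG17	SPEF2	SPESP1	SPO11	TAF7L	TEKT5	TFDP3	THEG	TPD52L3	TSSK6	ZNF165	ZNF645	XAGE3B	SPANXB2	MAGEB17	GAGE3	SPAG11A	SPAG11B	TEKT4	ARMC3	ATAD2B	CEP290	CCDC110	CCDC62	DCAF12	DMRT1	ELOVL4	GPATCH2	IGSF11	KDM5B	LDHAL6B	LYZL1	NLRP4	NXPH4	OTOA	PEPP2	PLAC1L	PRAMEF1	PRAMEF2	RQCD1	SPATA19	ACTL8	ADAM29	ANKRD45	ARX	C15orf60	CAGE1	CASC5	CCDC83	CDCA1	CENPV	CXorf61	CXorf67	DDX4	DPPA4	DSCR8	GOLGA6L2	HEMGN	HSPB9	IGF2BP3	LOC348120	MAGEE1	MAGEE2	MAGEF1	MAGEH1
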
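IL-17 signaling pathway	KEGG-like set built from the modeled pathway genes	IL17A	IL17F	IL17D	IL17RE	TRAF6	TRAF3IP2	HSP90AA1	MAP3K7	TAB2	TAB3	IKBKG	IKBKE	TRAF2	TRADD	ANAPC5	TNFAIP3	NFKB1	MAPK3	MAPK9	MAPK10	MAPK11	MAPK13	MAPK14	FOS	FOSL1	JUN	JUND	ELAVL1	SRSF1	CXCL1	CXCL2	CXCL3	CXCL5	CXCL8	CXCL10	CCL2	CCL7	CCL20	S100A7	S100A8	S100A9	LCN2	DEFB4A	DEFB4B	MMP1	MMP3	MMP9	MMP13	IL1B	IFNG	TNF
TNF signaling pathway	KEGG-like decoy set	TNF	TRADD	TRAF2	TRAF6	IKBKG	JUN	FOS	MAPK14	CCL2	CXCL10	MMP9	IL1B	CASP3	CASP8	RIPK1	NFKB1	MAP3K7	SOCS3	EDN1	VCAM1
MAPK signaling pathway	KEGG-like decoy set	MAPK1	MAPK3	MAPK8	MAPK9	MAPK10	MAPK11	MAPK13	MAPK14	JUN	FOS	TNF	IL1B	HSP90AA1	RAF1	BRAF	MAP2K1	MAP2K2	MAP3K7	DUSP1	ELK1	MYC	EGFR	FGFR1	NTRK1
p53 signaling pathway	KEGG-like decoy set	TP53	MDM2	MDM4	CDKN1A	CCND1	CCNE1	CDK2	CDK4	BAX	BBC3	PMAIP1	GADD45A	SFN	SESN1	SESN2	THBS1	SERPINE1	RRM2B	ZMAT3
Ribosome	KEGG-like decoy set	RPL3	RPL4	RPL5	RPL6	RPL7	RPL8	RPL9	RPL10	RPL11	RPL12	RPS2	RPS3	RPS4X	RPS5	RPS6	RPS7	RPS8	RPS9	RPS10	RPS11	RPS12	RPSA
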
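exemplar_id	genes	functional_annotation	p_value
127	TANK, TNFRSF11A, TNFRSF4, TNFRSF9, TRAFD1, ZBP1	Cytokine-cytokine receptor interaction (KEGG)	3.50E-06
32	ATP6V1A, BAIAP2, CAMK2D, CLU, DLG4, DYNLL1, EPS8, FZD1, FZD4, GRIA3, HCK, INADL, KCNJ10, NSF, OPRD1, PACSIN1, PACSIN2, PGK1, PHB2, PPP3CA, RGS12, SEMA4B, SEMA4C, SLC9A3R1, STXBP1, SYT1	Wnt signaling pathway (KEGG)	1.60E-03
44	CD2AP, DAPK1, EFNA2, EPHA4, FGR, FYN, PKD2, RAVER1, RGS1, SH2D1A, SH3BP1, SLAMF1, VAV1, VAV2, ZAP70	T cell receptor signaling pathway (KEGG)	26.7
93	HNRNPA1, LGALS3, NCOA3, PIAS1, RNF19A	Transcription cofactor activity (GO_BP)	5.30E-02
29	CLNK, FYB, LYN, PECAM1, SKAP2	Leukocyte activation (GO_BP)	6.30E-02
62	CSF2RB, EIF2AK2, GHR, GMCL1, GNB2L1, HES1, IFNGR1, IL6ST, JAK1, JAK2, JAK3, LMO4, NCL, PAG1, SLC40A1	Jak-STAT signaling pathway (KEGG)	2.10E-09
139	BRCA1, CIITA, GTF2H2, KDM5D, PDLIM4, POLR1A, POLR2B, TRIP4, TRPS1, ZFP111, ZFP292	Zinc ion binding (GO_BP)	5.30E-07
135	RIPK2, TAX1BP1, TIFA, TNFAIP3, TNIP2	Apoptosis (GO_BP)	6.70E-03
112	ANXA2, BMYC, GAB2, PRKCE, PRMT5, S100A10	Fc epsilon RI signaling pathway (KEGG)	1.40E-02
140	CCNG1, CCNG2, E2F1, GSTA4, NR4A3, SWAP70, TRIM32, TRP53	Cell cycle (GO_BP)	1.60E-03
124	HSPA5, HSPA9, HSPD1, PDXK, RAPGEF4, STIP1, YWHAE	Adenyl ribonucleotide binding (GO_MF)	6.60E-04
79	ALDOA, CD40, IL1R1, IL1RAP, IL1RL1, IRAK3, IRAK4, IRF4, IRF5, LRRFIP1, MYD88, TIRAP, TLR4, TNFRSF13B, TUBA1A	Cytokine-mediated signaling pathway (GO_BP)	2.50E-07
126	BCAR1, BLK, CD22, CD247, CLEC7A, ERBB2, IL15RA, ITGB3, RANBP2, SYK, TUBA4A, WIPF1	Cell surface receptor linked signal transduction (GO_BP)	4.10E-03
21	CCL3, CCL4, CCR1, CCR3, CCR5	Chemokine signaling pathway (GO_BP)	9.80E-07
63	APOE, CASK, CNN3, CTTN, HSP90B1, IPO11, KCNMA1, LDHA, MYO5A, NDEL1, NUDC, PRDX2, RAB6B, ROCK2, SH3BP4, TPM1, TPT1, TRF, TUBB5	Cellular homeostasis (GO_BP)	9.20E-04
80	MYO1C, PCDH15, RICTOR, RRN3, VPS35	Cytoskeleton organization (GO_BP)	9.30E-02
92	GFR, PDGFRA, PDGFRB, PTEN, SLC9A3R2	Transmembrane receptor protein tyrosine kinase signaling pathway (GO_BP)	2.80E-06
142	CSNK1E, NXN, PLCG2, RAD51, VANGL1, VANGL2	Wnt signaling pathway (KEGG)	3.90E-03
48	GRB10, IGF1R, MAP3K5	Insulin-like growth factor receptor signaling pathway (KEGG)	1.30E-03
50	HCST, IL2RB, KLRK1, TYROBP	Integral to membrane (GO_BP)	9.50E-02
52	ANP32A, DACH1, FOSB, HDAC2, HDAC9, L3MBTL2, MTA1, MTA3, RBBP7, REST, SP3, TCF7L2, WDR5, ZDHHC13, ZFPM1	Regulation of transcription (GO_BP)	4.00E-09
116	F2RL2, MAP3K2, SMAD1, SMAD5, TOB1, ZEB2	Cell surface receptor linked signal transduction (GO_BP)	4.60E-01
59	CASP1, CASP3, CASP8, CEBPB, GZMB, IL1B	Regulation of apoptosis (GO_BP)	1.30E-05
46	E2F2, GATA1, GATA3, GFI1B, LMO2, NFYA	Transcription (GO_BP)	1.30E-03
94	AXL, CD19, EPHA2, IL4RA, INSR, IRS2, KRAS, NEDD9, NME2, PDCD4, PIK3AP1, PIK3CA, PIK3CB, PIK3CD, PIK3R1, PLCG1, PTK2B, RALGDS, RASSF5, SIRPA, SOCS6, TEK, TLR2	Cell surface receptor linked signal transduction (GO_BP)	2.10E-03
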
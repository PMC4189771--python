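exemplar_id	genes	functional_annotation	p_value	cell_type
102	EPOR, PTPN1, STAT5B	Jak-STAT signaling pathway (KEGG)	5.20E-02	Hematopoetic stem cells
20	CCNT1, EIF2B1, MYC			Hematopoetic stem cells
86	EZR, NGFRAP1, NTF3	Neurotrophin signaling pathway	4.50E-02	Granylocytes
49	GRB7, TIA1			Hematopoetic stem cells
104	ARRB1 BGN PTS			Macrophages
96	PLCB2, POLA1, VIM			Granylocytes
98	POT1A, TERF1	Telomere maintenance via telomerase (GO-BP)	5.90E-04	Hematopoetic stem cells
7	AR, ATRX, CTCF, SMC1A, SMC3	Cell cycle (KEGG)	4.40E-02	Dendritic cells
119	CRE, PRPF40A, SMC2	Nucleoplasm (GO-CC)	8.00E-02	Dendritic cells
61	CLDN11, CNOT6L, ITGA5, ITGB1, SPARC	Cell adhesion molecules (CAMs) (KEGG)	7.80E-02	Macrophage
10	BICC1, CREBBP, CSK, KHDRBS1, PRMT1, RBM39	Control of Gene Expression by Vitamin D Receptor (KEGG)	7.00E-02	Ggranylocyte
97	EIF3L, POLR1B, POLR1E	RNA polymerase (KEGG)	4.70E-03	Hematopoetic stem cells
41	BRCA2, CEBPD, FANCD2	Cell cycle process (GO-BP)	5.70E-02	Macrophages
70	ADRB2, DLL1, MAGI3	Plasma membrane (GO-CC)	5.40E-02	abTcells
88	CHORDC1, IGBP1, NR3C1, PPP5C	Transition metal Ion binding (GO-MF)	3.90E-02	Hematopoetic stem cells
75	MEOX1, MEOX2, TLE4	Transcription factor activity	3.40E-03	Granylocytes
42	FBXW7, NOTCH1, NPM1 STAT4	Notch signaling pathway	1.20E-02	Hematopoetic stem cells
36	AEBP2, EED, MORC3, SETX, UHRF1	Nucleoplasm (GO-CC)	2.30E-03	Dendritic cells
38	EIF3A, EIF3B, EIF3I, EIF4E	Translational initiation (GO-BP)	2.00E-08	Hematopoetic stem cells
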
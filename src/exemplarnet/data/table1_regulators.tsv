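cell_type	activators
B cells	POU2AF1, PAX5, EBF1, SPIB, SFPI1, FOXP1
Dendritic cells	RELB, CIITA, AHR, SPIB, SFPI1
Granulocytes	CEBPB, NFE2, SFPI1, FOXO3, CEBPE, FLI1
Hematopoietic stem cells	HLF, LMO2, MYC, MYCN, GATA2, MEIS1, E2F6
Macrophage	CEBPA, CEBPB, SFPI1
Monocytes	CEBPB, SFPI1
Natural killer cells	EOMES, TBX21, SMAD3, GATA3
Natural killer t cells	GATA3, ZBTB16
abT cells	TCF7, BCL11B, GATA3, IKZF2, RORC, SMAD7, TOX
gdT Cells	GATA3, SOX13, ID3
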
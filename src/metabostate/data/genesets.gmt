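AMPK_TARGETS	pAMPK activity read-out: downstream targets of the PGC-1a/CREB/FOXO axes (reconstructed default list; edit freely)	PPARGC1A	PPARGC1B	NRF1	TFAM	SOD2	CAT	SIRT3	ULK1	FOXO1	FOXO3	PCK1	G6PC1	SESN2	CPT1C	PPARA
HIF1_TARGETS	HIF-1 activity read-out: canonical HIF-1 transcriptional targets (reconstructed default list; edit freely)	VEGFA	SLC2A1	CA9	LDHA	PDK1	BNIP3	NDRG1	ADM	ANGPTL4	EGLN3	P4HA1	PGF
TCA_ENZYMES	Citric acid cycle enzymes (10 genes)	CS	ACO2	IDH2	IDH3A	OGDH	SUCLA2	SUCLG1	SDHA	FH	MDH2
GLYCOLYSIS_ENZYMES	Glycolytic enzymes (8 genes)	HK2	GPI	PFKM	ALDOA	GAPDH	PGK1	ENO1	PKM
FAO_ENZYMES	Fatty-acid beta-oxidation enzymes (14 genes)	CPT1A	CPT1B	CPT2	SLC25A20	ACADVL	ACADL	ACADM	ACADS	HADHA	HADHB	ECI1	ACOX1	ACAA2	ETFA
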
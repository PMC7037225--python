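treatment	direction	gene
naturally_occurring_LDL	up	EP300
naturally_occurring_LDL	up	IQGAP1
naturally_occurring_LDL	up	MAP3K14
naturally_occurring_LDL	up	MAP3K3
naturally_occurring_LDL	up	NCF2
naturally_occurring_LDL	up	PIK3R5
naturally_occurring_LDL	up	PRKCD
naturally_occurring_LDL	up	PTGES
naturally_occurring_LDL	up	RAD23A
naturally_occurring_LDL	up	RIPK2
naturally_occurring_LDL	up	TAB1
naturally_occurring_LDL	down	AKT1
naturally_occurring_LDL	down	CDC42
naturally_occurring_LDL	down	DUSP7
naturally_occurring_LDL	down	GSK3B
naturally_occurring_LDL	down	HGF
naturally_occurring_LDL	down	NCF1
naturally_occurring_LDL	down	TAOK1
naturally_occurring_LDL	down	TGFB2
naturally_occurring_LDL	down	TRAF6
desialylated_LDL	up	EP300
desialylated_LDL	up	CASP2
desialylated_LDL	up	DUSP5
desialylated_LDL	up	IQGAP1
desialylated_LDL	up	PIK3R5
desialylated_LDL	up	PTGES
desialylated_LDL	up	PRKCD
desialylated_LDL	up	PRKCB
desialylated_LDL	up	RAD23A
desialylated_LDL	up	RIPK2
desialylated_LDL	down	DUSP7
desialylated_LDL	down	HGF
desialylated_LDL	down	MAP2K5
desialylated_LDL	down	MAP2K7
desialylated_LDL	down	NCF1
desialylated_LDL	down	TGFB2
desialylated_LDL	down	TGFB3
desialylated_LDL	down	TRADD
desialylated_LDL	down	TRAF6
acetylated_LDL	up	NCF2
acetylated_LDL	up	PRKCD
acetylated_LDL	up	PTGES
acetylated_LDL	up	SGK1
acetylated_LDL	down	AKT1
acetylated_LDL	down	CASP8
acetylated_LDL	down	DUSP1
acetylated_LDL	down	DUSP16
acetylated_LDL	down	GSK3B
acetylated_LDL	down	HDAC3
acetylated_LDL	down	IL1A
acetylated_LDL	down	MAP2K1
acetylated_LDL	down	MAP3K1
acetylated_LDL	down	MAP4K2
acetylated_LDL	down	OTUB1
acetylated_LDL	down	TAOK1
acetylated_LDL	down	TRADD
acetylated_LDL	down	TRAF6
oxidized_LDL	up	CASP2
oxidized_LDL	up	IQGAP1
oxidized_LDL	up	MAP3K14
oxidized_LDL	up	NCF2
oxidized_LDL	up	PRKCB
oxidized_LDL	up	RAD23A
oxidized_LDL	up	SGK1
oxidized_LDL	down	AKT1
oxidized_LDL	down	CDC42
oxidized_LDL	down	DUSP1
oxidized_LDL	down	DUSP16
oxidized_LDL	down	GSK3B
oxidized_LDL	down	HDAC3
oxidized_LDL	down	KRAS
oxidized_LDL	down	MAP3K1
oxidized_LDL	down	MAP4K2
oxidized_LDL	down	MAPK8IP1
oxidized_LDL	down	NCF1
oxidized_LDL	down	TAOK1
oxidized_LDL	down	TRAF6
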
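gene	innate_immunity	lipid_metabolism	phagocytosis
EP300	+	+	-
IQGAP1	-	?	+
MAP3K14	+	?	?
MAP3K3	+	+	?
NCF2	+	-	+
PIK3R5	-	-	?
PRKCD	+	+	+
PTGES	+	-	-
RAD23A	-	-	-
RIPK2	+	?	+
TAB1	+	?	?
AKT1	+	+	+
CDC42	+	+	+
DUSP7	-	?	?
GSK3B	+	+	+
HGF	+	+	+
NCF1	+	+	+
TAOK1	-	?	?
TGFB2	+	+	?
TRAF6	+	?	+
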
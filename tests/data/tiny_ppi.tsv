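# tiny hand-checked PPI fixture: 8 genes
GENE1	GENE2	1.0
GENE1	GENE3	2.0
GENE2	GENE3	1.0
GENE4	GENE5	1.0
GENE5	GENE6	2.0
GENE7	GENE8	1.5
GENE1	GENE7	0.5
GENE4	GENE8	1.0
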
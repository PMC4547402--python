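patient	GENE1	GENE2	GENE3	GENE4	GENE5	GENE6	GENE7	GENE8
P1	1	0	0	1	0	0	1	0
P2	0	1	0	1	0	0	0	1
P3	1	1	1	0	0	1	0	0
P4	0	0	0	1	1	0	0	0
P5	1	0	0	0	1	0	1	1
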
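gene	S1	S2	S3	S4	S5	S6
GENE1	1	2	3	4	5	6
GENE2	2	4	6	8	10	12
GENE3	6	5	4	3	2	1
GENE4	1	3	2	5	4	6
GENE5	2	2	2	2	2	2
GENE6	1	1	2	2	3	3
GENE7	3	1	4	1	5	9
GENE8	2	7	1	8	2	8
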
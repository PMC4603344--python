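genus	period	genomic	intron	utr	exon	total
Oryza	2	17	26	29	1	73
Arabidopsis	2	2	5	16	1	24
Oryza	3	18	16	70	142	246
Arabidopsis	3	2	2	26	67	97
Oryza	4	3	3	9	2	17
Arabidopsis	4	0	0	3	0	3
Oryza	5	4	1	10	0	15
Arabidopsis	5	0	0	3	0	3
Oryza	6	6	3	13	24	46
Arabidopsis	6	1	0	1	10	12
Oryza	total	48	49	131	169	397
Arabidopsis	total	5	7	49	78	139
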
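locus	genus	species	forward	reverse	motif	repeat_count	expected_min	expected_max	outcome	n_alleles	size_min	size_max
T6	Trifolium	T. pratense	CAACCAGTGGTGTGAGTAGGA	GACGTTGGTGGAGAGGTTGAG	AG	11	110	128	product	2	114	116
T7	Trifolium	T. repens	ATCACGCTTCACTCCTCCACC	AACTCCAAGCTTAAGATCGTGTA	AG	13	110	122	no_product	.	.	.
T1	Trifolium	T. repens	AGATTCCCACCAATCTCCCT	CAATACGCGGGTCTTGATCT	AG	11	210	228	stutter	.	257	261
T2	Trifolium	T. pratense	TTCCGGTTAGGTTAGGGTTT	TTTTCACATCTTCCGAAGCC	AAT	7	110	113	no_product	.	.	.
T3	Trifolium	T. repens	CACCACATATGCAACCACAA	GTCGACGACGGTTGTTACCT	AGT	8	110	126	no_product	.	.	.
T8	Trifolium	T. repens	GCAAAACTCAAGAGAACGGC	GGATGTCTTCGGAGGTGAGA	ACC	7	110	122	no_product	.	.	.
T9	Trifolium	T. repens	ACAACCCATTTGCCTCAAAG	TTTTCACTTCCACCACCTCC	ACC	7	110	133	product	2	124	127
T10	Trifolium	T. pratense	TCCACTAGTTCTAGAGCGGC	TCCTGTAAACTGGAGGAGCC	ACC	9	110	153	no_product	.	.	.
T11	Trifolium	T. pratense	TGGCGGTGGTGACTTATACA	TGTTTGGCAGTGGTGATGTT	AGG	8	110	153	no_product	.	.	.
T4	Trifolium	T. pratense	GCTGCCACAGCACTACCAGA	ATATTACCGTGAATGAAGCTCAG	ACC	8	110	113	product	1	110	110
T5	Trifolium	T. pratense	TGAGTTCCGAGTTAAGGCTCA	TTCGGTAACTCCGAGGATTG	ACCT	5	210	217	product	2	227	230
T12	Trifolium	T. repens	GATTATTCAACCAAACGCCG	TAGAAAGCCACGCCAAGACT	AATCC	20	290	290	no_product	.	.	.
C6	Centaurea	C. maculosa	TGGGATGCAGTCCAGTCATA	TTGCAACTTGCCTGTACCAC	AC	11	160	162	product	1	256	256
C1	Centaurea	C. maculosa	GGGAACCACACCTTTCATCT	GATCTGGCTTGACCCAAGAA	AC	10	90	119	product	2	99	101
C7	Centaurea	C. solstitialis	TCGTTTTCCGATCACAAACTC	CAATTTGGCGACATCTCCTT	AC	12	110	160	product	4	114	152
C2	Centaurea	C. solstitialis	CGCATTATGGAATAAACCCG	GCTTTCGACTTCATAAGCGG	AAG	7	140	152	product	1	147	147
C8	Centaurea	C. maculosa	CGATGTATACAGGTGGTGCG	GGAGAAGGGGAGACGTAAGG	ACC	7	110	150	product	2	141	144
C9	Centaurea	C. solstitialis	AACGGTAGGAACCAGCATTG	GATCCTCTGGCAGGGTCATA	ACC	9	260	302	product	4	290	299
C10	Centaurea	C. solstitialis	AGTTGCCAGAAAGGAGCAAG	TCGAGAACAATGGCCTATCC	AGC	7	210	229	no_product	.	.	.
C11	Centaurea	C. maculosa	TCCATGGATACAACCACCAA	GCGATATTCGGATGCAAAGT	AGG	7	160	175	product	4	160	172
C3	Centaurea	C. maculosa	GCCATCCCCTTCTCTACTCC	GTTACAGGTGACGATGGGG	AGT	7	160	181	no_product	.	.	.
C4	Centaurea	C. solstitialis	CTGCACCTACCCAGAGAAGC	CGGGAGAGGGTAAATTGTGA	AGGT	5	110	115	product	3	103	109
C12	Centaurea	C. maculosa	ATGCATTGAGAAGGCCAATC	AACTCGCAAGCCTTTTCAAG	AATCGG	4	210	223	no_product	.	.	.
C5	Centaurea	C. solstitialis	TTAAGCATTCTTCGAGGCGT	TCTATGCCTACGCCGATCTC	AAGCAG	5	110	110	no_product	.	.	.
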
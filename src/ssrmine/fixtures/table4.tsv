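locus	genus	species	n_individuals	outcome	n_alleles	size_min	size_max
C6	Centaurea	C. valesiaca	7	product	1	256	256
C6	Centaurea	C. borjae	2	product	1	256	256
C1	Centaurea	C. valesiaca	7	product	2	99	101
C1	Centaurea	C. borjae	2	product	2	90	101
C7	Centaurea	C. valesiaca	7	product	2	141	143
C7	Centaurea	C. borjae	2	product	4	114	152
C2	Centaurea	C. valesiaca	7	product	1	305	305
C2	Centaurea	C. borjae	2	product	1	305	305
C8	Centaurea	C. valesiaca	7	product	1	144	144
C8	Centaurea	C. borjae	2	product	1	141	141
C9	Centaurea	C. valesiaca	7	product	1	290	290
C9	Centaurea	C. borjae	2	product	3	293	299
C11	Centaurea	C. valesiaca	7	product	2	160	166
C11	Centaurea	C. borjae	2	product	3	160	169
C4	Centaurea	C. valesiaca	7	product	1	103	103
C4	Centaurea	C. borjae	2	product	2	105	109
T6	Trifolium	T. fragiferum	6	product	1	114	114
T6	Trifolium	T. saxatile	2	product	1	116	116
T1	Trifolium	T. fragiferum	6	stutter	.	257	261
T1	Trifolium	T. saxatile	2	stutter	.	257	261
T9	Trifolium	T. fragiferum	6	product	1	124	124
T9	Trifolium	T. saxatile	2	product	2	124	127
T4	Trifolium	T. fragiferum	6	product	1	110	110
T4	Trifolium	T. saxatile	2	product	1	110	110
T5	Trifolium	T. fragiferum	6	product	2	227	230
T5	Trifolium	T. saxatile	2	product	2	227	230
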
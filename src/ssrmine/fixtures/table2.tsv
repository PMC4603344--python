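group	n_genera	n_genera_ssr	n_est	di	tri	tetra	penta	hexa	total	commonest_motifs
Florideophyceae	2	2	16645	2	10	2	1	10	25	ACG/GGC
Charophyceae	1	1	88280	16	77	39	38	30	200	AG/TGA
Acrogymnospermae	18	15	1191184	144	145	30	58	193	570	AG/AT/CAG
Lycopodiophyta	3	3	101292	20	122	15	7	26	190	AG/CAG/TGA
Monilophyta	5	3	35665	129	18	3	2	6	158	AG/TGA
Magnoliidae	5	5	68569	193	89	11	9	30	332	AG/AT/CAG
Monocotyledoneae	58	37	3197142	598	1395	296	323	496	3108	AG/AT/AAG/CGG
Eudicotyledoneae	165	127	9742277	4160	4820	760	769	2010	12519	AG/AT/AAG/TGA
Total	257	193	14498726	5262	6676	1156	1207	2801	17102	-
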
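species	lineage	wgd_rounds	cons_targets	cons_total	noncons_targets	noncons_total
OS	monocot	0	178	521	771	2116
BD	monocot	0	156	495	319	1167
SB	monocot	0	158	413	489	1304
ZM	monocot	1	105	319	448	1548
VV	eudicot	0	29	282	124	796
TC	eudicot	0	77	149	554	1290
CP	eudicot	0	22	101	116	602
FV	eudicot	0	39	108	275	1344
MD	eudicot	1	49	125	1516	4127
PT	eudicot	1	59	122	389	1175
LJ	eudicot	1	23	46	219	622
AT	eudicot	2	51	74	685	1485
GM	eudicot	2	72	148	1307	3162
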
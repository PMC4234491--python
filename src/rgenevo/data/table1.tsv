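species	lineage	n_chr	n_gene	n_annot	n_pfam	n_prgdb	n_nonredundant	n_ortho_rgene	conservation_pct
Oryza sativa	monocot	12	41046	1180	2294	1316	2637
Sorghum bicolor	monocot	10	34008	570	1616	159	1717	413	24.1
Zea mays	monocot	10	32540	480	2630	399	1867	319	17.1
Brachypodium distachyon	monocot	5	25504	467	1473	0	1662	495	29.8
Vitis vinifera	eudicot	19	21189	256	892	170	1078
Arabidopsis thaliana	eudicot	5	33198	564	1407	1105	1559	74	4.7
Populus trichocarpa	eudicot	19	30260	212	1229	134	1297	122	9.4
Carica papaya	eudicot	9	19205	113	674	0	703	101	14.4
Glycine max	eudicot	20	46164	1023	3104	318	3310	148	4.5
Malus x domestica	eudicot	17	58979	853	4135	243	4252	125	2.9
Lotus japonicus	eudicot	6	15470	0	664	26	668	46	6.9
Fragaria vesca	eudicot	7	34809	0	1452	1	1452	108	7.4
Theobroma cacao	eudicot	10	27814	0	1439	4	1439	149	10.4
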
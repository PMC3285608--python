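chromosome	comparison	group	syn_cds	nonsyn_cds
Chr01	IR24_vs_MH63	shared	454	559
Chr02	IR24_vs_MH63	shared	237	223
Chr03	IR24_vs_MH63	shared	144	221
Chr04	IR24_vs_MH63	shared	119	182
Chr05	IR24_vs_MH63	shared	168	220
Chr06	IR24_vs_MH63	shared	192	229
Chr07	IR24_vs_MH63	shared	118	158
Chr08	IR24_vs_MH63	shared	275	355
Chr09	IR24_vs_MH63	shared	99	149
Chr10	IR24_vs_MH63	shared	118	173
Chr11	IR24_vs_MH63	shared	188	243
Chr12	IR24_vs_MH63	shared	178	250
Total	IR24_vs_MH63	shared	2290	2962
Chr01	IR24_vs_MH63	different	5	11
Chr02	IR24_vs_MH63	different	9	12
Chr03	IR24_vs_MH63	different	3	6
Chr04	IR24_vs_MH63	different	6	16
Chr05	IR24_vs_MH63	different	4	10
Chr06	IR24_vs_MH63	different	4	3
Chr07	IR24_vs_MH63	different	0	3
Chr08	IR24_vs_MH63	different	7	8
Chr09	IR24_vs_MH63	different	1	4
Chr10	IR24_vs_MH63	different	6	14
Chr11	IR24_vs_MH63	different	1	6
Chr12	IR24_vs_MH63	different	8	6
Total	IR24_vs_MH63	different	54	99
Chr01	IR24_vs_SH527	shared	475	592
Chr02	IR24_vs_SH527	shared	229	206
Chr03	IR24_vs_SH527	shared	172	246
Chr04	IR24_vs_SH527	shared	163	221
Chr05	IR24_vs_SH527	shared	206	251
Chr06	IR24_vs_SH527	shared	151	225
Chr07	IR24_vs_SH527	shared	94	139
Chr08	IR24_vs_SH527	shared	279	362
Chr09	IR24_vs_SH527	shared	143	195
Chr10	IR24_vs_SH527	shared	135	228
Chr11	IR24_vs_SH527	shared	291	419
Chr12	IR24_vs_SH527	shared	184	282
Total	IR24_vs_SH527	shared	2522	3366
Chr01	IR24_vs_SH527	different	15	8
Chr02	IR24_vs_SH527	different	13	8
Chr03	IR24_vs_SH527	different	3	10
Chr04	IR24_vs_SH527	different	17	25
Chr05	IR24_vs_SH527	different	0	16
Chr06	IR24_vs_SH527	different	3	5
Chr07	IR24_vs_SH527	different	4	7
Chr08	IR24_vs_SH527	different	8	7
Chr09	IR24_vs_SH527	different	12	23
Chr10	IR24_vs_SH527	different	8	14
Chr11	IR24_vs_SH527	different	0	4
Chr12	IR24_vs_SH527	different	11	11
Total	IR24_vs_SH527	different	94	138
Chr01	MH63_vs_SH527	shared	561	699
Chr02	MH63_vs_SH527	shared	504	560
Chr03	MH63_vs_SH527	shared	327	513
Chr04	MH63_vs_SH527	shared	286	421
Chr05	MH63_vs_SH527	shared	250	322
Chr06	MH63_vs_SH527	shared	383	486
Chr07	MH63_vs_SH527	shared	97	161
Chr08	MH63_vs_SH527	shared	404	599
Chr09	MH63_vs_SH527	shared	150	212
Chr10	MH63_vs_SH527	shared	127	202
Chr11	MH63_vs_SH527	shared	221	290
Chr12	MH63_vs_SH527	shared	207	273
Total	MH63_vs_SH527	shared	3517	4738
Chr01	MH63_vs_SH527	different	1	4
Chr02	MH63_vs_SH527	different	22	18
Chr03	MH63_vs_SH527	different	5	7
Chr04	MH63_vs_SH527	different	6	16
Chr05	MH63_vs_SH527	different	4	5
Chr06	MH63_vs_SH527	different	1	5
Chr07	MH63_vs_SH527	different	4	5
Chr08	MH63_vs_SH527	different	2	1
Chr09	MH63_vs_SH527	different	4	12
Chr10	MH63_vs_SH527	different	6	5
Chr11	MH63_vs_SH527	different	5	8
Chr12	MH63_vs_SH527	different	16	11
Total	MH63_vs_SH527	different	76	97
Chr01	threeway	shared	343	419
Chr02	threeway	shared	141	127
Chr03	threeway	shared	106	170
Chr04	threeway	shared	88	113
Chr05	threeway	shared	127	154
Chr06	threeway	shared	118	161
Chr07	threeway	shared	61	92
Chr08	threeway	shared	190	247
Chr09	threeway	shared	71	104
Chr10	threeway	shared	62	112
Chr11	threeway	shared	138	168
Chr12	threeway	shared	111	158
Total	threeway	shared	1556	2025
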
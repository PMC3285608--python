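chromosome	comparison	group	non_cds	cds
Chr01	IR24_vs_MH63	shared	1159	123
Chr02	IR24_vs_MH63	shared	433	61
Chr03	IR24_vs_MH63	shared	524	69
Chr04	IR24_vs_MH63	shared	383	63
Chr05	IR24_vs_MH63	shared	382	52
Chr06	IR24_vs_MH63	shared	398	48
Chr07	IR24_vs_MH63	shared	243	42
Chr08	IR24_vs_MH63	shared	548	56
Chr09	IR24_vs_MH63	shared	272	34
Chr10	IR24_vs_MH63	shared	303	41
Chr11	IR24_vs_MH63	shared	286	36
Chr12	IR24_vs_MH63	shared	311	41
Total	IR24_vs_MH63	shared	5242	666
Chr01	IR24_vs_MH63	different	20	1
Chr02	IR24_vs_MH63	different	28	0
Chr03	IR24_vs_MH63	different	14	0
Chr04	IR24_vs_MH63	different	13	0
Chr05	IR24_vs_MH63	different	14	0
Chr06	IR24_vs_MH63	different	3	0
Chr07	IR24_vs_MH63	different	5	0
Chr08	IR24_vs_MH63	different	25	0
Chr09	IR24_vs_MH63	different	15	0
Chr10	IR24_vs_MH63	different	11	0
Chr11	IR24_vs_MH63	different	11	0
Chr12	IR24_vs_MH63	different	9	0
Total	IR24_vs_MH63	different	168	1
Chr01	IR24_vs_SH527	shared	1212	128
Chr02	IR24_vs_SH527	shared	360	58
Chr03	IR24_vs_SH527	shared	550	71
Chr04	IR24_vs_SH527	shared	499	68
Chr05	IR24_vs_SH527	shared	404	52
Chr06	IR24_vs_SH527	shared	381	43
Chr07	IR24_vs_SH527	shared	233	43
Chr08	IR24_vs_SH527	shared	554	62
Chr09	IR24_vs_SH527	shared	383	43
Chr10	IR24_vs_SH527	shared	371	41
Chr11	IR24_vs_SH527	shared	462	54
Chr12	IR24_vs_SH527	shared	358	42
Total	IR24_vs_SH527	shared	5767	705
Chr01	IR24_vs_SH527	different	15	1
Chr02	IR24_vs_SH527	different	18	0
Chr03	IR24_vs_SH527	different	8	0
Chr04	IR24_vs_SH527	different	3	0
Chr05	IR24_vs_SH527	different	18	0
Chr06	IR24_vs_SH527	different	2	0
Chr07	IR24_vs_SH527	different	6	0
Chr08	IR24_vs_SH527	different	21	0
Chr09	IR24_vs_SH527	different	11	0
Chr10	IR24_vs_SH527	different	6	0
Chr11	IR24_vs_SH527	different	3	0
Chr12	IR24_vs_SH527	different	2	0
Total	IR24_vs_SH527	different	113	1
Chr01	MH63_vs_SH527	shared	1288	129
Chr02	MH63_vs_SH527	shared	859	73
Chr03	MH63_vs_SH527	shared	1047	83
Chr04	MH63_vs_SH527	shared	615	76
Chr05	MH63_vs_SH527	shared	608	57
Chr06	MH63_vs_SH527	shared	801	54
Chr07	MH63_vs_SH527	shared	233	37
Chr08	MH63_vs_SH527	shared	791	77
Chr09	MH63_vs_SH527	shared	364	35
Chr10	MH63_vs_SH527	shared	281	41
Chr11	MH63_vs_SH527	shared	288	38
Chr12	MH63_vs_SH527	shared	367	35
Total	MH63_vs_SH527	shared	7542	735
Chr01	MH63_vs_SH527	different	9	1
Chr02	MH63_vs_SH527	different	27	0
Chr03	MH63_vs_SH527	different	13	0
Chr04	MH63_vs_SH527	different	12	0
Chr05	MH63_vs_SH527	different	2	0
Chr06	MH63_vs_SH527	different	5	0
Chr07	MH63_vs_SH527	different	2	0
Chr08	MH63_vs_SH527	different	3	0
Chr09	MH63_vs_SH527	different	9	0
Chr10	MH63_vs_SH527	different	16	0
Chr11	MH63_vs_SH527	different	10	0
Chr12	MH63_vs_SH527	different	19	0
Total	MH63_vs_SH527	different	127	1
Chr01	threeway	shared	1033	108
Chr02	threeway	shared	278	51
Chr03	threeway	shared	451	61
Chr04	threeway	shared	324	55
Chr05	threeway	shared	324	42
Chr06	threeway	shared	329	37
Chr07	threeway	shared	192	34
Chr08	threeway	shared	464	49
Chr09	threeway	shared	228	29
Chr10	threeway	shared	219	34
Chr11	threeway	shared	242	30
Chr12	threeway	shared	223	29
Total	threeway	shared	4307	559
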
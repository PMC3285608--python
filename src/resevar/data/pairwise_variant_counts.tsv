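chromosome	pair	category	shared	different
Chr01	IR24_vs_MH63	SNP	16776	364
Chr02	IR24_vs_MH63	SNP	6207	331
Chr03	IR24_vs_MH63	SNP	6268	216
Chr04	IR24_vs_MH63	SNP	5813	257
Chr05	IR24_vs_MH63	SNP	7075	239
Chr06	IR24_vs_MH63	SNP	5042	211
Chr07	IR24_vs_MH63	SNP	3697	92
Chr08	IR24_vs_MH63	SNP	10698	271
Chr09	IR24_vs_MH63	SNP	3961	164
Chr10	IR24_vs_MH63	SNP	4809	234
Chr11	IR24_vs_MH63	SNP	5407	194
Chr12	IR24_vs_MH63	SNP	6203	226
Total	IR24_vs_MH63	SNP	81956	2799
Chr01	MH63_vs_SH527	SNP	17425	437
Chr02	MH63_vs_SH527	SNP	5548	470
Chr03	MH63_vs_SH527	SNP	6708	275
Chr04	MH63_vs_SH527	SNP	7138	618
Chr05	MH63_vs_SH527	SNP	7400	208
Chr06	MH63_vs_SH527	SNP	4631	229
Chr07	MH63_vs_SH527	SNP	3412	181
Chr08	MH63_vs_SH527	SNP	10938	335
Chr09	MH63_vs_SH527	SNP	5089	398
Chr10	MH63_vs_SH527	SNP	5513	275
Chr11	MH63_vs_SH527	SNP	9257	150
Chr12	MH63_vs_SH527	SNP	6530	422
Total	MH63_vs_SH527	SNP	89589	3998
Chr01	IR24_vs_SH527	SNP	20167	191
Chr02	IR24_vs_SH527	SNP	13209	586
Chr03	IR24_vs_SH527	SNP	15437	333
Chr04	IR24_vs_SH527	SNP	11451	275
Chr05	IR24_vs_SH527	SNP	10666	121
Chr06	IR24_vs_SH527	SNP	13302	150
Chr07	IR24_vs_SH527	SNP	3964	169
Chr08	IR24_vs_SH527	SNP	16565	109
Chr09	IR24_vs_SH527	SNP	6062	261
Chr10	IR24_vs_SH527	SNP	5085	152
Chr11	IR24_vs_SH527	SNP	6440	163
Chr12	IR24_vs_SH527	SNP	7016	417
Total	IR24_vs_SH527	SNP	129364	2927
Chr01	IR24_vs_MH63	InDel	5107	86
Chr02	IR24_vs_MH63	InDel	1833	162
Chr03	IR24_vs_MH63	InDel	2191	66
Chr04	IR24_vs_MH63	InDel	1597	49
Chr05	IR24_vs_MH63	InDel	2056	73
Chr06	IR24_vs_MH63	InDel	1663	17
Chr07	IR24_vs_MH63	InDel	1063	22
Chr08	IR24_vs_MH63	InDel	2745	132
Chr09	IR24_vs_MH63	InDel	1218	56
Chr10	IR24_vs_MH63	InDel	1514	57
Chr11	IR24_vs_MH63	InDel	1430	71
Chr12	IR24_vs_MH63	InDel	1636	69
Total	IR24_vs_MH63	InDel	24053	860
Chr01	MH63_vs_SH527	InDel	5380	70
Chr02	MH63_vs_SH527	InDel	1717	97
Chr03	MH63_vs_SH527	InDel	2410	51
Chr04	MH63_vs_SH527	InDel	2184	19
Chr05	MH63_vs_SH527	InDel	2058	88
Chr06	MH63_vs_SH527	InDel	1518	22
Chr07	MH63_vs_SH527	InDel	1017	15
Chr08	MH63_vs_SH527	InDel	2847	117
Chr09	MH63_vs_SH527	InDel	1693	49
Chr10	MH63_vs_SH527	InDel	1808	50
Chr11	MH63_vs_SH527	InDel	2406	22
Chr12	MH63_vs_SH527	InDel	1898	34
Total	MH63_vs_SH527	InDel	26936	634
Chr01	IR24_vs_SH527	InDel	5761	26
Chr02	IR24_vs_SH527	InDel	3747	170
Chr03	IR24_vs_SH527	InDel	4699	54
Chr04	IR24_vs_SH527	InDel	2732	41
Chr05	IR24_vs_SH527	InDel	3045	28
Chr06	IR24_vs_SH527	InDel	3541	23
Chr07	IR24_vs_SH527	InDel	979	17
Chr08	IR24_vs_SH527	InDel	4227	14
Chr09	IR24_vs_SH527	InDel	1655	32
Chr10	IR24_vs_SH527	InDel	1381	56
Chr11	IR24_vs_SH527	InDel	1594	58
Chr12	IR24_vs_SH527	InDel	1705	94
Total	IR24_vs_SH527	InDel	35066	613
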
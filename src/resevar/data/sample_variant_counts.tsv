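chromosome	sample	snps	indels	svs
Chr01	IR24	36134	8026	528
Chr02	IR24	25139	5258	215
Chr03	IR24	19810	4249	322
Chr04	IR24	19042	3413	273
Chr05	IR24	32928	6212	283
Chr06	IR24	16015	3187	233
Chr07	IR24	12093	2061	98
Chr08	IR24	29097	5564	423
Chr09	IR24	17905	3657	153
Chr10	IR24	21873	4281	269
Chr11	IR24	19377	3472	297
Chr12	IR24	17970	3467	192
Total	IR24	267383	52847	3286
Chr01	MH63	34498	7755	488
Chr02	MH63	36400	8064	274
Chr03	MH63	30599	7097	363
Chr04	MH63	26016	4986	276
Chr05	MH63	21990	4726	241
Chr06	MH63	24585	4880	261
Chr07	MH63	13607	2388	108
Chr08	MH63	27334	5501	382
Chr09	MH63	13685	2723	115
Chr10	MH63	16421	3315	201
Chr11	MH63	19470	3625	267
Chr12	MH63	24159	4598	250
Total	MH63	288764	59658	3226
Chr01	SH527	33949	7779	491
Chr02	SH527	29835	6868	246
Chr03	SH527	27263	6519	352
Chr04	SH527	22324	4259	284
Chr05	SH527	21396	4638	232
Chr06	SH527	25190	5247	262
Chr07	SH527	10325	1807	88
Chr08	SH527	26804	5491	390
Chr09	SH527	13451	2891	120
Chr10	SH527	14736	3105	189
Chr11	SH527	16873	3329	252
Chr12	SH527	17716	3567	221
Total	SH527	259862	55500	3127
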
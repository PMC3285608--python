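chromosome	comparison	atg_change	premature_stop	stop_change
Chr01	IR24_vs_MH63	0	8	3
Chr02	IR24_vs_MH63	4	3	3
Chr03	IR24_vs_MH63	1	5	2
Chr04	IR24_vs_MH63	0	4	3
Chr05	IR24_vs_MH63	0	7	1
Chr06	IR24_vs_MH63	0	2	0
Chr07	IR24_vs_MH63	0	1	0
Chr08	IR24_vs_MH63	0	6	2
Chr09	IR24_vs_MH63	0	5	1
Chr10	IR24_vs_MH63	0	6	3
Chr11	IR24_vs_MH63	0	2	2
Chr12	IR24_vs_MH63	0	1	1
Total	IR24_vs_MH63	5	50	21
Chr01	IR24_vs_SH527	0	8	4
Chr02	IR24_vs_SH527	1	2	1
Chr03	IR24_vs_SH527	1	7	2
Chr04	IR24_vs_SH527	1	6	3
Chr05	IR24_vs_SH527	0	9	1
Chr06	IR24_vs_SH527	0	3	0
Chr07	IR24_vs_SH527	0	0	0
Chr08	IR24_vs_SH527	0	9	2
Chr09	IR24_vs_SH527	0	7	1
Chr10	IR24_vs_SH527	0	7	1
Chr11	IR24_vs_SH527	0	6	3
Chr12	IR24_vs_SH527	0	5	0
Total	IR24_vs_SH527	3	69	18
Chr01	MH63_vs_SH527	0	12	4
Chr02	MH63_vs_SH527	0	4	3
Chr03	MH63_vs_SH527	0	13	4
Chr04	MH63_vs_SH527	0	8	3
Chr05	MH63_vs_SH527	0	5	4
Chr06	MH63_vs_SH527	0	5	0
Chr07	MH63_vs_SH527	0	2	0
Chr08	MH63_vs_SH527	0	14	2
Chr09	MH63_vs_SH527	0	6	2
Chr10	MH63_vs_SH527	1	5	3
Chr11	MH63_vs_SH527	0	2	2
Chr12	MH63_vs_SH527	0	6	0
Total	MH63_vs_SH527	1	82	27
Chr01	threeway	0	7	2
Chr02	threeway	0	0	1
Chr03	threeway	0	4	2
Chr04	threeway	0	3	2
Chr05	threeway	0	5	1
Chr06	threeway	0	1	0
Chr07	threeway	0	0	0
Chr08	threeway	0	5	2
Chr09	threeway	0	3	1
Chr10	threeway	0	3	1
Chr11	threeway	0	0	1
Chr12	threeway	0	1	0
Total	threeway	0	32	13
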
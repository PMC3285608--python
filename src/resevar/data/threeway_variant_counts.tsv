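chromosome	category	shared	different
Chr01	SNP	12245	0
Chr02	SNP	3255	2
Chr03	SNP	4313	1
Chr04	SNP	4082	2
Chr05	SNP	4645	0
Chr06	SNP	3141	1
Chr07	SNP	2112	0
Chr08	SNP	7665	1
Chr09	SNP	2493	0
Chr10	SNP	2460	0
Chr11	SNP	3772	2
Chr12	SNP	3504	1
Total	SNP	53687	10
Chr01	InDel	4336	0
Chr02	InDel	1197	2
Chr03	InDel	1841	2
Chr04	InDel	1331	1
Chr05	InDel	1592	0
Chr06	InDel	1275	0
Chr07	InDel	750	1
Chr08	InDel	2339	0
Chr09	InDel	979	0
Chr10	InDel	965	5
Chr11	InDel	1216	0
Chr12	InDel	1121	1
Total	InDel	18942	12
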
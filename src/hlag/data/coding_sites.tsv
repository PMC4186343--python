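genomic_pos_hg19	rsid	gene_pos	ref	ref_freq	alt	alt_freq	annotation
29795636	rs1630223	15	G	0.4967	A	0.5033	Synonymous
29795657	rs1630185	36	G	0.4967	A	0.5033	Synonymous
29795667	.	46	G	0.9991	T	0.0009	Non-synonymous
29795720	rs56388903	99	A	0.1120	G	0.8880	Intronic
29795747	rs6932888	126	G	0.7156	C	0.2844	Intronic
29795751	rs6932596	130	C	0.7161	T	0.2839	Intronic
29795768	rs1629329	147	T	0.4396	C	0.5604	Intronic
29795809	rs1628628	188	C	0.5669	T	0.4331	Intronic
29795822	.	201	A	0.9963	G	0.0037	Splice site acceptor
29795840	.	219	G	0.9967	T	0.0033	Non-synonymous
29795913	rs41551813	292	A	0.9503	T	0.0497	Non-synonymous
29795914	rs72558173	293	C	0.9986	T	0.0014	Non-synonymous
29795918	rs80153902	297	G	0.9958	A	0.0042	Synonymous
29795927	rs72558174	306	G	0.9972	A	0.0028	Synonymous
29795945	rs9258495	324	G	0.9991	T	0.0009	Synonymous
29795987	rs78627024	366	G	0.9972	A	0.0028	Synonymous
29795993	rs1130355	372	G	0.4967	A	0.5033	Synonymous
29796103	rs1626038	482	T	0.4340	C	0.5660	Intronic
29796106	rs17875399	485	G	0.9526	T	0.0474	Intronic
29796114	.	493	G	0.9991	A	0.0009	Intronic
29796115	rs1736927	494	A	0.4336	C	0.5665	Intronic
29796119	rs201510147	498	G	0.9986	A	0.0014	Intronic
29796126	rs3215482	505	A	0.4828	AC	0.5172	Intronic
29796128	.	507	C	0.9517	A	0.0483	Intronic
29796149	.	528	A	0.9967	C	0.0033	Intronic
29796152	rs1625907	531	G	0.4819	C	0.5181	Intronic
29796228	.	607	G	0.9981	A	0.0019	Intronic
29796234	rs375939243	613	CA	0.4991	C	0.5009	Intronic
29796245	.	624	T	0.9991	C	0.0009	Intronic
29796257	rs1625035	636	C	0.4493	T	0.5507	Intronic
29796265	rs17875401	644	G	0.9493	T	0.0507	Intronic
29796273	.	652	C	0.9981	T	0.0019	Intronic
29796306	rs1624337	685	G	0.4986	A	0.5014	Intronic
29796327	rs1130356	706	C	0.7621	T	0.2379	Synonymous
29796348	rs79303923	727	C	0.9981	T	0.0019	Synonymous
29796362	.	741	C	0.9991	G	0.0009	Non-synonymous
29796369	rs3873252	748	A	0.9345	T	0.0655	Synonymous
29796376	rs12722477	755	C	0.8053	A	0.1947	Non-synonymous
29796434	rs41557518	813	AC	0.9642	A	0.0358	Frame Shift
29796492	rs17875402	871	G	0.9944	A	0.0056	Synonymous
29796637	rs17875403	1016	C	0.9949	T	0.0051	Intronic
29796640	rs1632942	1019	T	0.4475	C	0.5525	Intronic
29796675	rs17875404	1054	G	0.9503	T	0.0497	Intronic
29796685	rs1632941	1064	T	0.4972	C	0.5028	Intronic
29796700	rs148061958	1079	C	0.9972	T	0.0028	Intronic
29796725	rs370704534	1104	C	0.9981	G	0.0019	Intronic
29796749	rs62391965	1128	C	0.9345	A	0.0655	Intronic
29796752	.	1131	A	0.9991	T	0.0009	Intronic
29796768	rs1632940	1147	T	0.2040	C	0.7960	Intronic
29796800	rs140935623	1179	A	0.9981	G	0.0019	Intronic
29796838	rs1736923	1217	A	0.4963	G	0.5037	Intronic
29796934	rs114041958	1313	G	0.9507	A	0.0493	Intronic
29796935	rs1632939	1314	G	0.4972	A	0.5028	Intronic
29796986	rs1632938	1365	G	0.4972	A	0.5028	Intronic
29797043	rs145023077	1422	C	0.9912	T	0.0088	Intronic
29797052	rs116139267	1431	C	0.9967	T	0.0033	Intronic
29797073	rs188836562	1452	G	0.9991	C	0.0009	Intronic
29797155	rs17875405	1534	G	0.9503	C	0.0497	Intronic
29797173	rs1736920	1552	A	0.4470	G	0.5530	Intronic
29797195	.	1574	A	0.9986	AC	0.0014	Frame Shift
29797211	rs41562616	1590	C	0.9503	T	0.0497	Synonymous
29797380	rs200931762	1759	G	0.9991	A	0.0009	Non-synonymous
29797420	rs12722482	1799	C	0.9698	T	0.0302	Non-synonymous
29797421	rs76951509	1800	G	0.9963	A	0.0037	Synonymous
29797448	rs17875406	1827	G	0.9554	A	0.0446	Synonymous
29797553	rs1632937	1932	G	0.4972	C	0.5028	Intronic
29797639	rs1049033	2018	C	0.7742	T	0.2258	Synonymous
29797696	rs1130363	2075	A	0.4470	G	0.5530	Synonymous
29797782	rs1611627	2161	T	0.5627	C	0.4373	Intronic
29797899	rs1632934	2278	T	0.4972	C	0.5028	Intronic
29797933	rs1632933	2312	C	0.4972	T	0.5028	Intronic
29797951	rs1736912	2330	A	0.4972	G	0.5028	Intronic
29798029	.	2408	T	0.9991	A	0.0009	Intronic
29798033	rs17179080	2412	G	0.9707	A	0.0293	Intronic
29798039	rs1632932	2418	G	0.4972	A	0.5028	Intronic
29798083	rs114038308	2462	C	0.9345	T	0.0655	Intronic
29798140	rs915667	2519	A	0.5084	G	0.4916	Intronic
29798248	rs186170315	2627	G	0.9991	A	0.0009	Intronic
29798419	rs915670	2798	G	0.7742	A	0.2258	Intronic
29798425	rs915669	2804	G	0.4480	T	0.5520	Intronic
29798459	rs915668	2838	C	0.4480	G	0.5520	Intronic
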
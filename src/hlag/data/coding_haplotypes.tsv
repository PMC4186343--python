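name	global_freq	15	36	99	126	130	147	188	292	372	482	485	494	505	507	531	613	636	644	685	706	748	755	813	1019	1054	1064	1128	1147	1217	1313	1314	1365	1534	1552	1590	1799	1827	1932	2018	2075	2161	2278	2312	2330	2412	2418	2462	2519	2798	2804	2838
G*01:01:01:01	0.2528	G	G	G	C	T	T	C	A	G	T	G	A	A	C	G	CA	C	G	G	C	A	C	AC	T	G	T	C	C	A	G	G	G	G	A	C	C	G	G	C	A	T	T	C	A	G	G	C	A	G	G	C
G*01:01:01:01new	0.02	G	G	G	C	T	T	C	A	G	T	G	A	A	C	G	CA	C	G	G	C	A	C	AC	T	G	T	C	C	A	G	G	G	G	A	C	C	G	G	C	A	T	T	C	A	A	G	C	A	G	G	C
G*01:01:01:04	0.0376	G	G	G	G	C	T	C	A	G	T	G	A	A	C	G	CA	C	G	G	C	A	C	AC	T	G	T	C	T	A	G	G	G	G	A	C	C	G	G	C	A	T	T	C	A	G	G	C	A	G	G	C
G*01:01:01:05	0.0911	G	G	A	G	C	T	C	A	G	T	G	A	A	C	G	CA	C	G	G	C	A	C	AC	T	G	T	C	T	A	G	G	G	G	A	C	C	G	G	C	A	T	T	C	A	G	G	C	A	G	G	C
G*01:01:02:01	0.1445	A	A	G	G	C	C	T	A	A	C	G	C	AC	C	C	C	T	G	A	T	A	C	AC	C	G	C	C	C	G	G	A	A	G	G	C	C	G	C	T	G	C	C	T	G	G	A	C	G	A	T	G
G*01:01:03:03	0.0627	A	A	G	G	C	C	C	A	A	C	G	C	AC	C	C	C	T	G	A	C	T	C	AC	C	G	C	A	C	G	G	A	A	G	G	C	C	G	C	C	G	T	C	T	G	G	A	T	G	G	T	G
G*01:03:01:02	0.0446	G	G	G	G	C	C	C	T	G	C	T	C	A	A	G	CA	T	T	G	C	A	C	AC	C	T	T	C	T	A	A	G	G	C	G	T	C	G	G	C	G	T	T	C	A	G	G	C	A	G	T	G
G*01:04:01	0.1329	A	A	G	G	C	C	T	A	A	C	G	C	AC	C	C	C	T	G	A	C	A	A	AC	C	G	C	C	C	G	G	A	A	G	G	C	C	G	C	C	G	C	C	T	G	G	A	C	G	G	T	G
G*01:04:04	0.0404	A	A	G	G	C	C	T	A	A	C	G	C	AC	C	C	C	T	G	A	C	A	A	AC	C	G	C	C	C	G	G	A	A	G	G	C	C	A	C	C	G	C	C	T	G	G	A	C	G	G	T	G
G*01:05N	0.033	A	A	G	G	C	C	T	A	A	C	G	C	AC	C	C	C	T	G	A	T	A	C	A	C	G	C	C	C	G	G	A	A	G	G	C	C	G	C	T	G	C	C	T	G	G	A	C	G	A	T	G
G*01:06	0.0283	A	A	G	G	C	C	T	A	A	C	G	C	AC	C	C	C	T	G	A	T	A	C	AC	C	G	C	C	C	G	G	A	A	G	G	C	T	G	C	T	G	C	C	T	G	G	A	C	G	A	T	G
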
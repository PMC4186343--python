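haplotype	CEU	TSI	GBR	FIN	IBS	CHB	CHS	JPT	YRI	LWK	ASW	MXL	PUR	CLM
010102a	0.2824	0.3418	0.3908	0.2283	0.4286	0.3385	0.2750	0.2360	0.2586	0.2713	0.2881	0.2742	0.1636	0.2328
010101a	0.3941	0.2704	0.3103	0.3370	0.3214	0.2813	0.4150	0.2303	0.1379	0.2394	0.1695	0.2419	0.2182	0.1810
010104a	0.0882	0.1327	0.0575	0.0652	0.0714	0.1979	0.1800	0.3820	0.2701	0.0904	0.1356	0.0806	0.1455	0.0862
010101b	0.0471	0.0510	0.0230	0.1902	0.0000	0.0417	0.0100	0.0056	0.0805	0.0266	0.0339	0.0645	0.0455	0.0690
010101f	0.0118	0.0255	0.0747	0.0109	0.0714	0.0000	0.0050	0.0056	0.0747	0.1277	0.0847	0.0484	0.0909	0.0603
010101c	0.1059	0.0867	0.0862	0.0870	0.1071	0.0052	0.0050	0.0000	0.0000	0.0053	0.0085	0.0161	0.0727	0.0603
010104b	0.0000	0.0000	0.0000	0.0000	0.0000	0.0781	0.0800	0.0899	0.0000	0.0000	0.0085	0.0726	0.0273	0.1379
010101d	0.0059	0.0153	0.0115	0.0000	0.0000	0.0000	0.0000	0.0000	0.0632	0.0691	0.0763	0.0403	0.0636	0.0431
0103a	0.0235	0.0153	0.0115	0.0163	0.0000	0.0156	0.0000	0.0169	0.0000	0.0000	0.0339	0.0887	0.0364	0.0345
0103e	0.0059	0.0051	0.0057	0.0000	0.0000	0.0104	0.0000	0.0000	0.0402	0.0479	0.0339	0.0081	0.0273	0.0259
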
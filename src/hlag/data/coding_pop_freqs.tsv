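haplotype	CEU	TSI	GBR	FIN	IBS	CHB	CHS	JPT	YRI	LWK	ASW	MXL	PUR	CLM
G*01:01:01:01	0.3824	0.2755	0.2989	0.3370	0.2857	0.2813	0.3900	0.2360	0.0690	0.1489	0.1271	0.2339	0.2182	0.1810
G*01:01:02:01	0.1824	0.1735	0.1954	0.1196	0.2500	0.0938	0.0350	0.1742	0.1379	0.1436	0.1780	0.2097	0.1000	0.1552
G*01:04:01	0.0647	0.1020	0.0517	0.0543	0.0714	0.2656	0.2400	0.3764	0.0402	0.0106	0.0339	0.1532	0.1364	0.1810
G*01:01:01:05	0.1529	0.1429	0.1092	0.2609	0.1071	0.0469	0.0150	0.0056	0.0632	0.0319	0.0339	0.0806	0.1182	0.1293
G*01:01:03:03	0.0529	0.0408	0.0920	0.0435	0.0357	0.1719	0.2050	0.0337	0.0000	0.0000	0.0085	0.0484	0.0455	0.0086
G*01:03:01:02	0.0353	0.0306	0.0230	0.0163	0.0000	0.0260	0.0000	0.0169	0.0690	0.0798	0.1186	0.0968	0.0818	0.0603
G*01:04:04	0.0235	0.0306	0.0115	0.0054	0.0000	0.0000	0.0000	0.0000	0.2299	0.0745	0.1102	0.0081	0.0273	0.0259
G*01:01:01:04	0.0118	0.0153	0.0632	0.0109	0.0714	0.0000	0.0000	0.0000	0.0747	0.1011	0.0763	0.0403	0.0727	0.0603
G*01:05N	0.0059	0.0408	0.0000	0.0109	0.0000	0.0417	0.0150	0.0056	0.1207	0.0638	0.0847	0.0242	0.0000	0.0172
G*01:06	0.0412	0.0714	0.0632	0.0272	0.1071	0.0260	0.0100	0.0056	0.0000	0.0053	0.0085	0.0242	0.0273	0.0431
G*01:01:01:01new	0.0059	0.0153	0.0115	0.0000	0.0000	0.0000	0.0000	0.0000	0.0460	0.0585	0.0593	0.0242	0.0364	0.0345
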
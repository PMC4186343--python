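haplotype	CEU	TSI	GBR	FIN	IBS	CHB	CHS	JPT	YRI	LWK	ASW	MXL	PUR	CLM
UTR-1	0.3882	0.2959	0.3333	0.3533	0.3214	0.2865	0.4200	0.2472	0.1322	0.2287	0.2288	0.2823	0.2909	0.2241
UTR-3	0.0882	0.1276	0.0575	0.0652	0.0714	0.2813	0.2600	0.4944	0.2989	0.1170	0.1610	0.1532	0.1818	0.2328
UTR-2	0.2471	0.2398	0.2644	0.1739	0.3929	0.1510	0.0500	0.1685	0.1667	0.2340	0.2627	0.2419	0.1000	0.2155
UTR-4	0.1529	0.1378	0.1092	0.2826	0.1071	0.0469	0.0200	0.0056	0.1322	0.1117	0.0508	0.0887	0.1273	0.1466
UTR-7	0.0471	0.0408	0.0747	0.0435	0.0357	0.1563	0.1800	0.0281	0.0000	0.0000	0.0085	0.0403	0.0455	0.0000
UTR-10	0.0000	0.0714	0.0230	0.0380	0.0000	0.0313	0.0100	0.0225	0.0977	0.0585	0.0339	0.0161	0.0364	0.0345
UTR-5	0.0353	0.0255	0.0172	0.0163	0.0000	0.0156	0.0000	0.0169	0.0460	0.0479	0.1017	0.0806	0.0909	0.0431
UTR-18	0.0118	0.0153	0.0517	0.0109	0.0714	0.0000	0.0000	0.0000	0.0172	0.0798	0.0508	0.0323	0.0727	0.0603
UTR-6	0.0059	0.0153	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0747	0.0266	0.0254	0.0081	0.0091	0.0000
others	0.0235	0.0306	0.0690	0.0163	0.0000	0.0313	0.0600	0.0169	0.0345	0.0957	0.0763	0.0565	0.0455	0.0431
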
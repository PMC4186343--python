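genomic_pos_hg19	rsid	gene_pos	ref	ref_freq	alt	alt_freq	annotation
29798563	.	2942	T	0.9986	C	0.0014	UTR
29798581	rs371194629	2960	G	0.7068	GATTTGTTCATGCCT	0.2932	UTR
29798608	.	3001	C	0.9986	T	0.0014	UTR
29798610	rs1707	3003	C	0.1152	T	0.8848	UTR
29798617	rs1710	3010	G	0.4610	C	0.5390	UTR
29798634	rs17179101	3027	C	0.9359	A	0.0641	UTR
29798639	rs146339774	3032	G	0.9967	C	0.0033	UTR
29798642	rs17179108	3035	C	0.8829	T	0.1171	UTR
29798659	.	3052	C	0.9991	T	0.0009	UTR
29798699	rs180827037	3092	G	0.9986	T	0.0014	UTR
29798728	rs138249160	3121	T	0.9967	C	0.0033	UTR
29798749	rs1063320	3142	C	0.4484	G	0.5516	UTR
29798784	.	3177	G	0.9991	T	0.0009	UTR
29798790	rs187320344	3183	G	0.9991	A	0.0009	UTR
29798794	rs9380142	3187	A	0.7045	G	0.2955	UTR
29798803	rs1610696	3196	C	0.7625	G	0.2375	UTR
29798834	rs1233331	3227	G	0.9707	A	0.0293	UTR
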
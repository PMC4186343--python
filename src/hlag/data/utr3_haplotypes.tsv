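name	global_freq	2960	3003	3010	3027	3035	3142	3187	3196	3227
UTR-1	0.2904	G	T	G	C	C	C	G	C	G
UTR-2	0.1938	GATTTGTTCATGCCT	T	C	C	C	G	A	G	G
UTR-3	0.1938	G	T	C	C	C	G	A	C	G
UTR-4	0.1083	G	C	G	C	C	C	A	C	G
UTR-7	0.0558	GATTTGTTCATGCCT	T	C	A	T	G	A	C	G
UTR-10	0.0367	G	T	C	C	C	G	A	G	G
UTR-5	0.0358	GATTTGTTCATGCCT	T	C	C	T	G	A	C	G
UTR-18	0.0283	G	T	G	C	C	C	A	C	A
UTR-6	0.0125	G	T	G	C	C	C	A	C	G
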
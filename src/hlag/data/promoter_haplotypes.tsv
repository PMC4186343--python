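name	global_freq	-1305	-1179	-1155	-1140	-1138	-1121	-964	-762	-725	-716	-689	-666	-646	-633	-546	-541	-509	-486	-483	-477	-443	-400	-391	-369	-201	-56	15
010102a	0.2825	A	G	G	T	A	C	A	T	C	G	G	T	A	A	A	GA	C	C	A	G	G	G	G	A	A	C	A
010101a	0.2728	G	A	G	A	A	C	G	C	C	T	A	G	A	G	A	GA	C	A	A	C	G	G	G	C	G	C	G
010104a	0.1501	A	G	A	A	A	C	A	T	C	G	G	T	A	A	A	GA	C	C	A	G	G	G	G	A	A	C	A
010101b	0.052	G	A	G	A	A	C	G	C	G	T	A	G	A	G	A	GA	C	A	A	C	G	G	G	C	G	C	G
010101f	0.0446	G	A	G	A	A	C	G	C	C	T	A	G	A	G	A	G	C	A	A	C	G	G	G	C	G	C	G
010101c	0.0418	G	A	G	A	A	T	G	C	G	T	A	G	A	G	A	GA	C	A	A	C	G	G	G	C	G	C	G
010104b	0.0353	A	G	A	A	A	C	A	T	C	G	G	T	A	A	A	GA	C	C	A	G	A	G	G	A	A	C	A
010101d	0.026	G	A	G	A	A	C	G	C	C	T	A	G	A	G	A	GA	C	A	G	C	G	G	G	C	G	C	G
0103a	0.0191	G	G	G	A	G	C	G	C	T	T	A	G	A	G	AG	GA	G	A	A	G	G	A	A	A	G	T	G
0103e	0.0149	G	G	G	A	G	C	G	C	T	T	A	G	G	G	A	GA	G	A	A	G	G	A	A	A	G	T	G
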
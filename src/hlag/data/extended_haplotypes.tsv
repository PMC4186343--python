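promoter	coding	utr3	lineage	global_freq	label
010101a	G*01:01:01:01	UTR-1	HG010101a	0.24257	G010101a/G*01:01:01:01/UTR-1
010102a	G*01:01:02:01	UTR-2	HG010102	0.11803	G010102a/G*01:01:02:01/UTR-2
0104a	G*01:04:01	UTR-3	HG0104	0.09108	G0104a/G*01:04:01/UTR-3
010102a	G*01:01:03:03	UTR-7	HG010103	0.05112	G010102a/G*01:01:03:03/UTR-7
010101b	G*01:01:01:05	UTR-4	HG010101c	0.04786	G010101b/G*01:01:01:05/UTR-4
010101c	G*01:01:01:05	UTR-4	HG010101c	0.04136	G010101c/G*01:01:01:05/UTR-4
0104a	G*01:04:04	UTR-3	HG0104	0.03810	G0104a/G*01:04:04/UTR-3
0104b	G*01:04:01	UTR-3	HG0104	0.03392	G0104b/G*01:04:01/UTR-3
010101f	G*01:01:01:04	UTR-18	HG010101b	0.02835	G010101f/G*01:01:01:04/UTR-18
010102a	G*01:06	UTR-2	HG010102	0.02556	G010102a/G*01:06/UTR-2
010101d	G*01:01:01:01new	UTR-1	HG010101a	0.01859	G010101d/G*01:01:01:01new/UTR-1
010102a	G*01:05N	UTR-10	HG010102	0.01812	G010102a/G*01:05N/UTR-10
0103a	G*01:03:01:02	UTR-5	HG0103	0.01766	G0103a/G*01:03:01:02/UTR-5
010102a	G*01:05N	UTR-2	HG010102	0.01255	G010102a/G*01:05N/UTR-2
010102a	G*01:01:02:01	UTR-10	HG010102	0.01115	G010102a/G*01:01:02:01/UTR-10
0104a	G*01:04:01-Like	UTR-3	HG0104	0.00883	G0104a/G*01:04:01-Like/UTR-3
010101d	G*01:01:01:04-Like	UTR-1	HG010101a	0.00651	G010101d/G*01:01:01:04-Like/UTR-1
0103c	G*01:03:01:02	UTR-5	HG0103	0.00651	G0103c/G*01:03:01:02/UTR-5
010101f	G*01:01:01:04	UTR-6	HG010101b	0.00604	G010101f/G*01:01:01:04/UTR-6
010101a	G*01:01:01:06	UTR-4	HG010101*	0.00604	G010101a/G*01:01:01:06/UTR-4
010102a	G*01:01:03:03	UTR-7-Like	HG010103	0.00604	G010102a/G*01:01:03:03/UTR-7-Like
0103e	G*01:03:01:02	UTR-13	HG0103	0.00558	G0103e/G*01:03:01:02/UTR-13
010102a	Unknown/new	UTR-2	HG010102	0.00558	G010102a/unknown/UTR-2
010101a	G*01:01:09	UTR-4	HG010101*	0.00558	G010101a/G*01:01:09/UTR-4
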
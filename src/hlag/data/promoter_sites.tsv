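genomic_pos_hg19	rsid	gene_pos	ref	ref_freq	alt	alt_freq	alt2	alt2_freq	pos_label
29794317	rs1736936	-1305	G	0.4995	A	0.5005			
29794443	rs1736935	-1179	A	0.4466	G	0.5534			
29794467	rs3823321	-1155	G	0.8020	A	0.1980			
29794482	rs1736934	-1140	A	0.6952	T	0.3048			
29794484	rs17875389	-1138	A	0.9493	G	0.0507			
29794501	rs3115630	-1121	T	0.0428	C	0.9572			
29794524	rs146374870	-1098	G	0.9972	A	0.0028			
29794658	rs1632947	-964	G	0.4986	A	0.5014			
29794700	rs370338057	-922	C	0.9981	A	0.0019			
29794812	rs182801644	-810	C	0.9986	T	0.0014			
29794860	rs1632946	-762	C	0.4972	T	0.5028			
29794897	rs1233334	-725	G	0.0953	C	0.8550	T	0.0497	
29794906	rs2249863	-716	T	0.4963	G	0.5037			
29794933	rs2735022	-689	A	0.4963	G	0.5037			
29794956	rs35674592	-666	G	0.4981	T	0.5019			
29794976	rs17875391	-646	A	0.9749	G	0.0251			
29794989	rs1632944	-633	G	0.4995	A	0.5005			
29795076	rs201221694	-546	A	0.9744	AG	0.0256			-546/-540
29795081	rs368205133	-541	GA	0.9545	G	0.0455			-541/-533
29795083	rs112940953	-539	A	0.9967	G	0.0033			
29795101	rs138987412	-521	C	0.9986	A	0.0014			
29795113	rs17875393	-509	C	0.9559	G	0.0441			
29795136	rs1736933	-486	A	0.4991	C	0.5009			
29795139	rs149890776	-483	A	0.9717	G	0.0283			
29795145	rs1736932	-477	C	0.4461	G	0.5539			
29795179	rs17875394	-443	G	0.9638	A	0.0362			
29795222	rs17875395	-400	G	0.9559	A	0.0441			
29795231	rs17875396	-391	G	0.9559	A	0.0441			
29795253	rs1632943	-369	C	0.4480	A	0.5520			
29795267	rs191630481	-355	G	0.9967	A	0.0033			
29795338	.	-284	G	0.9991	A	0.0009			
29795366	.	-256	TC	0.9958	T	0.0042			
29795421	rs1233333	-201	G	0.4967	A	0.5033			
29795472	.	-150	C	0.9977	T	0.0023			
29795566	rs17875397	-56	C	0.9503	T	0.0497			
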
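population	group	n_chromosomes
CEU	Europe	170
TSI	Europe	196
GBR	Europe	174
FIN	Europe	184
IBS	Europe	28
CHB	Asia	192
CHS	Asia	200
JPT	Asia	178
YRI	Africa	174
LWK	Africa	188
ASW	Admixed	118
MXL	Admixed	124
PUR	Admixed	110
CLM	Admixed	116
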
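rank	Kg	subgroup	subgroup_index	K	protein	Ds_ud	Pr
1	45	x	1	1	β-catenin	6.809993	0.175768
2	46	x	2	2	p53	6.789229	0.171249
3	47	x	3	3	ESR1	4.513399	0.113285
4	48	x	4	4	STAT3	4.109638	0.104088
5	49	x	5	5	RelA	3.343309	0.085443
6	50	x	6	6	PPAR-γ	3.086237	0.070668
7	51	x	7	7	IKK-β	1.696330	0.043249
8	52	x	8	8	SNAIL1	1.477019	0.034269
9	53	x	9	10	MMP-14	1.368302	0.029121
10	2	t	2	9	TGF-β 1	1.081828	0.029166
11	54	x	10	12	Flotillin-1	0.787569	0.016863
12	3	t	3	13	TGF-β 2	0.333981	0.012451
13	4	t	4	20	TGF-β 3	0.159633	0.004157
14	1	t	1	30	TGF-β 0	0.081261	0.002090
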
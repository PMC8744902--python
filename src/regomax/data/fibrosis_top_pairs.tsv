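Ks	Kg_a	label_a	protein_a	Kg_b	label_b	protein_b	Dab
1	25	Kd=1	CLEC3B	53	Kx=9	MMP-14	0.263109
2	22	Ku=18	GALNT3	46	Kx=2	p53	0.259298
3	13	Ku=9	C1QTNF3	50	Kx=6	PPAR-γ	0.225877
4	26	Kd=2	SCARA5	52	Kx=8	SNAIL1	0.219938
5	27	Kd=3	SLC10A6	50	Kx=6	PPAR-γ	0.214345
6	29	Kd=5	MYOC	54	Kx=10	Flotillin-1	0.200157
7	19	Ku=15	LAMA1	46	Kx=2	p53	0.199892
8	43	Kd=19	FMO2	47	Kx=3	ESR1	0.196550
9	29	Kd=5	MYOC	45	Kx=1	β-catenin	0.196394
10	39	Kd=15	GFRA1	45	Kx=1	β-catenin	0.184019
11	6	Ku=2	FGF21	46	Kx=2	p53	0.182339
12	20	Ku=16	RAPGEF4	45	Kx=1	β-catenin	0.182303
13	28	Kd=4	CXCL5	46	Kx=2	p53	0.181444
14	10	Ku=6	ADAMTS8	45	Kx=1	β-catenin	0.177848
15	42	Kd=18	PEG10	45	Kx=1	β-catenin	0.177726
16	35	Kd=11	HMGCS2	45	Kx=1	β-catenin	0.177443
17	15	Ku=11	IL11	45	Kx=1	β-catenin	0.177227
18	35	Kd=11	HMGCS2	46	Kx=2	p53	0.176906
19	21	Ku=17	DNER	45	Kx=1	β-catenin	0.176820
20	11	Ku=7	MEGF6	45	Kx=1	β-catenin	0.176612
21	36	Kd=12	LGI2	45	Kx=1	β-catenin	0.176606
22	7	Ku=3	TNFSF18	45	Kx=1	β-catenin	0.176603
23	41	Kd=17	IL1R2	45	Kx=1	β-catenin	0.176598
24	14	Ku=10	ANO4	45	Kx=1	β-catenin	0.176556
25	34	Kd=10	GPR88	45	Kx=1	β-catenin	0.176432
26	23	Ku=19	ACSBG1	45	Kx=1	β-catenin	0.176323
27	5	Ku=1	ADAMTS16	45	Kx=1	β-catenin	0.176315
28	12	Ku=8	SV2B	45	Kx=1	β-catenin	0.176264
29	17	Ku=13	HTR2B	45	Kx=1	β-catenin	0.176197
30	16	Ku=12	CDH10	45	Kx=1	β-catenin	0.176192
31	24	Ku=20	OLFM2	45	Kx=1	β-catenin	0.176038
32	32	Kd=8	SELENBP1	45	Kx=1	β-catenin	0.175939
33	33	Kd=9	FMO1	45	Kx=1	β-catenin	0.175776
34	33	Kd=9	FMO1	46	Kx=2	p53	0.175367
35	30	Kd=6	IFITM1	45	Kx=1	β-catenin	0.175056
36	44	Kd=20	COX4I2	45	Kx=1	β-catenin	0.174371
37	23	Ku=19	ACSBG1	46	Kx=2	p53	0.174167
38	34	Kd=10	GPR88	46	Kx=2	p53	0.173893
39	5	Ku=1	ADAMTS16	46	Kx=2	p53	0.173822
40	14	Ku=10	ANO4	46	Kx=2	p53	0.173770
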
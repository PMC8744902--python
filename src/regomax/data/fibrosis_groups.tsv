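Kg	subgroup	subgroup_index	node_id	protein_name	K	Kstar	KM	KstarM
1	t	1	TGF-beta_0	TGF-β 0	30	37	10780	26299
2	t	2	TGF-beta_1	TGF-β 1	9	14	235	5690
3	t	3	TGF-beta_2	TGF-β 2	13	33	968	25073
4	t	4	TGF-beta_3	TGF-β 3	20	45	4726	29508
5	u	1	ADAMTS16	ADAMTS16	46	35	28737	25928
6	u	2	FGF21	FGF21	17	34	3478	25137
7	u	3	TNFSF18	TNFSF18	52	39	40048	28152
8	u	4	ACAN	ACAN	16	26	2467	19160
9	u	5	RPH3A	RPH3A	14	31	1489	24511
10	u	6	ADAMTS8	ADAMTS8	42	46	26600	29559
11	u	7	MEGF6	MEGF6	51	47	34769	39960
12	u	8	SV2B	SV2B	40	38	26295	27326
13	u	9	C1QTNF3	C1QTNF3	44	48	27111	36021
14	u	10	ANO4	ANO4	50	49	34616	39841
15	u	11	IL11	IL11	32	24	12696	16566
16	u	12	CDH10	CDH10	43	30	26624	23640
17	u	13	HTR2B	HTR2B	26	50	7263	30243
18	u	14	LAMA1	LAMA1	19	16	4647	6551
19	u	15	LAMA1_2	LAMA1	28	36	8342	26295
20	u	16	RAPGEF4	RAPGEF4	18	17	4021	8252
21	u	17	DNER	DNER	48	51	29945	36964
22	u	18	GALNT3	GALNT3	36	18	22159	8569
23	u	19	ACSBG1	ACSBG1	47	23	29145	15531
24	u	20	OLFM2	OLFM2	37	20	24786	8735
25	d	1	CLEC3B	CLEC3B	35	40	19039	28262
26	d	2	SCARA5	SCARA5	41	41	26477	28290
27	d	3	SLC10A6	SLC10A6	39	22	26109	11185
28	d	4	CXCL5	CXCL5	24	44	6360	29204
29	d	5	MYOC	MYOC	33	19	14952	8729
30	d	6	IFITM1	IFITM1	22	28	5961	22288
31	d	7	ANGPTL4	ANGPTL4	21	13	5599	4483
32	d	8	SELENBP1	SELENBP1	38	25	25538	17434
33	d	9	FMO1	FMO1	34	52	18938	33179
34	d	10	GPR88	GPR88	49	53	34080	39427
35	d	11	HMGCS2	HMGCS2	23	27	6276	22141
36	d	12	LGI2	LGI2	53	43	37060	28328
37	d	13	PTN	PTN	29	11	9162	2485
38	d	14	ADORA2A	ADORA2A	11	15	513	5974
39	d	15	GFRA1	GFRA1	27	29	7789	22652
40	d	16	IL1R2	IL1R2	25	21	6718	8844
41	d	17	IL1R2_2	IL1R2	54	42	35446	28306
42	d	18	PEG10	PEG10	31	12	12148	3444
43	d	19	FMO2	FMO2	45	54	27829	36195
44	d	20	COX4I2	COX4I2	15	32	1973	24994
45	x	1	beta-catenin	β-catenin	1	4	3	13
46	x	2	p53	p53	2	1	4	6
47	x	3	ESR1	ESR1	3	2	11	10
48	x	4	STAT3	STAT3	4	5	13	25
49	x	5	RelA	RelA	5	3	22	11
50	x	6	PPAR-gamma	PPAR-γ	6	6	38	82
51	x	7	IKK-beta	IKK-β	7	8	111	767
52	x	8	SNAIL1	SNAIL1	8	7	179	198
53	x	9	MMP-14	MMP-14	10	9	237	1520
54	x	10	Flotillin-1	Flotillin-1	12	10	578	2123
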
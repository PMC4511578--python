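# Per-query KB evaluation results for the ten GE'13 submissions.
# Columns: query, team, gold count (GS), system count (P), true positives (TP),
# and the published recall / precision / F1 percentages.
query	team	gs	p	tp	r	pr	f
Q1	EVEX	604	604	497	82.28	82.28	82.28
Q1	TEES-2.1	604	604	497	82.28	82.28	82.28
Q1	BioSEM	604	537	456	75.50	84.92	79.93
Q1	NCBI	604	647	493	81.62	76.20	78.82
Q1	DlutNLP	604	591	475	78.64	80.37	79.50
Q1	HDS4NLP	604	563	500	82.78	88.81	85.69
Q1	NICTANLM	604	748	501	82.95	66.98	74.11
Q1	USheff	604	452	386	63.91	85.40	73.11
Q1	UZH	604	496	404	66.89	81.45	73.45
Q1	HCMUS	604	763	481	79.64	63.04	70.37
Q2	EVEX	94	56	45	47.87	80.36	60.00
Q2	TEES-2.1	94	59	48	51.06	81.36	62.75
Q2	BioSEM	94	52	43	45.74	82.69	58.90
Q2	NCBI	94	46	38	40.43	82.61	54.29
Q2	DlutNLP	94	38	35	37.23	92.11	53.03
Q2	HDS4NLP	94	68	50	53.19	73.53	61.73
Q2	NICTANLM	94	52	30	31.91	57.69	41.10
Q2	USheff	94	26	23	24.47	88.46	38.33
Q2	UZH	94	40	34	36.17	85.00	50.75
Q2	HCMUS	94	68	31	32.98	45.59	38.27
Q3	EVEX	300	324	182	60.67	56.17	58.33
Q3	TEES-2.1	300	336	188	62.67	55.95	59.12
Q3	BioSEM	300	355	182	60.67	51.27	55.57
Q3	NCBI	300	318	177	59.00	55.66	57.28
Q3	DlutNLP	300	352	193	64.33	54.83	59.20
Q3	HDS4NLP	300	393	219	73.00	55.73	63.20
Q3	NICTANLM	300	369	175	58.33	47.43	52.32
Q3	USheff	300	252	156	52.00	61.90	56.52
Q3	UZH	300	255	143	47.67	56.08	51.53
Q3	HCMUS	300	491	207	69.00	42.16	52.34
Q4	EVEX	83	122	27	32.53	22.13	26.34
Q4	TEES-2.1	83	144	32	38.55	22.22	28.19
Q4	BioSEM	83	114	21	25.30	18.42	21.32
Q4	NCBI	83	167	24	28.92	14.37	19.20
Q4	DlutNLP	83	179	25	30.12	13.97	19.08
Q4	HDS4NLP	83	72	15	18.07	20.83	19.35
Q4	NICTANLM	83	177	21	25.30	11.86	16.15
Q4	USheff	83	43	13	15.66	30.23	20.63
Q4	UZH	83	0	0	0.00	0.00	0.00
Q4	HCMUS	83	75	19	22.89	25.33	24.05
Q5	EVEX	108	61	18	16.67	29.51	21.30
Q5	TEES-2.1	108	65	18	16.67	27.69	20.81
Q5	BioSEM	108	45	14	12.96	31.11	18.30
Q5	NCBI	108	34	8	7.41	23.53	11.27
Q5	DlutNLP	108	69	20	18.52	28.99	22.60
Q5	HDS4NLP	108	31	13	12.04	41.94	18.71
Q5	NICTANLM	108	31	5	4.63	16.13	7.19
Q5	USheff	108	18	5	4.63	27.78	7.94
Q5	UZH	108	6	0	0.00	0.00	0.00
Q5	HCMUS	108	94	9	8.33	9.57	8.91
Q6	EVEX	360	197	126	35.00	63.96	45.24
Q6	TEES-2.1	360	218	133	36.94	61.01	46.02
Q6	BioSEM	360	155	90	25.00	58.06	34.95
Q6	NCBI	360	103	69	19.17	66.99	29.81
Q6	DlutNLP	360	174	106	29.44	60.92	39.70
Q6	HDS4NLP	360	31	17	4.72	54.84	8.70
Q6	NICTANLM	360	112	64	17.78	57.14	27.12
Q6	USheff	360	60	35	9.72	58.33	16.67
Q6	UZH	360	21	8	2.22	38.10	4.20
Q6	HCMUS	360	156	33	9.17	21.15	12.79
Q7	EVEX	111	52	38	34.23	73.08	46.63
Q7	TEES-2.1	111	67	43	38.74	64.18	48.31
Q7	BioSEM	111	26	21	18.92	80.77	30.66
Q7	NCBI	111	37	25	22.52	67.57	33.78
Q7	DlutNLP	111	49	36	32.43	73.47	45.00
Q7	HDS4NLP	111	0	0	0.00	0.00	0.00
Q7	NICTANLM	111	42	24	21.62	57.14	31.37
Q7	USheff	111	31	20	18.02	64.52	28.17
Q7	UZH	111	10	2	1.80	20.00	3.31
Q7	HCMUS	111	38	16	14.41	42.11	21.48
Q8	EVEX	128	61	50	39.06	81.97	52.91
Q8	TEES-2.1	128	77	56	43.75	72.73	54.63
Q8	BioSEM	128	31	25	19.53	80.65	31.45
Q8	NCBI	128	37	32	25.00	86.49	38.79
Q8	DlutNLP	128	52	41	32.03	78.85	45.56
Q8	HDS4NLP	128	0	0	0.00	0.00	0.00
Q8	NICTANLM	128	40	30	23.44	75.00	35.71
Q8	USheff	128	29	20	15.63	68.97	25.48
Q8	UZH	128	10	3	2.34	30.00	4.35
Q8	HCMUS	128	38	16	12.50	42.11	19.28
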
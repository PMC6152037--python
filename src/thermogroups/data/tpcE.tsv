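entry	atom_type	neighbours	contribution	occurrences	molecules
1	Const		60.14	2686	2686
2	C sp3	H3C	5.33	5873	2490
3	C sp3	H3N	16.05	12	6
4	C sp3	H3O	2.66	195	172
5	C sp3	H3Si	3.08	110	5
6	C sp3	H2C2	4.04	30650	2478
7	C sp3	H2CN	-1.70	286	114
8	C sp3	H2CO	-0.01	3584	1901
9	C sp3	H2CS	-8.01	68	42
10	C sp3	H2CCl	-27.41	2	2
11	C sp3	H2CBr	-10.24	3	3
12	C sp3	H2CJ	30.88	1	1
13	C sp3	H2CSi	-2.48	6	3
14	C sp3	HC3	-9.84	1088	414
15	C sp3	HC2N	-17.47	4	4
16	C sp3	HC2O	-19.96	428	324
17	C sp3	HC2S	-42.59	18	18
18	C sp3	HC2Cl	-12.96	53	53
19	C sp3	HC2Br	6.97	4	4
20	C sp3	HCO2	7.19	34	28
21	C sp3	HCF2	-21.83	11	11
22	C sp3	C4	-0.53	212	120
23	C sp3	C3O	12.06	10	10
24	C sp3	C3F	-25.29	2	2
25	C sp3	C2F2	4.67	272	57
26	C sp3	CSF2	-1.17	5	5
27	C sp3	CF3	-8.30	67	54
28	C sp3	OF3	24.11	2	2
29	C sp3	SF3	-196.06	1	1
30	C sp2	H2=C	14.81	58	56
31	C sp2	HC=C	-2.97	946	440
32	C sp2	HC=N	-2.07	922	704
33	C sp2	HC=N(+)	32.39	9	9
34	C sp2	HC=O	15.32	6	6
35	C sp2	H=CN	-16.69	43	41
36	C sp2	H=CO	-2.30	28	28
37	C sp2	H=CS	-4.67	2	2
38	C sp2	H=NS	74.91	1	1
39	C sp2	C2=C	-13.21	186	160
40	C sp2	C2=N	9.17	17	17
41	C sp2	C2=O	2.80	266	202
42	C sp2	C=CN	2.69	28	21
43	C sp2	C=CO	-53.38	21	21
44	C sp2	C=CS	-5.66	340	150
45	C sp2	C=CF	31.70	10	5
46	C sp2	CN=N	-13.68	15	15
47	C sp2	CN=O	-1.75	326	171
48	C sp2	C=NO	-39.68	45	30
49	C sp2	CN=S	-6.95	8	6
50	C sp2	C=NS	38.49	105	77
51	C sp2	=CNS	-47.14	22	11
52	C sp2	CO=O	8.07	3115	1580
53	C sp2	=COS	128.10	5	5
54	C sp2	C=OS	5.46	91	81
55	C sp2	=CSCl	15.27	9	9
56	C sp2	=CSJ	10.36	2	2
57	C sp2	N=NS	-11.16	72	72
58	C sp2	NO=O	38.80	6	6
59	C sp2	=NOS	96.96	24	12
60	C sp2	O2=O	26.06	3	3
61	C aromatic	H:C2	3.37	28602	2538
62	C aromatic	H:C:N	-0.02	151	82
63	C aromatic	H:C:N(+)	-9.49	12	6
64	C aromatic	:C3	-8.40	322	107
65	C aromatic	C:C2	-9.58	7933	2410
66	C aromatic	C:C:N	-38.40	89	61
67	C aromatic	:C2N	-13.66	1866	1124
68	C aromatic	:C2N(+)	-5.68	135	119
69	C aromatic	:C2:N	16.73	34	33
70	C aromatic	:C2O	-4.24	5711	2230
71	C aromatic	:C2S	-29.84	116	105
72	C aromatic	:C2Si	10.60	4	2
73	C aromatic	:C2F	4.38	525	266
74	C aromatic	:C2Cl	-3.87	197	151
75	C aromatic	:C2Br	2.55	24	23
76	C aromatic	:C2J	-35.42	9	9
77	C aromatic	C:N2	-43.07	27	21
78	C aromatic	:C:NCl	-51.42	2	2
79	C aromatic	N:N2	-17.88	6	3
80	C aromatic	:N2O	-31.16	4	4
81	C sp	H#C	15.40	1	1
82	C sp	C#C	-1.90	929	304
83	C sp	=C2	-15.98	9	9
84	C sp	C#N	4.72	229	212
85	C sp	#CO	29.96	2	1
86	C sp	=N=O	0.85	3	2
87	C sp	=N=S	15.48	42	42
88	C sp	#NS	7.49	26	26
89	N sp3	H2C	-12.08	5	5
90	N sp3	H2C(pi)	-66.66	6	6
91	N sp3	HC2(pi)	18.61	17	9
92	N sp3	HC2(2pi)	-4.58	233	143
93	N sp3	HCN(pi)	-6.87	6	3
94	N sp3	HCN(2pi)	42.99	12	12
95	N sp3	HCS(pi)	157.30	1	1
96	N sp3	C3	-75.12	10	10
97	N sp3	C3(pi)	-20.84	64	33
98	N sp3	C3(2pi)	8.12	34	25
99	N sp3	C3(3pi)	29.75	24	14
100	N sp2	C=C	14.07	1014	778
101	N sp2	C=N	9.88	722	295
102	N sp2	C=N(+)	8.87	32	32
103	N sp2	=CN	-40.91	206	94
104	N sp2	=CO	33.53	26	26
105	N aromatic	:C2	18.59	169	125
106	N aromatic	:C:N	17.07	12	3
107	N(+) sp2	CO=O(-)	0.77	94	78
108	N(+) sp2	C=CO(-)	-3.27	9	9
109	N(+) sp2	C=NO(-)	0.00	32	32
110	N(+) aromatic	:C2O(-)	23.39	6	6
111	O	HC	20.86	186	70
112	O	HC(pi)	16.46	202	156
113	O	C2	1.72	100	57
114	O	C2(pi)	-0.12	3901	2018
115	O	C2(2pi)	-2.52	2419	1340
116	O	CN(2pi)	-4.06	26	26
117	S2	HC(pi)	-10.11	2	2
118	S2	C2	12.90	18	18
119	S2	C2(pi)	14.58	55	42
120	S2	C2(2pi)	15.10	379	314
121	S4	CN=O2	-36.49	1	1
122	Si	C3Si	0.00	10	5
123	Si	C2Si2	-3.55	45	5
124	H	H Acceptor	-17.84	151	107
125	Angle60		0.00	0	0
126	Angle90		0.00	0	0
127	Angle102		7.37	513	138
128	Endocyclic bonds	No of single bonds	-1.14	3024	309
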
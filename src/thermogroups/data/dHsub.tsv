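entry	atom_type	neighbours	contribution	occurrences	molecules
1	Const		21.03	1960	1960
2	B	C3	65.82	2	2
3	C sp3	H3C	5.99	1322	623
4	C sp3	H3N	26.96	143	87
5	C sp3	H3N(+)	98.98	1	1
6	C sp3	H3O	28.51	181	122
7	C sp3	H3S	30.06	7	6
8	C sp3	H2C2	6.88	2602	508
9	C sp3	H2CN	21.98	224	116
10	C sp3	H2CN(+)	27.46	13	11
11	C sp3	H2CO	29.62	242	134
12	C sp3	H2CS	23.29	50	31
13	C sp3	H2CF	15.91	1	1
14	C sp3	H2CCl	17.59	3	3
15	C sp3	H2CBr	22.76	5	4
16	C sp3	H2CJ	21.83	3	2
17	C sp3	H2N2	43.95	18	6
18	C sp3	H2NCl	36.29	1	1
19	C sp3	H2O2	53.35	25	13
20	C sp3	H2OS	54.78	1	1
21	C sp3	H2S2	47.45	6	4
22	C sp3	HBC2	-36.17	3	1
23	C sp3	HC3	2.28	509	190
24	C sp3	HC2N	14.28	34	30
25	C sp3	HC2N(+)	21.01	9	9
26	C sp3	HC2O	24.27	82	47
27	C sp3	HC2S	17.59	14	11
28	C sp3	HC2F	5.18	1	1
29	C sp3	HC2Cl	11.49	7	2
30	C sp3	HC2Br	-0.95	1	1
31	C sp3	HCN2	39.48	8	2
32	C sp3	HCN2(+)	39.93	2	2
33	C sp3	HCNO	34.73	2	1
34	C sp3	HCNS	20.56	2	1
35	C sp3	HCO2	39.96	3	3
36	C sp3	HCF2	-0.19	1	1
37	C sp3	HCCl2	15.78	1	1
38	C sp3	HN3(+)	37.31	1	1
39	C sp3	HO3	72.23	3	3
40	C sp3	C4	-4.25	209	137
41	C sp3	C3N	5.87	18	13
42	C sp3	C3N(+)	18.44	14	11
43	C sp3	C3O	15.18	40	31
44	C sp3	C3S	6.40	5	5
45	C sp3	C3F	1.89	3	3
46	C sp3	C3Cl	-8.06	1	1
47	C sp3	C3Br	2.34	1	1
48	C sp3	C2N2(+)	34.78	7	6
49	C sp3	C2O2	39.73	8	8
50	C sp3	C2S2	37.28	4	1
51	C sp3	C2F2	7.07	62	8
52	C sp3	CN3(+)	43.89	19	12
53	C sp3	CN2F(+)	25.98	1	1
54	C sp3	CO3	57.42	2	2
55	C sp3	CF3	-4.71	27	23
56	C sp3	CCl3	16.10	3	2
57	C sp3	N3F(+)	44.00	1	1
58	C sp3	O4	73.43	1	1
59	C sp2	H2=C	7.97	12	12
60	C sp2	HC=C	5.10	452	213
61	C sp2	HC=N	35.49	21	19
62	C sp2	HC=N(+)	72.64	7	7
63	C sp2	H=CN	32.79	83	69
64	C sp2	HC=O	20.74	15	15
65	C sp2	H=CO	16.89	16	14
66	C sp2	H=CS	15.22	49	36
67	C sp2	HN=N	55.52	19	18
68	C sp2	HN=O	35.41	4	3
69	C sp2	H=NO	40.91	1	1
70	C sp2	H=NS	33.85	2	2
71	C sp2	C2=C	3.91	78	61
72	C sp2	C2=N	30.47	35	26
73	C sp2	C2=N(+)	13.76	5	5
74	C sp2	C=CN	26.81	57	48
75	C sp2	C=CN(+)	41.65	7	7
76	C sp2	C2=O	15.10	200	161
77	C sp2	C=CO	22.08	40	31
78	C sp2	C2=S	18.21	3	3
79	C sp2	C=CS	15.64	36	27
80	C sp2	C=CF	16.81	2	2
81	C sp2	C=CCl	11.02	9	5
82	C sp2	C=CBr	34.06	2	2
83	C sp2	C=CJ	32.46	1	1
84	C sp2	=CN2	64.94	6	6
85	C sp2	=CN2(+)	60.65	4	4
86	C sp2	CN=N	54.51	27	25
87	C sp2	CN=N(+)	44.16	3	3
88	C sp2	CN=O	39.66	234	194
89	C sp2	C=NO	42.74	2	2
90	C sp2	CN=S	39.85	8	7
91	C sp2	C=NS	34.89	1	1
92	C sp2	=CNS(+)	41.29	2	2
93	C sp2	=CNCl	38.14	4	3
94	C sp2	CO=O	34.06	424	345
95	C sp2	CO=O(-)	80.89	22	22
96	C sp2	C=OCl	29.03	1	1
97	C sp2	CS=S	56.97	3	3
98	C sp2	N2=N	80.72	4	4
99	C sp2	N2=N(+)	65.95	6	5
100	C sp2	N2=O	59.57	76	70
101	C sp2	N2=S	66.62	29	29
102	C sp2	N=NS	51.62	22	22
103	C sp2	NO=O	52.79	8	8
104	C sp2	=NO2	61.12	1	1
105	C sp2	N=OS	48.27	1	1
106	C sp2	NO=S	58.04	11	11
107	C sp2	=NOS	52.75	1	1
108	C sp2	NS=S	60.83	5	3
109	C sp2	=NS2	64.37	1	1
110	C sp2	O2=O	41.40	7	7
111	C sp2	=OS2	41.22	2	2
112	C sp2	OS=S	73.06	1	1
113	C sp2	S2=S	49.39	5	5
114	C aromatic	H:C2	5.36	7115	1269
115	C aromatic	H:C:N	18.20	150	96
116	C aromatic	H:C:N(+)	28.26	48	28
117	C aromatic	H:N2	23.27	7	5
118	C aromatic	B:C2	-25.04	3	1
119	C aromatic	:C3	5.51	454	155
120	C aromatic	C:C2	3.12	1684	835
121	C aromatic	C:C:N	11.10	80	48
122	C aromatic	C:C:N(+)	16.04	33	21
123	C aromatic	:C2N	22.21	354	258
124	C aromatic	:C2N(+)	28.67	169	134
125	C aromatic	:C2:N	17.03	79	61
126	C aromatic	:C2:N(+)	18.05	35	20
127	C aromatic	:C2O	20.46	617	387
128	C aromatic	:C2P	-1.63	12	4
129	C aromatic	:C2S	16.31	80	64
130	C aromatic	:C2F	4.45	77	42
131	C aromatic	:C2Cl	12.48	424	166
132	C aromatic	:C2Br	14.66	63	43
133	C aromatic	:C2J	20.68	31	27
134	C aromatic	:C2Si	4.80	10	2
135	C aromatic	C:N2	28.80	4	2
136	C aromatic	:CN:N	29.72	11	9
137	C aromatic	:CN:N(+)	33.74	3	2
138	C aromatic	:C:NO	41.44	13	12
139	C aromatic	:C:NO(+)	33.50	5	5
140	C aromatic	:C:NCl	21.70	18	13
141	C aromatic	:C:NBr	31.31	3	2
142	C aromatic	N:N2	43.11	13	8
143	C aromatic	:N2O	39.92	3	1
144	C aromatic	:N2S	36.08	3	3
145	C aromatic	:N2Cl	35.90	3	3
146	C sp	=C2	6.39	3	2
147	C sp	C#C	3.24	14	7
148	C sp	C#N	16.49	96	67
149	C sp	C#N(+)	11.33	4	3
150	C sp	#CS	28.03	2	2
151	C sp	N#N	47.80	1	1
152	C sp	#NP	12.53	3	1
153	N sp3	H2C	5.03	23	12
154	N sp3	H2C(pi)	6.38	223	199
155	N sp3	H2N	17.97	10	8
156	N sp3	H2S	41.98	1	1
157	N sp3	HC2	-23.83	14	13
158	N sp3	HC2(pi)	-13.51	72	55
159	N sp3	HC2(2pi)	-20.10	200	165
160	N sp3	HCN	-0.15	2	1
161	N sp3	HCN(pi)	6.71	14	9
162	N sp3	HCN(2pi)	-6.84	25	25
163	N sp3	HCS(pi)	-15.10	20	20
164	N sp3	C3	-51.07	16	11
165	N sp3	C3(pi)	-53.90	59	49
166	N sp3	C3(2pi)	-60.80	72	54
167	N sp3	C3(3pi)	-61.26	18	14
168	N sp3	C2N(pi)	-7.05	6	3
169	N sp3	C2N(+)(pi)	-5.52	24	9
170	N sp3	C2N(2pi)	-36.36	4	4
171	N sp3	C2N(+)(2pi)	-20.13	1	1
172	N sp3	C2N(3pi)	-54.74	3	3
173	N sp3	C2S	-49.13	4	2
174	N sp3	C2F(2pi)	-64.78	1	1
175	N sp3	CN2(pi)	30.74	4	3
176	N sp3	CN2(2pi)	-49.40	3	3
177	N sp3	CN2(+)(2pi)	3.72	1	1
178	N sp3	CNF(2pi)	-34.74	5	4
179	N sp2	C=C	-32.77	79	74
180	N sp2	C=N	-4.54	13	9
181	N sp2	C=N(+)	-15.43	5	5
182	N sp2	=CN	-4.63	38	36
183	N sp2	=CN(+)	36.68	1	1
184	N sp2	C=O	-12.04	9	9
185	N sp2	C=P	-49.18	1	1
186	N sp2	=CO	-16.24	18	13
187	N sp2	=CS	-26.78	10	8
188	N sp2	N=N	12.19	21	13
189	N sp2	N=O	0.00	10	6
190	N sp2	=NO	-6.67	2	1
191	N aromatic	:C2	-14.01	208	145
192	N aromatic	:C:N	-4.98	4	2
193	N(+) sp3	H3C	2.77	13	13
194	N(+) sp3	H2C2	-82.36	3	3
195	N(+) sp2	C=CO(-)	-68.61	7	7
196	N(+) sp2	C=NO	-26.37	10	5
197	N(+) sp2	C=NO(-)	-11.30	3	3
198	N(+) sp2	CO=O(-)	-4.38	270	163
199	N(+) sp2	=CO2(-)	2.17	5	5
200	N(+) sp2	NO=O(-)	0.15	28	12
201	N(+) sp2	O2=O(-)	6.00	14	6
202	N(+) aromatic	H:C2	-46.79	6	6
203	N(+) aromatic	:C2O(-)	-7.10	56	40
204	N(+) sp	C#C(-)	-14.36	3	3
205	N(+) sp	#CO(-)	0.00	4	3
206	N(+) sp	=N2(-)	19.14	2	2
207	O	HC	4.49	143	92
208	O	HC(pi)	8.19	560	470
209	O	HN(pi)	2.28	4	3
210	O	HO	29.95	4	4
211	O	C2	-39.23	94	37
212	O	C2(pi)	-31.33	292	201
213	O	C2(2pi)	-24.06	147	121
214	O	CN(pi)	0.00	2	1
215	O	CN(+)(pi)	0.00	14	6
216	O	CN(2pi)	4.91	1	1
217	O	CO(pi)	-27.16	8	6
218	O	CP(pi)	-16.12	3	1
219	O	N2(2pi)	5.87	4	4
220	O	N2(+)(2pi)	6.27	5	5
221	P3	C3	16.70	2	2
222	P3	S3	-66.68	1	1
223	P4	C3=N	0.00	1	1
224	P4	C3=O	-30.50	1	1
225	P4	C3=S	46.30	1	1
226	P4	O3=O	0.00	1	1
227	S2	HC	-2.58	1	1
228	S2	HC(pi)	18.47	2	2
229	S2	C2	-22.69	19	12
230	S2	C2(pi)	-15.86	34	29
231	S2	C2(2pi)	-7.94	59	49
232	S2	CN(pi)	25.96	1	1
233	S2	CN(2pi)	-6.82	6	6
234	S2	CS(pi)	-6.16	8	4
235	S2	CP(pi)	0.00	3	1
236	S2	N2	-2.00	1	1
237	S2	N2(2pi)	21.36	2	2
238	S2	NS	1.00	2	1
239	S4	C2=O	-5.89	2	2
240	S4	C2=O2	-4.26	27	27
241	S4	CN=O2	9.20	20	20
242	Si	C4	2.02	1	1
243	Si	C3Si	-0.67	2	1
244	H	H Acceptor	-8.63	107	89
245	Alkane	No. of C atoms	-0.53	849	59
246	Unsaturated HC	No. of C atoms	-0.10	2679	148
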
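entry	atom_type	neighbours	contribution	occurrences	molecules
1	Const		31.12	2809	2809
2	B	C3	12.34	2	2
3	B	CO2	51.11	5	5
4	C sp3	H3B	-4.93	3	1
5	C sp3	H2BC	4.93	3	1
6	C sp3	H3C	1.90	2944	1402
7	C sp3	H3N	15.63	279	149
8	C sp3	H3N(+)	7.07	2	2
9	C sp3	H3O	14.42	366	232
10	C sp3	H3P	21.07	3	3
11	C sp3	H3S	12.93	35	31
12	C sp3	H3Si	8.19	283	46
13	C sp3	H2C2	8.46	8600	1239
14	C sp3	H2CN	14.85	505	257
15	C sp3	H2CN(+)	19.09	29	21
16	C sp3	H2CO	14.52	952	473
17	C sp3	H2CP	17.50	3	2
18	C sp3	H2CS	16.77	166	83
19	C sp3	H2CF	12.36	1	1
20	C sp3	H2CCl	10.67	30	24
21	C sp3	H2CBr	11.79	24	17
22	C sp3	H2CJ	3.10	2	2
23	C sp3	H2CSi	8.50	62	20
24	C sp3	H2N2	5.03	20	11
25	C sp3	H2NO	8.98	8	7
26	C sp3	H2NS	43.70	4	4
27	C sp3	H2O2	22.34	23	14
28	C sp3	H2S2	29.21	7	5
29	C sp3	H2SCl	22.89	1	1
30	C sp3	H2Si2	12.02	6	3
31	C sp3	HC3	0.64	817	388
32	C sp3	HC2N	18.09	117	103
33	C sp3	HC2N(+)	-9.91	16	16
34	C sp3	HC2O	10.63	357	226
35	C sp3	HC2S	9.80	18	13
36	C sp3	HC2F	8.23	2	2
37	C sp3	HC2Cl	10.38	22	10
38	C sp3	HC2Br	8.94	5	4
39	C sp3	HC2Si	-14.02	1	1
40	C sp3	HCN2	1.21	2	1
41	C sp3	HCNO	23.14	7	6
42	C sp3	HCNS	23.70	1	1
43	C sp3	HCO2	19.18	30	26
44	C sp3	HCOCl	19.13	2	1
45	C sp3	HCF2	4.20	4	4
46	C sp3	HCFCl	-10.16	1	1
47	C sp3	HCCl2	9.01	10	9
48	C sp3	HCClBr	-3.80	1	1
49	C sp3	C4	-0.23	435	256
50	C sp3	C3N	14.87	22	20
51	C sp3	C3N(+)	12.86	6	5
52	C sp3	C3O	4.63	81	74
53	C sp3	C3S	16.54	6	6
54	C sp3	C3F	18.64	14	12
55	C sp3	C3Cl	9.23	14	9
56	C sp3	C3Br	3.44	2	2
57	C sp3	C3J	31.10	1	1
58	C sp3	C2N2	52.69	3	2
59	C sp3	C2N2(+)	4.24	7	6
60	C sp3	C2NO	34.66	1	1
61	C sp3	C2NF	47.27	1	1
62	C sp3	C2NCl(+)	13.35	1	1
63	C sp3	C2O2	13.44	47	29
64	C sp3	C2S2	10.13	1	1
65	C sp3	C2F2	-0.09	262	37
66	C sp3	C2Cl2	10.32	9	7
67	C sp3	CN3(+)	7.29	6	5
68	C sp3	CNF2	6.86	7	3
69	C sp3	COF2	-3.57	4	3
70	C sp3	CS3	30.56	4	1
71	C sp3	CSF2	41.61	2	1
72	C sp3	CSCl2	46.90	2	2
73	C sp3	CF3	3.38	91	76
74	C sp3	CF2Cl	-1.55	6	5
75	C sp3	CF2Br	8.94	4	3
76	C sp3	CFCl2	-6.89	3	2
77	C sp3	CCl3	0.92	17	16
78	C sp3	NF3	11.04	1	1
79	C sp3	O2F2	20.23	1	1
80	C sp3	OF3	2.25	2	2
81	C sp3	SF3	24.96	4	4
82	C sp3	SCl3	46.90	1	1
83	C sp3	SiCl3	14.20	1	1
84	C sp2	H2=C	5.49	84	76
85	C sp2	HC=C	2.46	607	323
86	C sp2	HC=N	-0.81	48	40
87	C sp2	H=CN	3.18	44	37
88	C sp2	HC=O	8.29	18	18
89	C sp2	H=CO	5.29	19	17
90	C sp2	H=CS	-1.85	43	33
91	C sp2	H=CCl	10.11	3	3
92	C sp2	H=CSi	2.92	3	3
93	C sp2	HN=N	9.78	30	22
94	C sp2	HN=O	-10.25	3	3
95	C sp2	H=NO	21.94	1	1
96	C sp2	H=NS	1.04	4	4
97	C sp2	HO=O	14.63	2	2
98	C sp2	C2=C	0.30	212	166
99	C sp2	C2=N	7.33	35	33
100	C sp2	C2=N(+)	2.31	1	1
101	C sp2	C=CN	-2.70	51	45
102	C sp2	C=CN(+)	0.00	2	1
103	C sp2	C2=O	1.57	386	298
104	C sp2	C=CO	5.58	70	52
105	C sp2	C=CS	0.18	38	25
106	C sp2	C=CCl	3.68	20	13
107	C sp2	C=CBr	45.90	1	1
108	C sp2	=CN2	12.85	17	17
109	C sp2	=CN2(+)	6.14	1	1
110	C sp2	CN=N	1.47	25	19
111	C sp2	=CNO	-1.47	6	4
112	C sp2	CN=O	0.63	366	234
113	C sp2	C=NO	9.33	5	5
114	C sp2	C=NS	7.20	7	7
115	C sp2	CN=S	-2.87	10	8
116	C sp2	=CNCl	11.25	1	1
117	C sp2	CO=O	5.68	718	546
118	C sp2	CO=O(-)	-16.84	19	19
119	C sp2	C=OF	9.78	3	2
120	C sp2	C=OCl	14.97	2	1
121	C sp2	C=OS	16.72	1	1
122	C sp2	=CS2	-7.29	12	2
123	C sp2	=CSCl	2.93	3	2
124	C sp2	=CSBr	-4.03	1	1
125	C sp2	=CF2	11.60	3	2
126	C sp2	=CFCl	1.87	1	1
127	C sp2	=CCl2	5.32	9	8
128	C sp2	=CBr2	46.05	1	1
129	C sp2	N2=N	11.87	9	9
130	C sp2	N2=O	-3.48	90	84
131	C sp2	N=NO	3.41	1	1
132	C sp2	N2=S	0.55	32	31
133	C sp2	N=NS	-3.08	23	23
134	C sp2	NO=O	0.38	62	60
135	C sp2	N=OS	20.86	2	2
136	C sp2	NO=S	-2.08	8	8
137	C sp2	NS=S	25.24	3	3
138	C sp2	=NS2	-12.86	2	2
139	C sp2	O2=O	-9.60	10	10
140	C sp2	=OS2	6.53	1	1
141	C aromatic	B:C2	-47.51	5	5
142	C aromatic	H:C2	2.57	8600	1498
143	C aromatic	H:C:N	1.17	108	68
144	C aromatic	H:N2	-1.12	5	3
145	C aromatic	:C3	-1.60	481	153
146	C aromatic	C:C2	-2.58	2198	1062
147	C aromatic	C:C:N	5.44	46	38
148	C aromatic	:C2N	-0.38	524	389
149	C aromatic	:C2:N	-5.26	33	20
150	C aromatic	:C2N(+)	4.26	203	144
151	C aromatic	:C2O	2.82	853	532
152	C aromatic	:C2P	-2.68	12	5
153	C aromatic	:C2S	0.30	98	73
154	C aromatic	:C2Si	3.80	45	21
155	C aromatic	:C2F	4.24	150	69
156	C aromatic	:C2Cl	5.68	860	318
157	C aromatic	:C2Br	4.73	92	57
158	C aromatic	:C2J	6.30	26	19
159	C aromatic	:CN:N	5.87	28	27
160	C aromatic	:CN:N(+)	0.05	2	1
161	C aromatic	:C:NO	3.76	9	7
162	C aromatic	:C:NS	2.70	2	1
163	C aromatic	:C:NCl	9.38	8	8
164	C aromatic	N:N2	-9.59	85	40
165	C aromatic	:N2O	-5.16	4	2
166	C aromatic	:N2S	-2.43	5	5
167	C aromatic	:N2Cl	19.07	8	7
168	C sp	H#C	2.83	26	23
169	C sp	C#C	-0.52	183	83
170	C sp	=C2	7.54	4	4
171	C sp	C#N	2.66	120	94
172	C sp	#CSi	3.40	3	2
173	C sp	N#N	-16.19	1	1
174	C sp	=N2	23.07	1	1
175	C sp	#NO	6.78	10	4
176	C sp	=N=O	14.08	6	3
177	N sp3	H2C	9.39	34	21
178	N sp3	H2C(pi)	7.89	190	160
179	N sp3	H2N	0.92	5	5
180	N sp3	H2P	-16.37	1	1
181	N sp3	H2S	10.07	7	7
182	N sp3	HC2	-1.65	20	20
183	N sp3	HC2(pi)	-9.81	190	133
184	N sp3	HC2(2pi)	4.73	204	169
185	N sp3	HCN	-5.80	4	3
186	N sp3	HCN(pi)	-2.85	8	6
187	N sp3	HCN(+)(pi)	16.06	4	2
188	N sp3	HCN(2pi)	0.95	12	11
189	N sp3	HCO(pi)	30.19	1	1
190	N sp3	HCP	-6.83	2	2
191	N sp3	HCS	17.10	2	2
192	N sp3	HCS(pi)	9.38	22	22
193	N sp3	HSi2	1.67	7	2
194	N sp3	C3	-32.04	41	37
195	N sp3	C3(pi)	-17.08	137	97
196	N sp3	C3(2pi)	-12.64	136	108
197	N sp3	C3(3pi)	4.26	22	20
198	N sp3	C2N	-18.10	3	3
199	N sp3	C2N(pi)	-6.67	7	5
200	N sp3	C2N(+)(pi)	20.95	32	17
201	N sp3	C2N(2pi)	-3.87	15	14
202	N sp3	C2N(3pi)	1.17	6	6
203	N sp3	C2N(+)(2pi)	-0.16	12	12
204	N sp3	C2O	-41.10	5	5
205	N sp3	C2O(pi)	9.25	39	15
206	N sp3	C2O(2pi)	29.03	1	1
207	N sp3	C2P	7.24	1	1
208	N sp3	C2S	-25.22	3	3
209	N sp3	C2S(pi)	-22.07	1	1
210	N sp3	C2S(2pi)	-6.25	3	3
211	N sp3	CF2	-2.10	6	2
212	N(+) sp3	H2C2	4.33	19	19
213	N(+) sp3	C3O(-)	-33.09	1	1
214	N sp2	H=C	16.94	3	3
215	N sp2	C=C	-7.28	122	101
216	N sp2	C=N	-11.24	64	32
217	N sp2	C=N(+)	10.95	10	7
218	N sp2	=CN	-0.51	38	31
219	N sp2	=CO	0.98	32	31
220	N sp2	=CS	-4.17	3	2
221	N sp2	N=N	-0.32	10	6
222	N sp2	N=O	18.24	4	2
223	N aromatic	:C2	5.43	222	128
224	N aromatic	:C:N	-4.60	6	3
225	N(+) sp2	C=NO(-)	-19.90	4	4
226	N(+) sp2	CO=O(-)	1.45	248	163
227	N(+) sp2	=CO2(-)	-3.88	1	1
228	N(+) sp2	NO=O(-)	-1.33	48	31
229	N(+) sp2	O2=O(-)	1.85	7	5
230	N(+) sp	C#C(-)	10.24	1	1
231	N(+) sp	=N2(-)	2.76	6	3
232	O	HC	-2.00	452	254
233	O	HC(pi)	3.39	478	400
234	O	HN	0.63	36	12
235	O	HN(pi)	-1.02	19	19
236	O	HP	-8.39	2	1
237	O	HS	60.03	5	2
238	O	BC	0.00	5	5
239	O	BN	0.00	5	5
240	O	C2	-4.67	357	135
241	O	C2(pi)	-5.72	740	513
242	O	C2(2pi)	-3.04	267	217
243	O	CN	-20.33	4	4
244	O	CN(pi)	0.00	1	1
245	O	CN(2pi)	1.82	12	11
246	O	CN(+)(pi)	0.47	7	5
247	O	CO	1.80	8	4
248	O	CP	-6.11	47	25
249	O	CP(pi)	6.35	20	17
250	O	CS(pi)	1.11	3	3
251	O	CSi	-12.94	5	2
252	O	N2(2pi)		0	0
253	O	N2(+)(2pi)	0.00	1	1
254	O	Si2	2.53	84	24
255	P3	C3	-6.01	3	2
256	P4	C3=O	-6.07	1	1
257	P4	C=OF2	-1.93	1	1
258	P4	C=OFCl	-4.92	1	1
259	P4	C=OCl2	6.84	1	1
260	P4	N2O=O	6.11	1	1
261	P4	NO2=O	-7.48	1	1
262	P4	NOS=S	6.11	1	1
263	P4	O3=O	-5.29	2	2
264	P4	O3=S	-3.13	13	12
265	P4	CO2=O	0.00	1	1
266	P4	CO2=S	7.66	2	2
267	P4	O2S=S	-5.52	7	7
268	S2	HC	-0.29	19	19
269	S2	HC(pi)	-11.91	2	2
270	S2	C2	-10.10	74	47
271	S2	C2(pi)	1.44	44	37
272	S2	C2(2pi)	8.54	74	60
273	S2	CN	0.00	3	3
274	S2	CN(pi)	5.57	1	1
275	S2	CS	1.49	8	4
276	S2	CS(pi)	0.18	6	4
277	S2	CP	0.00	8	8
278	S2	N2(2pi)	-3.71	1	1
279	S4	C2=O	-10.46	6	4
280	S4	C2=O2	-10.18	22	22
281	S4	CN=O2	1.23	31	31
282	S4	CO=O2	0.00	8	5
283	S4	C=OS	4.07	2	2
284	S4	N2=O2	4.49	2	2
285	Si	H3C	0.00	1	1
286	Si	HC2O	-77.65	3	3
287	Si	HCO2	18.28	1	1
288	Si	C4	-12.05	23	18
289	Si	C3O	-15.58	14	9
290	Si	C3Cl	-8.02	2	2
291	Si	C3Si	-6.42	6	3
292	Si	C2N2	0.00	7	2
293	Si	C2O2	1.03	75	18
294	Si	C2Cl2	-1.79	2	2
295	Si	C2Si2	-10.09	34	5
296	Si	CCl3	4.64	8	7
297	Si	O4	13.30	1	1
298	H	H Acceptor	6.31	153	128
299	Angle60		0.54	120	33
300	Angle90		2.37	138	29
301	Angle102		0.12	1131	342
302	Endocyclic bonds	No. of single bonds	-4.42	5302	680
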
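entry	atom_type	neighbours	contribution	occurrences	molecules
1	Const		8.61	3581	3581
2	B	C3	21.55	2	2
3	B	N2Cl	33.19	1	1
4	B	NCl2	28.59	1	1
5	B	O2Cl	28.23	2	2
6	B	OCl2	25.53	1	1
7	B	S3	76.74	4	4
8	C sp3	H3C	3.07	5380	2388
9	C sp3	H3N	15.65	242	133
10	C sp3	H3N(+)	31.33	2	2
11	C sp3	H3O	16.71	372	263
12	C sp3	H3S	14.44	31	25
13	C sp3	H3P	9.04	6	4
14	C sp3	H3Si	5.87	136	53
15	C sp3	H2BC	-3.07	6	2
16	C sp3	H2C2	4.67	10588	2030
17	C sp3	H2CN	15.00	430	243
18	C sp3	H2CN(+)	29.15	10	9
19	C sp3	H2CO	15.79	1147	779
20	C sp3	H2CS	15.50	159	101
21	C sp3	H2CP	6.67	6	2
22	C sp3	H2CF	6.20	11	11
23	C sp3	H2CCl	14.13	76	65
24	C sp3	H2CBr	16.69	24	21
25	C sp3	H2CJ	20.90	29	26
26	C sp3	H2CSi	2.01	134	54
27	C sp3	H2N2	28.27	5	3
28	C sp3	H2NO	20.46	4	4
29	C sp3	H2O2	27.43	19	16
30	C sp3	H2OS	22.40	1	1
31	C sp3	H2OF	18.90	1	1
32	C sp3	H2OCl	23.06	2	2
33	C sp3	H2OSi	10.30	1	1
34	C sp3	H2S2	24.08	2	2
35	C sp3	H2SSi	6.66	9	9
36	C sp3	H2Si2	2.87	2	1
37	C sp3	HC3	3.54	939	615
38	C sp3	HC2N	12.69	75	64
39	C sp3	HC2N(+)	28.39	3	3
40	C sp3	HC2O	14.99	243	203
41	C sp3	HC2S	13.61	26	22
42	C sp3	HC2Si	7.20	6	4
43	C sp3	HC2F	5.96	7	6
44	C sp3	HC2Cl	9.66	40	38
45	C sp3	HC2Br	12.12	21	16
46	C sp3	HC2J	18.79	4	4
47	C sp3	HCN2(+)	47.10	3	3
48	C sp3	HCO2	25.39	25	22
49	C sp3	HCOCl	20.93	1	1
50	C sp3	HCF2	7.10	15	14
51	C sp3	HCFCl	12.61	15	15
52	C sp3	HCCl2	16.96	23	22
53	C sp3	HCClBr	18.23	1	1
54	C sp3	HNO2	32.31	1	1
55	C sp3	HO3	37.33	4	4
56	C sp3	HOF2	17.06	7	7
57	C sp3	HOFCl	20.49	1	1
58	C sp3	HSiCl2	23.89	1	1
59	C sp3	C4	1.92	335	274
60	C sp3	C3N	12.60	28	23
61	C sp3	C3N(+)	26.15	4	4
62	C sp3	C3O	12.21	135	116
63	C sp3	C3S	13.69	18	16
64	C sp3	C3F	2.94	31	19
65	C sp3	C3Cl	7.77	8	6
66	C sp3	C3Br	11.95	3	3
67	C sp3	C3J	19.63	2	2
68	C sp3	C2NO	20.34	1	1
69	C sp3	C2NF	8.88	1	1
70	C sp3	C2O2	23.16	35	27
71	C sp3	C2OF	18.38	3	3
72	C sp3	C2F2	4.75	328	70
73	C sp3	C2FCl	8.73	5	5
74	C sp3	C2Cl2	13.35	5	5
75	C sp3	CN3(+)	46.89	3	3
76	C sp3	CNF2	15.25	15	6
77	C sp3	CNF2(+)	30.77	3	2
78	C sp3	CN2F(+)	28.25	4	3
79	C sp3	CO3	28.48	6	6
80	C sp3	COF2	13.65	36	30
81	C sp3	COCl2	20.61	4	4
82	C sp3	CSF2	12.70	2	1
83	C sp3	CF3	2.96	147	90
84	C sp3	CF2Cl	6.64	10	9
85	C sp3	CF2Br	9.02	5	4
86	C sp3	CFCl2	13.41	7	7
87	C sp3	CFClBr	17.37	1	1
88	C sp3	CCl3	17.43	22	21
89	C sp3	NF3	14.48	5	4
90	C sp3	NF3(+)	-1.76	2	1
91	C sp3	N3F(+)	32.36	1	1
92	C sp3	O4	38.15	2	2
93	C sp3	O2F2	24.80	14	2
94	C sp3	OF3	9.71	9	7
95	C sp3	OF2Cl	17.84	2	2
96	C sp3	OCl3	27.40	2	2
97	C sp3	PF3	2.73	2	1
98	C sp2	H2=C	2.17	182	170
99	C sp2	HC=C	5.03	1314	694
100	C sp2	HC=N	8.81	15	15
101	C sp2	HC=O	11.44	122	122
102	C sp2	H=CN	17.18	103	57
103	C sp2	H=CO	10.25	35	32
104	C sp2	H=CS	8.20	49	35
105	C sp2	H=CSi	10.77	4	4
106	C sp2	H=CF	-0.09	1	1
107	C sp2	H=CCl	10.38	8	6
108	C sp2	H=CBr	13.73	1	1
109	C sp2	HN=N	30.13	39	39
110	C sp2	HN=O	34.46	6	6
111	C sp2	H=NO	14.07	1	1
112	C sp2	H=NS	18.07	2	2
113	C sp2	HO=O	18.86	14	12
114	C sp2	C2=C	5.27	220	190
115	C sp2	C2=N	8.22	15	14
116	C sp2	C2=O	13.59	149	140
117	C sp2	C=CN	15.36	14	10
118	C sp2	C=CO	12.54	39	31
119	C sp2	C2=S	71.29	2	2
120	C sp2	C=CS	9.45	29	24
121	C sp2	C=CF	2.72	11	5
122	C sp2	C=CCl	5.83	8	5
123	C sp2	C=CBr	15.79	1	1
124	C sp2	=CN2	9.12	3	2
125	C sp2	CN=N	28.80	16	16
126	C sp2	CN=N(+)	11.32	2	2
127	C sp2	CN=O	35.35	47	47
128	C sp2	C=NO	22.79	5	5
129	C sp2	CN=S	18.27	3	2
130	C sp2	C=NS	17.49	1	1
131	C sp2	C=NCl	11.93	1	1
132	C sp2	=CNCl	22.67	2	1
133	C sp2	CO=O	17.20	684	594
134	C sp2	=COS	17.48	1	1
135	C sp2	C=OS	12.33	9	9
136	C sp2	=COF	15.53	1	1
137	C sp2	C=OCl	15.41	11	9
138	C sp2	C=OBr	22.28	3	3
139	C sp2	C=OJ	25.82	2	2
140	C sp2	=CF2	-0.26	3	3
141	C sp2	=CFCl	9.81	3	2
142	C sp2	=CCl2	17.52	6	5
143	C sp2	N2=N	29.25	2	2
144	C sp2	N2=O	35.05	3	3
145	C sp2	N=NS	13.50	5	5
146	C sp2	NO=O	33.48	3	3
147	C sp2	=NOCl	24.27	1	1
148	C sp2	NS=S	44.39	2	2
149	C sp2	O2=O	31.57	13	13
150	C sp2	O=OCl	22.73	2	2
151	C sp2	S2=S	34.03	1	1
152	C aromatic	H:C2	4.64	4749	928
153	C aromatic	H:C:N	11.74	118	70
154	C aromatic	H:C:N(+)	22.04	2	1
155	C aromatic	H:N2	15.36	7	5
156	C aromatic	:C3	6.67	233	69
157	C aromatic	C:C2	5.29	1053	618
158	C aromatic	C:C:N	9.94	38	30
159	C aromatic	:C2N	14.44	140	115
160	C aromatic	:C2N(+)	24.38	33	31
161	C aromatic	:C2:N	10.60	21	14
162	C aromatic	:C2O	8.04	443	253
163	C aromatic	:C2S	9.47	30	25
164	C aromatic	:C2Si	4.67	10	8
165	C aromatic	:C2F	4.45	143	72
166	C aromatic	:C2Cl	9.43	429	146
167	C aromatic	:C2Br	12.49	149	69
168	C aromatic	:C2J	19.48	29	26
169	C aromatic	:CN:N	16.72	2	2
170	C aromatic	:C:NO	13.67	4	3
171	C aromatic	:C:NF	14.34	1	1
172	C aromatic	:C:NCl	15.74	3	3
173	C aromatic	:C:NBr	25.24	1	1
174	C aromatic	N:N2	20.19	5	2
175	C aromatic	:N2O	16.44	2	2
176	C sp	H#C	2.42	15	14
177	C sp	C#C	6.05	62	33
178	C sp	=C2	5.50	4	4
179	C sp	C#N	17.38	72	70
180	C sp	#CCl	9.31	3	2
181	C sp	=N=O	10.44	6	5
182	C sp	=N=S	23.08	3	3
183	N sp3	H2C	2.30	78	58
184	N sp3	H2C(pi)	8.05	61	59
185	N sp3	H2N	19.23	8	7
186	N sp3	H2S	28.18	2	2
187	N sp3	HC2	-11.34	59	56
188	N sp3	HC2(pi)	-1.94	27	26
189	N sp3	HC2(2pi)	-2.43	21	21
190	N sp3	HCN	-0.76	3	2
191	N sp3	HCN(pi)	-13.33	3	3
192	N sp3	HCN(2pi)	4.97	1	1
193	N sp3	HCS(pi)	5.34	7	7
194	N sp3	HCSi	-4.02	6	6
195	N sp3	HSi2	1.94	1	1
196	N sp3	BC2	-31.30	3	2
197	N sp3	C3	-30.50	111	101
198	N sp3	C3(pi)	-25.56	37	31
199	N sp3	C3(2pi)	-22.95	52	50
200	N sp3	C3(3pi)	-27.03	13	13
201	N sp3	C2N	-19.64	4	3
202	N sp3	C2N(+)	0.00	1	1
203	N sp3	C2N(pi)	-27.16	3	2
204	N sp3	C2N(+)(pi)	3.24	4	4
205	N sp3	C2N(2pi)	-24.28	4	4
206	N sp3	C2N(3pi)	-26.84	2	2
207	N sp3	C2O	8.24	1	1
208	N sp3	C2P	-17.98	5	2
209	N sp3	C2Si	-19.79	12	8
210	N sp3	CN2(2pi)	-36.43	1	1
211	N sp3	CN2(+)(2pi)	16.44	1	1
212	N sp3	CF2	-4.56	2	2
213	N sp3	CF2(pi)	-12.61	1	1
214	N sp3	CSi2	-17.81	1	1
215	N sp3	Si3	-1.79	1	1
216	N sp2	H=C	1.29	2	2
217	N sp2	C=C	-10.46	85	82
218	N sp2	C=N	-5.89	19	10
219	N sp2	C=N(+)	-2.79	15	13
220	N sp2	=CN	18.81	9	9
221	N sp2	=CO	10.27	17	14
222	N sp2	=CF	0.00	1	1
223	N sp2	N=N	15.91	5	3
224	N sp2	O=O	0.59	7	7
225	N aromatic	:C2	-5.10	104	78
226	N aromatic	:C:N	5.35	8	4
227	N(+) sp3	C2NO(-)	0.00	1	1
228	N(+) sp2	CO=O(-)	-2.09	78	56
229	N(+) sp2	C=NO(-)	-19.89	3	3
230	N(+) sp2	NO=O(-)	0.35	6	5
231	N(+) sp2	O2=O(-)	9.02	17	11
232	N(+) aromatic	:C2O(-)	0.00	1	1
233	N(+) sp	C#C(-)	-8.48	2	2
234	N(+) sp	=N2(-)	5.96	12	10
235	O	HC	14.55	322	288
236	O	HC(pi)	20.98	174	157
237	O	HN	0.00	1	1
238	O	HN(pi)	19.03	2	2
239	O	HO	23.75	5	5
240	O	HSi	26.41	1	1
241	O	BC	-17.91	5	3
242	O	C2	-17.86	424	270
243	O	C2(pi)	-13.29	744	629
244	O	C2(2pi)	-7.15	145	120
245	O	CN(pi)	0.00	7	7
246	O	CN(+)(pi)	2.17	17	11
247	O	CN(2pi)	-2.82	9	9
248	O	CO	-8.76	54	20
249	O	CS	2.45	18	9
250	O	CP	-2.71	104	42
251	O	CP(pi)	1.25	7	5
252	O	CSi	-11.39	79	29
253	O	CSi(pi)	-14.85	37	13
254	O	N2(2pi)	-0.72	3	3
255	O	OSi	4.23	9	4
256	O	P2	16.68	1	1
257	O	Si2	-6.52	15	4
258	P3	C3	-6.83	3	3
259	P3	C2O	2.71	1	1
260	P3	N3	-7.09	1	1
261	P3	N2Cl	10.64	1	1
262	P3	O3	-4.07	1	1
263	P4	HO2=O	9.23	2	2
264	P4	CO2=O	5.40	3	3
265	P4	O3=O	-3.86	16	15
266	P4	O3=S	1.10	9	9
267	P4	O2=OS	1.77	4	4
268	P4	O2S=S	1.73	8	8
269	S2	HC	1.49	33	29
270	S2	HC(pi)	6.23	1	1
271	S2	HP	23.50	3	3
272	S2	BC	-24.53	12	4
273	S2	C2	-10.51	67	65
274	S2	C2(pi)	-2.71	23	22
275	S2	C2(2pi)	0.53	44	44
276	S2	CS	-0.35	16	8
277	S2	CS(pi)	2.39	2	1
278	S2	CP	-1.99	9	9
279	S2	Si2	-3.40	1	1
280	S4	C2=O	22.60	4	4
281	S4	C2=O2	27.80	9	9
282	S4	C2F2	-5.92	1	1
283	S4	CN=O2	1.94	9	9
284	S4	C=O2S	37.54	2	1
285	S4	O2=O	-3.83	5	5
286	S4	O2=O2	4.79	4	4
287	Si	H3C	0.00	1	1
288	Si	H2CN	2.20	1	1
289	Si	HC3	-4.21	24	24
290	Si	HC2O	2.36	2	1
291	Si	HC2S	0.00	2	1
292	Si	HCO2	8.33	5	1
293	Si	HN3	8.01	2	2
294	Si	C4	-0.57	21	20
295	Si	C3N	-1.80	18	14
296	Si	C3O	0.35	6	6
297	Si	C2O2	5.64	18	11
298	Si	CO3	-2.40	26	26
299	Si	O4	-16.14	6	6
300	H	H Acceptor	-12.45	16	16
301	Alkane	No. of C atoms	0.09	3072	286
302	Unsaturated HC	No. of C atoms	-0.07	4100	413
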
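entry	atom_type	neighbours	contribution	occurrences	molecules
1	Const		-13.33	436	436
2	C sp3	H3C	-4.44	483	265
3	C sp3	H3N	-31.51	47	28
4	C sp3	H3N(+)	-31.22	1	1
5	C sp3	H3O	-15.38	34	29
6	C sp3	H3S	-12.79	7	4
7	C sp3	H2C2	-3.86	506	186
8	C sp3	H2CN	-31.29	55	37
9	C sp3	H2CN(+)	-22.60	2	2
10	C sp3	H2CO	-15.26	178	90
11	C sp3	H2CS	-12.03	9	6
12	C sp3	H2CF	-6.02	1	1
13	C sp3	H2CCl	-8.52	15	11
14	C sp3	H2CBr	-11.73	1	1
15	C sp3	H2CJ	-13.80	2	2
16	C sp3	H2O2	-14.86	1	1
17	C sp3	HC3	-2.51	45	35
18	C sp3	HC2N	-29.99	6	5
19	C sp3	HC2N(+)	-20.74	1	1
20	C sp3	HC2O	-14.95	32	29
21	C sp3	HC2F	-5.77	1	1
22	C sp3	HC2Cl	-8.53	1	1
23	C sp3	HC2J	-14.39	1	1
24	C sp3	HCF2	-5.07	3	3
25	C sp3	HCCl2	-11.02	5	4
26	C sp3	C4	0.43	10	10
27	C sp3	C3N	-24.37	3	3
28	C sp3	C3O	-16.23	6	6
29	C sp3	C3Cl	-1.29	1	1
30	C sp3	C3Br	1.24	1	1
31	C sp3	C3J	-7.51	1	1
32	C sp3	C2F2	-5.12	2	2
33	C sp3	COF2	0.74	1	1
34	C sp3	CF3	-2.85	11	9
35	C sp3	CF2Cl	-3.44	3	2
36	C sp3	CFCl2	-12.04	1	1
37	C sp3	CCl3	-12.64	2	2
38	C sp2	H2=C	-2.93	15	13
39	C sp2	HC=C	-2.16	26	20
40	C sp2	HC=O	-16.45	9	9
41	C sp2	H=CN	-13.78	17	13
42	C sp2	H=CO	-10.21	1	1
43	C sp2	H=CS	-6.13	2	1
44	C sp2	H=CCl	-7.34	5	3
45	C sp2	HN=N	-10.70	2	2
46	C sp2	HN=O	-33.05	4	4
47	C sp2	HO=O	-14.45	7	7
48	C sp2	C2=C	1.28	11	11
49	C sp2	C=CN	-15.51	2	2
50	C sp2	C=CN(+)	-39.48	1	1
51	C sp2	C2=O	-17.65	20	20
52	C sp2	C=CF	-6.97	2	2
53	C sp2	C=CCl	-31.39	1	1
54	C sp2	C=CBr	-28.79	1	1
55	C sp2	C=CJ	-31.42	1	1
56	C sp2	=CN2	-32.45	3	3
57	C sp2	CN=O	-39.35	30	30
58	C sp2	=CNCl	-30.33	1	1
59	C sp2	CO=O	-17.24	63	52
60	C sp2	=CF2	0.44	3	2
61	C sp2	=CCl2	-11.89	2	2
62	C sp2	N2=O	-35.29	25	25
63	C sp2	N2=S	-41.79	6	6
64	C aromatic	H:C2	-2.84	437	100
65	C aromatic	H:C:N	-14.82	29	18
66	C aromatic	:C3	-3.23	13	6
67	C aromatic	C:C2	-1.72	90	63
68	C aromatic	C:C:N	-15.13	7	6
69	C aromatic	:C2N	-10.35	13	13
70	C aromatic	:C2N(+)	-21.83	6	6
71	C aromatic	:C2:N	-15.19	1	1
72	C aromatic	:C2O	-9.63	21	17
73	C aromatic	:C2F	-1.79	1	1
74	C aromatic	:C2Cl	-3.91	37	19
75	C aromatic	:C2Br	-5.99	1	1
76	C aromatic	:CN:N	-16.20	1	1
77	C sp	H#C	-1.37	1	1
78	C sp	C#C	0.00	1	1
79	C sp	C#N	-17.66	15	12
80	N sp3	H2C	-2.40	25	20
81	N sp3	H2C(pi)	-16.13	32	30
82	N sp3	HC2	24.30	6	6
83	N sp3	HC2(pi)	11.97	26	22
84	N sp3	HC2(2pi)	3.09	21	12
85	N sp3	C3	57.51	5	5
86	N sp3	C3(pi)	52.51	10	9
87	N sp3	C3(2pi)	36.53	13	8
88	N sp2	C=C	-19.81	2	2
89	N aromatic	:C2	5.38	19	19
90	N(+) sp2	CO=O(-)	8.85	11	11
91	O	HC	-17.23	61	50
92	O	HC(pi)	-18.29	32	26
93	O	HO	-22.54	2	1
94	O	C2	8.60	68	39
95	O	C2(pi)	10.97	56	49
96	O	C2(2pi)	9.97	2	2
97	S2	HC	1.98	4	4
98	S2	C2	6.62	3	3
99	S2	C2(2pi)	0.00	1	1
100	S2	CS	2.30	4	2
101	S4	C2=O	-33.00	1	1
102	H	H Acceptor	10.02	2	2
103	Alkane	No. of C atoms	0.96	142	23
104	Unsaturated HC	No. of C atoms	0.25	307	37
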
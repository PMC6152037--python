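descriptor	row	label	statistic	value	n
dHvap	A	Based on	Valid groups	185	3581
dHvap	B	Goodness of fit	R2	0.9678	3460
dHvap	C	Deviation	Average	2.99	3460
dHvap	D	Deviation	Standard	4.30	3460
dHvap	E	K-fold cv	K	10	3386
dHvap	F	Goodness of fit	Q2	0.9641	3386
dHvap	G	Deviation	Average (cv)	3.14	3386
dHvap	H	Deviation	Standard (cv)	4.56	3386
dHsub	A	Based on	Valid groups	154	1960
dHsub	B	Goodness of fit	R2	0.8887	1866
dHsub	C	Deviation	Average	7.81	1866
dHsub	D	Deviation	Standard	10.33	1866
dHsub	E	K-fold cv	K	10	1791
dHsub	F	Goodness of fit	Q2	0.8657	1791
dHsub	G	Deviation	Average (cv)	8.56	1791
dHsub	H	Deviation	Standard (cv)	11.39	1791
dHsolv	A	Based on	Valid groups	61	436
dHsolv	B	Goodness of fit	R2	0.9731	388
dHsolv	C	Deviation	Average	2.68	388
dHsolv	D	Deviation	Standard	3.53	388
dHsolv	E	K-fold cv	K	10	373
dHsolv	F	Goodness of fit	Q2	0.9546	373
dHsolv	G	Deviation	Average (cv)	3.22	373
dHsolv	H	Deviation	Standard (cv)	4.34	373
dSfus	A	Based on	Valid groups	188	2809
dSfus	B	Goodness of fit	R2	0.8875	2701
dSfus	C	Deviation	Average	12.33	2701
dSfus	D	Deviation	Standard	16.72	2701
dSfus	E	K-fold cv	K	10	2637
dSfus	F	Goodness of fit	Q2	0.8727	2637
dSfus	G	Deviation	Average (cv)	13.23	2637
dSfus	H	Deviation	Standard (cv)	17.93	2637
tpcE	A	Based on	Valid groups	108	2686
tpcE	B	Goodness of fit	R2	0.6094	2663
tpcE	C	Deviation	Average	23.83	2663
tpcE	D	Deviation	Standard	31.62	2663
tpcE	E	K-fold cv	K	10	2643
tpcE	F	Goodness of fit	Q2	0.5804	2643
tpcE	G	Deviation	Average (cv)	24.65	2643
tpcE	H	Deviation	Standard (cv)	32.79	2643
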
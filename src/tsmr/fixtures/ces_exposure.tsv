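snp	chr	gene	ea	nea	eaf	beta	se	pval
rs146390073	1	RGS7	T	C	0.02	0.6678	0.1205	2.20E-08
rs6891174	5	NKX2-5	A	G	0.35	0.1044	0.0206	5.82E-09
rs13143308	4	PITX2	T	G	0.34	0.2776	0.0193	1.86E-47
rs12932445	16	ZFHX3	C	T	0.21	0.1823	0.0213	6.86E-18
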
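snp	chr	gene	ea	nea	eaf	beta	se	pval
rs7610618	3	TM4SF4-TM4SF1	T	C	0.01	0.8459	0.1490	1.44E-8
rs17612742	4	EDNRA	C	T	0.21	0.1740	0.0278	1.46E-11
rs10820405	9	LINC01492	G	A	0.82	0.1823	0.0341	4.51E-08
rs12124533	1	TSPAN2	T	C	0.24	0.1570	0.0262	1.22E-8
rs2107595	7	HDAC9-TWIST1	A	G	0.24	0.1906	0.0233	3.65E-15
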
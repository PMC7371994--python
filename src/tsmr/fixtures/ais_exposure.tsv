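snp	chr	gene	ea	nea	eaf	beta	se	pval
rs34311906	4	ANK2	C	T	0.41	0.0677	0.0120	1.07E-08
rs6825454	4	FGA	C	T	0.31	0.0583	0.0096	7.43E-10
rs11957829	5	LOC100505841	A	G	0.82	0.0677	0.0119	7.51E-09
rs42039	7	CDK6	C	T	0.77	0.0677	0.0120	6.55E-09
rs7304841	12	PDE3A	A	C	0.59	0.0488	0.0097	4.93E-08
rs4932370	15	FURIN-FES	A	G	0.33	0.0488	0.0097	2.88E-08
rs11867415	17	PRPF8	G	A	0.18	0.0862	0.0163	4.81E-08
rs2229383	19	ILF3-SLC44A2	T	G	0.65	0.0488	0.0097	4.72E-08
rs635634	9	ABO	T	C	0.19	0.0770	0.0142	9.18E-09
rs2005108	11	MMP12	T	C	0.12	0.0770	0.0142	3.33E-08
rs3184504	12	SH2B3	T	C	0.45	0.0770	0.0094	2.17E-14
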
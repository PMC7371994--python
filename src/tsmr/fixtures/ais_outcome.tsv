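snp	chr	gene	ea	nea	eaf	beta	se	pval
rs56010410	4	FGA	C	T		0.0047	0.0184	0.7961
rs11957829	5	LOC100505841	A	G		0.0093	0.022	0.6732
rs42039	7	CDK6	C	T		0.039	0.0187	0.03639
rs7304841	12	PDE3A	A	C		-0.0142	0.0176	0.4183
rs4932370	15	FURIN-FES	A	G		-0.0071	0.0171	0.6793
rs11867415	17	PRPF8	G	A		-0.0392	0.0347	0.258
rs2229383	19	ILF3-SLC44A2	T	G		0.0158	0.0169	0.3508
rs635634	9	ABO	T	C		-0.0055	0.0195	0.7793
rs2005108	11	MMP12	T	C		-0.0003	0.0231	0.9888
rs3184504	12	SH2B3	T	C		-0.0252	0.0159	0.1134
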
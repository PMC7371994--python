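snp	chr	gene	ea	nea	eaf	beta	se	pval
rs6891174	5	NKX2-5	A	G		-0.0021	0.017	0.9006
rs13143308	4	PITX2	T	G		-0.0128	0.0188	0.4972
rs12932445	16	ZFHX3	C	T		-0.0261	0.0216	0.2272
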
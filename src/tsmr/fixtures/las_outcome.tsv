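snp	chr	gene	ea	nea	eaf	beta	se	pval
rs17612742	4	EDNRA	C	T		-0.0562	0.0234	0.01618
rs10820405	9	LINC01492	G	A		-0.0086	0.0198	0.6644
rs12124533	1	TSPAN2	T	C		0.0321	0.0187	0.08658
rs2107595	7	HDAC9-TWIST1	A	G		-0.0038	0.0211	0.8582
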
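snp	chr	gene	ea	nea	eaf	beta	se	pval
rs880315	1	CASZ1	C	T		-0.0083	0.0171	0.6301
rs12037987	1	WNT2B	C	T		-0.0058	0.0333	0.8606
rs16896398	6	SLC22A7-ZNF318	T	A		-0.0072	0.017	0.6719
rs7859727	9	Chr9p21	T	C		0.024	0.0156	0.1244
rs2295786	10	SH3PXD2A	A	T		-0.0263	0.0162	0.1043
rs35436	12	TBX3	C	T		0.0112	0.0165	0.4949
rs9526212	13	LRCH1	G	A		-0.0187	0.0181	0.3015
rs8103309	19	SMARCA4-LDLR	T	C		0.0249	0.0172	0.1487
rs1052053	1	PMF1-SEMA4A	G	A		-0.0209	0.016	0.1898
rs4959130	6	FOXF2	A	G		-0.033	0.0236	0.1625
rs12445022	16	ZCCHC14	A	G		0.0303	0.0167	0.07066
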
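snp	chr	gene	ea	nea	eaf	beta	se	pval
rs880315	1	CASZ1	C	T	0.4	0.0527	0.0084	3.619E-10
rs12037987	1	WNT2B	C	T	0.16	0.071	0.0128	2.734E-08
rs16896398	6	SLC22A7-ZNF318	T	A	0.34	0.0477	0.0084	1.301E-08
rs7859727	9	Chr9p21	T	C	0.53	0.0494	0.0079	4.221E-10
rs2295786	10	SH3PXD2A	A	T	0.6	0.0526	0.0082	1.797E-10
rs35436	12	TBX3	C	T	0.62	0.0462	0.0083	2.865E-08
rs9526212	13	LRCH1	G	A	0.76	0.0587	0.0094	5.034E-10
rs8103309	19	SMARCA4-LDLR	T	C	0.65	0.0501	0.0091	3.397E-08
rs1052053	1	PMF1-SEMA4A	G	A	0.4	0.0624	0.0082	2.699E-14
rs4959130	6	FOXF2	A	G	0.14	0.0779	0.0129	1.424E-09
rs12445022	16	ZCCHC14	A	G	0.31	0.0574	0.0089	1.048E-10
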
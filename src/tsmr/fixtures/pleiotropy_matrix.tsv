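snp	tauB	ptauB	abeta42B	alcohol_continuous	alcohol_dichotomous
rs880315	0.652	0.9521	0.2221	0.6342	0.05835
rs12037987	0.8547	0.6817	0.03467	NA	NA
rs16896398	0.029	0.1406	0.0105	0.4732	0.7572
rs7859727	0.4139	0.1943	0.05511	0.4999	0.9692
rs2295786	0.05925	0.2305	0.5089	0.966	0.4138
rs35436	0.514	0.7463	0.3127	NA	NA
rs9526212	0.6056	0.5681	0.8516	NA	NA
rs1052053	0.2341	0.4901	0.6899	0.8213	0.1064
rs4959130	0.8545	0.6134	0.4263	NA	NA
rs12445022	0.8024	0.6333	0.08774	0.1053	0.1229
rs8103309	NA	NA	NA	NA	NA
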
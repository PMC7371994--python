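analysis	method	field	expected	decimals	tol
AS	ivw	beta	-0.039	3	
AS	ivw	pvalue	0.750	3	
AS	weighted_median	beta	-0.156	3	
AS	weighted_median	pvalue	0.274	3	0.1
AS	egger_slope	beta	-1.312	3	
AS	egger_slope	pvalue	0.098	3	
AS	egger_intercept	beta	0.071	3	
AS	egger_intercept	pvalue	0.105	3	
AS	heterogeneity	q	15.8637	4	
AS	heterogeneity	pvalue	0.1036	4	
AIS	ivw	beta	-0.103	3	
AIS	ivw	pvalue	0.305	3	
AIS	weighted_median	beta	-0.092	3	
AIS	weighted_median	pvalue	0.487	3	0.1
AIS	egger_slope	beta	-0.512	3	
AIS	egger_slope	pvalue	0.290	3	
AIS	egger_intercept	beta	0.027	3	
AIS	egger_intercept	pvalue	0.387	3	
AIS	heterogeneity	q	4.7585	4	
AIS	heterogeneity	pvalue	0.7831	4	
LAS	ivw	beta	0.037	3	
LAS	ivw	pvalue	0.568	3	
LAS	weighted_median	beta	-0.022	3	
LAS	weighted_median	pvalue	0.793	3	0.1
LAS	egger_slope	beta	-1.220	3	
LAS	egger_slope	pvalue	0.122	3	
LAS	egger_intercept	beta	0.222	3	
LAS	egger_intercept	pvalue	0.110	3	
LAS	heterogeneity	q	2.8418	4	
LAS	heterogeneity	pvalue	0.2415	4	
CES	ivw	beta	-0.064	3	
CES	ivw	pvalue	0.245	3	
CES	weighted_median	beta	-0.057	3	
CES	weighted_median	pvalue	0.331	3	0.1
CES	egger_slope	beta	-0.062	3	
CES	egger_slope	pvalue	0.673	3	
CES	egger_intercept	beta	-0.001	3	
CES	egger_intercept	pvalue	0.985	3	
CES	heterogeneity	q	0.5889	4	
CES	heterogeneity	pvalue	0.7450	4	
AS_steiger	ivw	beta	0.0259	4	
AS_steiger	ivw	pvalue	0.8492	4	
AS_steiger	weighted_median	beta	-0.129	3	
AS_steiger	weighted_median	pvalue	0.3956	4	0.1
AS_steiger	egger_slope	beta	-1.725	3	
AS_steiger	egger_slope	pvalue	0.0482	4	
AIS_steiger	ivw	beta	-0.1025	4	
AIS_steiger	ivw	pvalue	0.3053	4	
AIS_steiger	weighted_median	beta	-0.0886	4	
AIS_steiger	weighted_median	pvalue	0.4919	4	0.1
AIS_steiger	egger_slope	beta	-0.5124	4	
AIS_steiger	egger_slope	pvalue	0.3255	4	
LAS_steiger	ivw	beta	0.0371	4	
LAS_steiger	ivw	pvalue	0.6320	4	
LAS_steiger	weighted_median	beta	-0.0231	4	
LAS_steiger	weighted_median	pvalue	0.7907	4	0.1
LAS_steiger	egger_slope	beta	-1.2205	4	
LAS_steiger	egger_slope	pvalue	0.3652	4	
CES_steiger	ivw	beta	-0.0643	4	
CES_steiger	ivw	pvalue	0.2453	4	
CES_steiger	weighted_median	beta	-0.05697	5	
CES_steiger	weighted_median	pvalue	0.3374	4	0.1
CES_steiger	egger_slope	beta	-0.0618	4	
CES_steiger	egger_slope	pvalue	0.7457	4	
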
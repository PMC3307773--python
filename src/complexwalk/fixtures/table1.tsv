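protein	TAP	INI1	SS18	SS18SSX1	BCL7A	BCL7C	DPF2	BRD9	PHF10	ann_alternative_names	ann_polya_mrna
BRG1	0	0.303	5.337	4.440	2.039	2.290	1.662	0.141	0.984	SMARCA4	5.93
BRM	0	0	1.339	0.730	0.116	0.280	0.179	0	0.028	SMARCA2	1.45
BAF250A	0	0.027	5.692	2.079	0.379	1.766	1.485	0.027	0.027	SMARCF1, ARID1A	1.63
BAF250B	0	0	2.728	1.540	0.179	0.638	0.315	0.028	0	ARID1B, OSA1	2.04
BAF200	0	0.122	0	0.029	0.029	0.122	0	0	0.884	ARID2, zipzap	nd
BAF180	0	0.457	0	0	0	0.248	0	0	1.769	Polybromo-1	4.36
BAF170	0	1.532	2.793	2.360	0.438	1.432	1.154	0.084	1.745	SMARCC2	9.25
BAF155	0	2.981	5.813	3.467	1.239	2.043	2.831	0.080	0.468	SMARCC1	6.94
BAF60A	0	0.15	3.037	3.037	0.784	2.054	1.477	0.072	0.630	SMARCD1	4.01
BAF60B	0	0.719	7.161	4.080	1.762	2.875	2.384	0	0.607	SMARCD2	7.69
BAF60C	0	0	1.102	0.346	0	0.346	0.16	0	0	SMARCD3	3.02
BAF57	0	0.957	11.115	5.190	1.154	3.642	3.217	0.957	1.61	SMARCE1	9.97
BAF53A	0.233	0.110	6.305	6.305	2.511	2.511	0.874	0.369	0.52	ACTL6A, ArpNb	8.37
BAF53B	0	0	0	0	0	0	0	0	0	ACTL6B, ArpNa	1.68
BAF47	0	0.931	5.449	3.160	1.154	3.160	0.551	0.245	0.823	SMARCB1, INI1, SNF5	5.81
BAF45A	0	0.086	0	0	0	0	0	0	2.728	PHF10	3.08
BAF45B	0	0	0	0.110	0	0.110	0	0	0	DPF1	0.50
BAF45C	0	0	0	0	0	0.105	0	0	0	DPF3, CERD4	0.26
BAF45D	0	0	4.623	1.610	0.101	1.371	1.873	0	0	DPF2, REQ, UBID4	2.80
SS18	0	0	9.00	9.00	0.78	0	2.16	1.000	0	SYT, SSXT	3.73
SS18L1	0	0	0	0	0	0.585	0.585	0	0	CREST	9.92
BCL7A	0	0	0.874	1.310	3.329	0	0.585	0.233	0		nd
BCL7B	0	0	0	0.292	0	0	0	0	0	Hom s 3	4.77
BCL7C	0	0	0	1.783	0	11.915	0	0	0		4.18
BRD7	0	0.064	0	0	0	0	0	0	0.645	CELTIX-1	nd
BRD9	0	0	0.186	0.668	0	0.089	0	4.505	0	MU-RMS-40.8	0.18
SSX1	0	0	0	1.154	0	0	0	0	0		nd
GLTSCR1	0	0	0.619	1.116	0.055	0.708	0	0	0	GSCR1	1.20
SRRM2	0	0	0	0	0	0	0	0	0		8.15
MYBBP1A	0	0	0	0	0	0	0	0	0	p160	3.72
NONO	0.066	0	0	0.066	0	0	0	1.966	0.292	NMT55, p54(nrb)	nd
NUMA1	0	0	0	0	0	0	0	0.167	0		3.23
SFPQ	0.199	0	0	0	0	0	0	0.624	0.528	PSF	11.42
DDX3X	0.116	0	0	0	0	0	0	10.159	0.315	HLP2	12.18
DDX17	0.058	0	0	0	0	0	0.058	9.578	0.136	p72	11.85
RBM14	0	0	0	0	0	0	0	4.736	0	COAA	7.10
DDX5	0	0	0	0	0	0	0.061	4.223	0.805	p68	17.37
actin	4.109	1.371	4.109	6.499	2.481	2.831	0.778	7.254	3.437	actg1	30.37
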
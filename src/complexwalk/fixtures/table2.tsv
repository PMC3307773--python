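human_protein	alternative_names	complex_class	fly_ortholog	fly_complex	yeast_swi_snf	yeast_rsc
BRG1	SMARCA4	Core	brahma/CG5942	Core	SNF2	STH1
BRM	SMARCA2	Core	brahma/CG5942		SNF2	STH1
BAF250A	SMARCF1, ARID1A	BAF	OSA/eyelid/CG7467	BAP	SWI1
BAF250B	ARID1B, OSA1	BAF	OSA/eyelid/CG7467		SWI1
BAF200	ARID2, zipzap	PBAF	BAP170/CG3274	PBAP
BAF180	Polybromo-1	PBAF	polybromo/BAP180/CG11375	PBAP		RSC1, RSC2, RSC4
BAF170	SMARCC2	Core	moira/BAP155/CG18740	Core	SWI3	RSC8
BAF155	SMARCC1	Core	moira/BAP155/CG18740		SWI3	RSC8
BAF60A	SMARCD1	Core	BAP60/CG4303	Core	SWP73	RSC6
BAF60B	SMARCD2	Core	BAP60/CG4303		SWP73	RSC6
BAF60C	SMARCD3	Core	BAP60/CG4303		SWP73	RSC6
BAF57	SMARCE1	Core	dalao/BAP111/CG7055	Core
BAF53A	ACTL6A, ArpNb	Core	BAP55/CG6546	Core	ARP7 & ARP9	ARP7 & ARP9
BAF53B	ACTL6B, ArpNa	Core	?		ARP7 & ARP9	ARP7 & ARP9
BAF47	SMARCB1, INI1, SNF5	Core	SNR1/CG1064	Core	SNF5	SFH1
BAF45A	PHF10	PBAF	e(y)3/SAYP/CG12238	PBAP
BAF45B	DPF1	BAF	d4/CG2682	?
BAF45C	DPF3, CERD4	BAF	d4/CG2682
BAF45D	DPF2, REQ, UBID4	BAF	d4/CG2682
SS18	SYT, SSXT	BAF	CG10555	?
SS18L1	CREST	BAF	CG10555
BCL7A		BAF	BCL7-like/CG17252	?
BCL7B	Hom s 3	BAF	BCL7-like/CG17252
BCL7C		BAF	BCL7-like/CG17252
BRD7	CELTIX-1	PBAF	CG7154	?
BRD9	MU-RMS-40.8	BAF	CG7154
actin	actg1		actin		actin	actin
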
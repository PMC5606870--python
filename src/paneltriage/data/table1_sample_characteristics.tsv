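section	row	Australasia	Ontario	Hawaii	Mayo	Seattle	USCC	All
ethnicity	Caucasian	173	204	10	269	112	163	931
ethnicity	African American	0	0	0	1	4	134	139
ethnicity	Asian	3	6	20	0	5	10	44
ethnicity	Admix	4	7	6	3	15	82	117
ascertainment	Population	113	203	36	126	136	294	908
ascertainment	Clinic	67	14	0	147	0	95	323
group	FCCTX	35	44	7	37	6	24	153
group	Unselected	65	120	4	0	68	291	548
group	Young Onset	36	43	8	159	48	39	333
group	pMMR	11	9	5	22	4	17	68
group	dMMR	33	1	12	55	10	18	129
group	Negative control	19	16	0	58	0	0	93
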
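sample_id	group	gene	variant1	variant2	v1_known_pathogenic	v2_known_pathogenic
s_1204004008	Unselected	APC	Ser26Arg	Lys1436Glu	0	0
s_1207501457	Unselected	APC	Ser26Arg	Lys1436Glu	0	0
s_1208805000	Unselected	CDH1	Pro30Thr	Val55Gly	0	0
s_1204004011	Unselected	CDKN2A	His123Gln	Arg144Cys	0	0
s_1204003858	Unselected	MLH1	c.589-2A>G	Val716Met	1	0
s_1204003974	Unselected	MLH1	c.589-2A>G	Val716Met	1	0
s_1210304575	Young Onset	MLH1	c.589-2A>G	Val716Met	1	0
s_1204003894	Unselected	MSH3	Gly896*	Leu911Trp	1	0
s_1204003966	Unselected	MSH3	Asn524Thr	Arg669Trp	0	0
s_1204003936	Unselected	MSH6	Val717fs	Glu1163Val	1	0
s_1210304546	FCCTX	MUTYH	Tyr179Cys	Pro359Thr	1	0
s_1217302838	FCCTX	MUTYH	Pro405Leu	Pro405Leu	1	1
s_1218802771	FCCTX	MUTYH	Gly396Asp	Gly396Asp	1	1
s_1204003854	Unselected	MUTYH	Tyr179Cys	Arg426Cys	1	0
s_1208805011	Unselected	MUTYH	Tyr179Cys	Gly396Asp	1	1
s_1208903273	Unselected	MUTYH	Tyr179Cys	Gly396Asp	1	1
s_1208704158	Young Onset	MUTYH	Tyr179Cys	Tyr179Cys	1	1
s_1210304610	Young Onset	MUTYH	Gly396Asp	Gly396Asp	1	1
s_1218101197	Young Onset	MUTYH	Tyr179Cys	Gly396Asp	1	1
s_1218101281	Young Onset	MUTYH	Tyr179Cys	Ala357fs	1	1
s_1218101344	Young Onset	MUTYH	Tyr179Cys	Tyr179Cys	1	1
s_1204003928	Unselected	PMS1	Glu27Gln	Arg277*	0	1
s_1204003998	Unselected	PMS1	Gly501Arg	Gly501Arg	0	0
s_1208804993	Unselected	PMS1	Pro134Leu	Glu537Lys	0	0
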
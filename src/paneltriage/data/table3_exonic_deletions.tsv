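sample_id	group	gene	boundaries	features	age_dx	ihc_mlh1	ihc_msh2	ihc_msh6	two_deletions
s_1204002002	dMMR	MSH2	chr2:47697669:47708724	intron 10 - intron 15	40	Normal	Failed	Missing	0
s_1204003924	Unselected	MLH1	chr3:37087820:37092640	intron 15 - 3'	25	ND	ND	ND	0
s_1207501563	Unselected	MSH2	chr2:47629431:47649608	5' - intron 6	49	ND	ND	ND	0
s_1207501567	Unselected	MLH1	chr3:37084259:37093565	intron 15 - 3'	60	ND	ND	ND	0
s_1208804910	Unselected	MLH1	chr3:37061440:42236604	intron 10 - 3'	57	ND	ND	ND	0
s_1208804959	Unselected	MLH1	chr3:37029085:197686994	5' - 3'	59	ND	ND	ND	1
s_1208804959	Unselected	MSH2	chr2:47643733:48022675	intron 6 - 3'	59	ND	ND	ND	1
s_1208804977	Unselected	MSH6	chr2:48023417:55214950	intron 3 - 3'	51	Normal	Normal	Normal	0
s_1208805044	Unselected	MLH1	chr3:37083176:37084778	intron 14 - intron 15	24	ND	ND	ND	0
s_1208903221	Unselected	MSH6	chr2:48005252:48034082	5' - 3'	56	ND	ND	ND	0
s_1210304581	pMMR	MSH2	chr2:47676087:47696198	intron 8 - intron 10	52	ND	ND	ND	0
s_1210304633	Young Onset	MLH1	chr3:37039963:37051213	intron 2 - intron 6	35	ND	ND	ND	0
s_1211600397	FCCTX	MSH2	chr2:47626940:48023946	5' - 3'	48	Normal	Normal	Normal	0
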
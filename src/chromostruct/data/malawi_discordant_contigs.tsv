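contig	size_bp	map_id	lg	n_markers	note
000084F	2383905	mzeb_mben	LG1	1
000084F	2383905	lfue_trc	LG3	3
000084F	2383905	mben_akon	LG3	6
000084F	2383905	mben_abae	LG3	3
000105F_1	1312536	lfue_trc	LG10a	1
000105F_1	1312536	mben_akon	LG2	1
000105F_1	1312536	mben_abae	LG2	3
000201F	1489552	mzeb_mben	LG3	1
000201F	1489552	lfue_trc	LG1	3
000201F	1489552	mben_akon	LG3	3
000201F	1489552	mben_abae	LG3	1
000223F	1452516	mzeb_mben	LG8	4	Repetitive markers on LG3
000223F	1452516	lfue_trc	LG8	8	Repetitive markers on LG3
000223F	1452516	mben_akon	LG3	2	Repetitive markers on LG3
000223F	1452516	mben_abae	LG8	4	Repetitive markers on LG3
000256F	1241607	mzeb_mben	LG20	1
000256F	1241607	lfue_trc	LG20	1
000256F	1241607	mben_abae	LG9	1
000414F	805874	mzeb_mben	LG5	1
000414F	805874	lfue_trc	LG5	1
000414F	805874	mben_abae	LG3	1
000521F	566343	mzeb_mben	LG15	2	Repetitive marker on LG17
000521F	566343	mben_akon	LG17	1	Repetitive marker on LG17
000541F	515490	lfue_trc	LG2	1
000541F	515490	mben_akon	LG3	1
000671F	374096	mzeb_mben	LG23	1
000671F	374096	mben_akon	LG23	1
000671F	374096	mben_abae	LG22	1
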
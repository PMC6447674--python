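lg	mzeb_mben	lfue_trc	mben_akon	mben_abae	final	selected_map
LG1	31191433	32150205	38662702	36192366	38662702	mben_akon
LG2	25783542	28952651	32647892	33362328	32647892	mben_akon
LG3	18498838	14707016	37717145	24847713	37309556	mben_akon
LG4	28418370	24424243	29889472	23743562	30507480	mben_akon
LG5	29725229	34008850	36154892	30984548	36154892	mben_akon
LG6	15868181	32717361	39879506	32438073	39760669	mben_akon
LG7	29333014	57016972	64381187	50973986	64889811	mben_akon
LG8	19307854	16999744	24280574	18082738	23959896	mben_akon
LG9	21018370	22620859	18771712	24011483	21018370	mzeb_mben
LG10	25942318	26176893	32583833	25149136	32346187	mben_akon
LG11	32253887	30903800	34404464	31577152	32434411	mzeb_mben
LG12	23231402	31401442	34043602	31595605	34077077	mben_akon
LG13	25893161	24034634	31886878	28831406	32061881	mben_akon
LG14	32750971	32025991	37909455	30978148	37855742	mben_akon
LG15	28015059	28462857	34537245	28405563	34537245	mben_akon
LG16	24665172	26935058	34727877	29158962	34727877	mben_akon
LG17	28473329	31631813	35766785	31607415	35766785	mben_akon
LG18	19927984	23757304	29457134	30047761	29494144	mben_akon
LG19	24076222	19992035	25739093	22726673	25955740	mben_akon
LG20	28281247	30800769	24975175	29774176	29774176	mben_abae
LG22	27460019	31372369	34717234	30512954	34717234	mben_akon
LG23	27069552	27967022	42736004	37848175	42076657	mben_akon
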
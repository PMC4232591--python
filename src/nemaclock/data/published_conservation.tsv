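mammal_query	insect_query	C_elegans	A_suum	B_malayi	B_xylophilus	C_angaria	C_brenneri	C_briggsae	C_japonica	C_remanei	C_sp7	C_sp9	C_sp11	P_pacificus
BMAL1	Cyc	C25A1.11a	GS_18509	BM21318	BUX.s00397.112	CAN07933	CBN21788	CBG12219	CJA09659	CRE23963	g19865	g12945	g9507	PPA09278
CSNK1a	Dbt	C03C10.1	GS_19252	BM20483	BUX.s00055.190	CAN15839	CBN06321	CBG20206	CJA17198	CRE13355	g29573	g44344	g14251	PPA25500
FBXL	Jetlag	C02F5.7a	GS_19076	BM06465	BUX.s00422.570	CAN15035	CBN03873	CBG16659	CJA04910	CRE25417	g22800	g29591	g435	PPA20677
PPARGC1a	Lark	F18H3.3b	GS_22069	BM03094	BUX.s00579.708	CAN13338	CBN18184	CBG07431	CJA16600	CRE22405	g33812	g23257	g1414	PPA20102
PER	Period	F47F6.1c	GS_08634	BM06378	BUX.s00397.112	CAN12189	CBN20940	CBG07211	CJA16851	CRE17943	g31054	g23334	g4740	PPA04587
WD-Rep	Wds-PB	C14B1.4	GS_18544	BM03793	BUX.s00579.553	CAN22866	CBN24532	CBG09206	CJA10837	CRE25440	g26350	g4010	g7816	PPA00309
PRDX-2	Jafrac	F09E5.15a	GS_23521	BM19146	BUX.s01109.415	CAN05705	CBN11882	CBG25150	CJA14459	CRE11768	g24613	g38213	g9373	PPA28346
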
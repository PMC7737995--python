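haplotype	variable_sites	hf	pct
H1	ATAATGATATATATATACCAATTTATAACAAATATTTTCAT	3	2.50
H2	.....C....C.C.C....C...............CCA...	6	5.00
H3	.....CC.C.C.C.C....C......C........CCA...	6	5.00
H4	..........C.C.C..A........C........CCA...	4	3.33
H5	..C.C..C.C.C.C...AT.C....C.C....C..CC.TGC	2	1.67
H6	CCCC.CC.C........AT..C.C....T...C.....TGC	2	1.67
H7	.C...CC.C......C.AT..C.C....T...C.....TGC	11	9.17
H8	.C.........C.....AT..C.C....T...C.....TGC	3	2.50
H9	...............C.AT..C.C....T...C.....TGC	3	2.50
H10	.C.............C.AT..C.C....T...C.....TGA	2	1.67
H11	.C.............C.AT..C.C....T...C.....TGC	55	45.83
H12	CCCC.CC.C.C.C.CCC..C.CCCC.C.TC..C.....TGC	2	1.67
H13	CCCC.CC.C.C.C.CCC..C.CCC..C.TCCCCCC...TGC	4	3.33
H14	CCCC.CC.C.C.C.CCC..C.CC.C.C..CCCCCC..A.GC	1	0.83
H15	CCCC.CC.C.C.C.CCC..C.CCCC.C.T...C.....TGC	3	2.50
H16	CCC..CC.C.C.C.CCC..C.CCCC.C.T...C.....TGC	1	0.83
H17	.....CC.C.C.C.C.C..C..CCC.C.TCCCC........	6	5.00
H18	.C...CC.C.C.C.C.C..C..CCC.C..CCCC........	2	1.67
H19	CCCC.CC.C.CCC.C.CA.C............C....A.GC	2	1.67
H20	CCCC.CC.C.C.C.C.CA..............C.....TGC	2	1.67
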
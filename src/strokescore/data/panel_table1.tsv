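snp_id	gene	chromosome
rs1883832	CD40	20
rs1130864	CRP	1
rs1205	CRP	1
rs1800947	CRP	1
rs2430561	IFNG	12
rs1800872	IL10	1
rs1800896	IL10	1
rs1295686	IL13	5
rs1800587	IL1A	2
rs1143627	IL1B	2
rs1143634	IL1B	2
rs16944	IL1B	2
rs1801275	IL4R	16
rs1805015	IL4R	16
rs2069812	IL5	5
rs2290608	IL5RA	3
rs1800795	IL6	7
rs1800796	IL6	7
rs1800797	IL6	7
rs2069885	IL9	5
rs1126643	ITGA2	5
rs1024611	MCP1	17
rs1799750	MMP1	11
rs486055	MMP10	11
rs2276109	MMP12	11
rs2252070	MMP13	11
rs243864	MMP2	16
rs3025058	MMP3	11
rs11568818	MMP7	11
rs1320632	MMP8	11
rs2236416	MMP9	20
rs2250889	MMP9	20
rs2274755	MMP9	20
rs2274756	MMP9	20
rs3787268	MMP9	20
rs3918241	MMP9	20
rs3918248	MMP9	20
rs3918253	MMP9	20
rs3918256	MMP9	20
rs3918278	MMP9	20
rs8113877	MMP9	20
rs1137933	NOS2A	17
rs10266564	NOS3	7
rs10275136	NOS3	7
rs12703116	NOS3	7
rs1800779	NOS3	7
rs2070744	NOS3	7
rs2243428	NOS3	7
rs2257073	NOS3	7
rs2257090	NOS3	7
rs2288649	NOS3	7
rs2435608	NOS3	7
rs2435609	NOS3	7
rs2487151	NOS3	7
rs310584	NOS3	7
rs310585	NOS3	7
rs310586	NOS3	7
rs310588	NOS3	7
rs310589	NOS3	7
rs310590	NOS3	7
rs4722204	NOS3	7
rs6952465	NOS3	7
rs5355	SELE	1
rs5361	SELE	1
rs6133	SELP	1
rs2070584	TIMP1	23
rs1800629	TNF	6
rs1061622	TNFRSF1B	1
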
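# m/z values exactly as printed in the source fragmentation study, kept
# verbatim (including apparent typos and the unreconciled near-duplicates in
# the type-II amine-loss list).  role is free text; section names the results
# section the value appears in.
index	mz	role	section
1	286.1445	[M+H]+	type II worked example
1	269.1180	[M-NH3]+ high abundance	type I / type II worked example
1	107.0448	beta-cleavage marker	type I
1	175.0755	fragment - CH3OH	type I
2	300.1582	[M+H]+	type I
2	269.1169	[M-NHR1R2]+ high abundance	type I
2	107.0448	beta-cleavage marker	type I
2	175.0750	fragment - CH3OH	type I
3	316.1545	[M+H]+	type I
3	285.1137	[M-NHR1R2]+ high abundance	type I
3	123.0434	beta-cleavage marker	type I
3	175.0749	fragment - CH3OH	type I
4	330.1714	[M+H]+	type I
4	299.1279	[M-NHR1R2]+ high abundance	type I
4	137.0592	beta-cleavage marker	type I
4	175.0753	fragment - CH3OH	type I
5	288.1233	[M+H]+	type I
5	271.0984	[M-NHR1R2]+ high abundance	type I
5	123.0440	beta-cleavage marker	type I
6	302.1394	[M+H]+	type I
6	285.1134	[M-NHR1R2]+ high abundance	type I
6	123.0446	beta-cleavage marker	type I
6	175.0756	fragment - CH3OH	type I
7	316.1552	[M+H]+	type I
7	299.1281	[M-NHR1R2]+ high abundance	type I
7	137.0593	beta-cleavage marker	type I
7	175.0749	fragment - CH3OH	type I
8	342.1701	[M]+	type I
8	297.1114	[M-NHR1R2]+ high abundance	type I
8	265.0856	fragment - CH3OH	type I
9	342.1696	[M+H]+	type I
9	311.1279	[M-NHR1R2]+ high abundance	type I
9	279.1014	fragment - CH3OH	type I
10	467.2898	[M+H]+	type I
10	450.2633	[M-NH3]+ high abundance	type I
10	434.2325	fragment - CH4	type I
10	422.2318	[M-NH3-C2H4]+ ipecac diagnostic	type I
11	481.3063	[M+H]+	type I
11	464.2797	[M-NH3]+ high abundance	type I
11	448.2486	fragment - CH4	type I
11	436.2492	[M-NH3-C2H4]+ ipecac diagnostic	type I
12	354.1313	[M+H]+	type I
12	336.1210	[M+H-H2O]+ chelidonine diagnostic	type I
12	323.0893	[M-NHR1R2]+ high abundance	type I
12	305.0785	mother fragment of the CH2O-loss chain	type I
12	275.0683	fragment - CH2O	type I
12	247.0737	fragment - CH2O - CO	type I
12	217.0627	fragment - CH2O - CO - CH2O	type I
13	623.3121	[M+H]+	type I
13	592.2707	[M-NHR1R2]+ high abundance	type I
13	607.2807	fragment - CH4	type I
13	580.2694	[M-CH3N=CH2]+ retro-Diels-Alder marker	type I
14	328.1542	[M+H]+	type II worked example
14	311.1273	[M-NH3]+ low abundance	type II
15	309.1121	[M-NHR1R2]+ low abundance	type II
16	307.0987	[M-NHR1R2]+ low abundance	type II
16	176.0704	B-ring cleavage fragment	type II
17	325.1467	[M-NHR1R2]+ low abundance	type II
18	323.1290	[M-NHR1R2]+ low abundance	type II
19	339.1601	[M-NHR1R2]+ low abundance	type II
20	338.1377	[M]+	type III comparison
20	307.0952	[M-NHR1R2]+ low abundance (type II list)	type II
20	307.0971	[M-NH2CH3]+ low abundance (worked example)	type III comparison
20	322.1091	[M-CH4]+ low abundance	type II
20	190.0861	B-ring cleavage fragment	type II
21	309.1121	[M-NHR1R2]+ low abundance	type II
21	324.2292	[M-CH4]+ low abundance	type II
22	311.1284	[M-NHR1R2]+ low abundance	type II
22	326.1354	[M-CH4]+ low abundance	type II
23	323.1287	[M-NHR1R2]+ low abundance	type II
23	338.1493	[M-CH4]+ low abundance	type II
24	311.1280	[M-NHR1R2]+ low abundance	type II
24	326.1378	[M-CH4]+ low abundance	type II
25	323.0898	[M-NHR1R2]+ low abundance	type II
25	336.1212	[M+H-H2O]+ protopine diagnostic	type II
25	165.0539	alpha-cleavage marker	type II
26	339.1179	[M-NHR1R2]+ low abundance	type II
26	352.1531	[M+H-H2O]+ protopine diagnostic	type II
26	181.0850	alpha-cleavage marker	type II
27	255.1010	[M-NHR1R2]+ low abundance	type II
27	227.0716	[M-NH2CH3-C2H4]+	type II
27	58.06	1,2-cleavage marker	type II
28	269.1306	[M-NHR1R2]+ low abundance	type II
28	241.0844	[M-NH2CH3-C2H4]+	type II
28	58.06	1,2-cleavage marker	type II
29	383.1143	[M-NHR1R2]+ low abundance	type II
30	308.0750	[M+H]+	type III
30	290.0672	[M+H-H2O]+	type III
30	272.0536	[M+H-2H2O]+	type III
30	248.0542	retro-Diels-Alder ion	type III
31	382.1285	[M+H]+	type III
31	364.1164	[M+H-H2O]+	type III
33	390.1335	[M+H]+	type III
33	332.0913	[M-HR3]+ (loss of CH3COCH3)	type III
33	318.0759	[M-CH3R3]+ (loss of CH3CH2COCH3)	type III
58	336.1226	[M]+	type III comparison
58	305.1039	suspected [M-NH2CH3]+ rejected at 75.7 ppm	type III comparison
58	320.0912	[M-CH4]+	type III
59	334.1063	[fragment-2H]+	type III
59	306.1124	mother ion of the methyl-radical loss	common pathways
59	291.0867	fragment - CH3 radical	common pathways
59	263.0809	fragment - CH3 - CO	common pathways
60	320.1266	[fragment-2H]+	type III
60	337.1313	mother ion of the methyl-radical loss	common pathways
60	322.1078	fragment - CH3 radical	common pathways
60	294.1128	fragment - CH3 - CO	common pathways
61	274.0850	[fragment-CH2O]+ with CO loss	type III
61	317.0685	[M-CH3]+ from quaternary N-methyl	common pathways
62	302.0809	[fragment-CH2O]+ with CO loss	type III
63	334.1093	mother ion	common pathways
63	319.0867	[fragment-CH3]+ high abundance	common pathways
65	252.1011	[fragment-CO2]+	type III
65	237.0776	[fragment-CO2]+	type III
65	281.0673	[M-CH3]+ from quaternary N-methyl	common pathways
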
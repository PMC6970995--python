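# Reference compounds of the 19 isoquinoline-alkaloid subtypes.
# species: protonated ([M+H]+) or intrinsic_cation ([M]+, quaternary nitrogen).
# formula: neutral molecule for protonated species, cation (trailing '+') for
# intrinsic cations.  Formulas come from the compounds' standard published
# identities (the study prints only m/z); blank where the identity of an
# in-house derivative could not be assigned with confidence.
# printed_precursor_mz: precursor m/z exactly as printed in the study, if any.
index	name	subtype	species	formula	printed_precursor_mz	note
1	coclaurine	benzyltetrahydroisoquinoline	protonated	C17H19NO3	286.1445
2	N-methylcoclaurine	benzyltetrahydroisoquinoline	protonated	C18H21NO3	300.1582
3	3'-hydroxy-N-methylcoclaurine	benzyltetrahydroisoquinoline	protonated	C18H21NO4	316.1545
4	reticuline	benzyltetrahydroisoquinoline	protonated	C19H23NO4	330.1714
5	norlaudanosoline	benzyltetrahydroisoquinoline	protonated	C16H17NO4	288.1233
6	6-O-methylnorlaudanosoline	benzyltetrahydroisoquinoline	protonated	C17H19NO4	302.1394
7	norreticuline	benzyltetrahydroisoquinoline	protonated	C18H21NO4	316.1552
8	magnoflorine	aporphine	intrinsic_cation	C20H24NO4+	342.1701	quaternary N,N-dimethyl
9	isocorydine	aporphine	protonated	C20H23NO4	342.1696
10	cephaeline	ipecac	protonated	C28H38N2O4	467.2898
11	emetine	ipecac	protonated	C29H40N2O4	481.3063
12	chelidonine	chelidonine	protonated	C20H19NO5	354.1313
13	tetrandrine	bisbenzyltetrahydroisoquinoline	protonated	C38H42N2O6	623.3121
14	scoulerine	tetrahydroprotoberberine	protonated	C19H21NO4	328.1542
15	cheilanthifoline	tetrahydroprotoberberine	protonated	C19H19NO4
16	stylopine	tetrahydroprotoberberine	protonated	C19H17NO4
17	tetrahydrocolumbamine	tetrahydroprotoberberine	protonated	C20H23NO4
18	canadine	tetrahydroprotoberberine	protonated	C20H21NO4
19	tetrahydropalmatine	tetrahydroprotoberberine	protonated	C21H25NO4
20	N-methylstylopine	n_methyltetrahydroprotoberberine	intrinsic_cation	C20H20NO4+	338.1377	quaternary N-methyl
21	N-methylcheilanthifoline	n_methyltetrahydroprotoberberine	intrinsic_cation	C20H22NO4+		quaternary N-methyl
22	phellodendrine	n_methyltetrahydroprotoberberine	intrinsic_cation	C20H24NO4+		quaternary N-methyl
23	N-methyltetrahydroberberine	n_methyltetrahydroprotoberberine	intrinsic_cation	C21H24NO4+		quaternary N-methyl
24	N-methylscoulerine	n_methyltetrahydroprotoberberine	intrinsic_cation	C20H24NO4+		quaternary N-methyl
25	protopine	protopine	protonated	C20H19NO5
26	allocryptopine	protopine	protonated	C21H23NO5
27	morphine	morphinan	protonated	C17H19NO3
28	codeine	morphinan	protonated	C18H21NO3
29	noscapine	phthalideisoquinoline	protonated	C22H23NO7
30	narciclasine	narciclasine	protonated	C14H13NO7	308.0750
31	anortianamide	anortianamide	protonated	C21H19NO6	382.1285	formula inferred from printed [M+H]+
32	sanguinarine dimer	benzophenanthridine_dimer	protonated	C40H28N2O8		formula inferred: oxidative sanguinarine dimer
33	6-acetonyldihydrosanguinarine	dihydrobenzophenanthridine	protonated	C23H19NO5	390.1335
34	(1'->6)-hydroxyethyldihydrosanguinarine	dihydrobenzophenanthridine	protonated
35	6-cyanodihydrosanguinarine	dihydrobenzophenanthridine	protonated
36	6-cyanodihydrochelerythrine	dihydrobenzophenanthridine	protonated
37	6-cyanodihydrochelilutine	dihydrobenzophenanthridine	protonated
38	maclekarpine E	dihydrobenzophenanthridine	protonated
39	(1'->6)-hydroxyethyldihydrochelerythrine	dihydrobenzophenanthridine	protonated
40	6-acetonyldihydrochelerythrine	dihydrobenzophenanthridine	protonated
41	6-hydroxymethylsanguinarine	dihydrobenzophenanthridine	protonated
42	6-ethoxy-dihydrosanguinarine	dihydrobenzophenanthridine	protonated
43	ethyl 2'-(dihydrosanguinarine-6-yl)acetate	dihydrobenzophenanthridine	protonated
44	ethyl 2'-(dihydrosanguinarine-6-yl)propanoate	dihydrobenzophenanthridine	protonated
45	ethyl 2'-(dihydrosanguinarine-6-yl)malonate	dihydrobenzophenanthridine	protonated
46	1'-(4-nitrophenyl)-2'-(dihydrosanguinarine-6-yl)ethanone	dihydrobenzophenanthridine	protonated
47	1'-phenyl-2'-(dihydrosanguinarine-6-yl)ethanone	dihydrobenzophenanthridine	protonated
48	1'-(4-methoxyphenyl)-2'-(dihydrosanguinarine-6-yl)ethanone	dihydrobenzophenanthridine	protonated
49	ethyl 2'-(dihydrochelerythrine-6-yl)acetate	dihydrobenzophenanthridine	protonated
50	ethyl 2'-(dihydrochelerythrine-6-yl)propanoate	dihydrobenzophenanthridine	protonated
51	6-hydroxyethyldihydrochelerythrine	dihydrobenzophenanthridine	protonated
52	6-hydroxymethyl-7,8-demethylenedihydrochelerythrine	dihydrobenzophenanthridine	protonated
53	dihydrochelirubine	dihydrobenzophenanthridine	protonated
54	8-demethyldihydrochelerythrine	dihydrobenzophenanthridine	protonated
55	dihydrosanguinarine	dihydrobenzophenanthridine	protonated	C20H15NO4
56	dihydrochelerythrine	dihydrobenzophenanthridine	protonated	C21H19NO4
57	oxysanguinarine	dihydrobenzophenanthridine	protonated	C20H13NO5
58	7,8-dihydrocoptisine	dihydroprotoberberine_7_8	intrinsic_cation	C20H18NO4+	336.1226	printed precursor inconsistent with the name (which implies C19H16NO4+, 322.1074); formula assigned to match the printed ion
59	berberine	protoberberine	intrinsic_cation	C20H18NO4+		quaternary aromatic N
60	palmatine chloride	protoberberine	intrinsic_cation	C21H22NO4+		chloride counterion not part of the cation
61	sanguinarine	benzophenanthridine	intrinsic_cation	C20H14NO4+		quaternary aromatic N
62	chelerythrine	benzophenanthridine	intrinsic_cation	C21H18NO4+		quaternary aromatic N
63	7-demethylchelerythrine	benzophenanthridine	intrinsic_cation	C20H16NO4+	334.1093
64	6-methoxy-norchelerythrine	benzophenanthridine	protonated
65	2,3-methylenedioxy-7,10-dimethyl-8-carboxyl-benzoquinoline	benzoquinoline	intrinsic_cation	C17H14NO4+		formula inferred from printed fragment ions
66	2,3-methylenedioxy-7,10-dimethyl-7,8,9,10-tetrahydro-benzoquinoline	tetrahydrobenzoquinoline	protonated	C16H17NO2		formula inferred from the systematic name
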
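# Characteristic neutral losses of isoquinoline alkaloids in positive-mode CID.
# Columns: name, formula (Hill, trailing '.' = radical), mass (Da, must equal the
# formula's monoisotopic mass; validated at load), substituent_tag, diagnostic_roles
# (comma-separated subtype labels this loss evidences), description.
name	formula	mass	substituent_tag	diagnostic_roles	description
NH3	NH3	17.0265	amine		ammonia; amine loss from N with R1=R2=H
CH5N	CH5N	31.0422	amine		methylamine; amine loss from N-CH3 (R1=H, R2=CH3)
C2H7N	C2H7N	45.0578	amine		dimethylamine; amine loss from N(CH3)2
CH4O	CH4O	32.0262	vicinal_methoxy_hydroxy		methanol; vicinal methoxy + hydroxy groups
CH4	CH4	16.0313	vicinal_methoxy_or_n_methyl	n_methyltetrahydroprotoberberine,dihydroprotoberberine_7_8	methane; vicinal methoxy pair, or N-methyl + vicinal H
CH2O	CH2O	30.0106	methylenedioxy	benzophenanthridine	formaldehyde; methylenedioxy bridge
CO	CO	27.9949	methylenedioxy	benzophenanthridine	carbon monoxide; methylenedioxy bridge (after CH2O) or carbonyl
CH3	CH3.	15.0235	methoxy_or_quaternary_n_methyl		methyl radical; methoxy group or quaternary N-methyl
H2O	H2O	18.0106	hydroxy	chelidonine,protopine,narciclasine,anortianamide	water; hydroxy group
CO2	CO2	43.9898	carboxyl	benzoquinoline	carbon dioxide; carboxyl group
C2H4	C2H4	28.0313		ipecac,morphinan	ethene; ring-contraction after amine loss
C2H5N	C2H5N	43.0422		bisbenzyltetrahydroisoquinoline	CH2=N-CH3; retro-Diels-Alder marker at the B-ring
H2	H2	2.0157		protoberberine	dihydrogen; aromatization of C5-C6 ([fragment-2H]+ pairs)
C3H6O	C3H6O	58.0419		dihydrobenzophenanthridine	acetone; loss of H + acetonyl substituent at C-6 (HR3)
C4H8O	C4H8O	72.0575		dihydrobenzophenanthridine	butanone; loss of CH3 + acetonyl substituent at C-6 (CH3R3)
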
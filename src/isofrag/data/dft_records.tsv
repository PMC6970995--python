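# Reference DFT energetics (B3LYP/6-31G(d)), stored verbatim from the source
# study and NEVER recomputed by this package.  Values marked derived=1 were
# obtained from differences the study states in prose rather than a printed
# table entry.
# context: protonation_site | pathway | bond_dissociation
label	relative_energy_kcal_mol	context	derived	note
Nitrogen	0.0	protonation_site	0	most favoured protonation site of alkaloid 1
Phenyl ring A	24.77	protonation_site	0
Phenyl ring C	34.19	protonation_site	0
Oxygen of 3-OCH3	47.69	protonation_site	0
Oxygen of 2-OH	52.55	protonation_site	0
Oxygen of 4'-OH	60.84	protonation_site	0
R1-1	5.77	pathway	0	NH3-loss pathway 1 intermediate
R1-2	30.33	pathway	0	NH3-loss pathway 1 transition state
R1-3	48.43	pathway	0	NH3-loss pathway 1 product ion
R2-1	2.69	pathway	1	stated 3.08 kcal/mol below R1-1
R2-2	14.50	pathway	1	stated 15.83 kcal/mol below R1-2
R2-3	28.63	pathway	1	stated 19.80 kcal/mol below R1-3
R'1-2	55.60	pathway	0	N-demethylation fragment of the alkaloid-63 mother ion
N-CH3	55.60	bond_dissociation	0	favoured methyl-radical loss site
O-CH3	57.57	bond_dissociation	1	stated 1.97 kcal/mol above N-CH3
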
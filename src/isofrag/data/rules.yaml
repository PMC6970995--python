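# Subtype decision rules for the three-category / 19-subtype flowchart.
#
# Within each category, subtypes are listed in evaluation (flowchart) order;
# ties in score are broken toward the earlier entry.  The exact branch order
# of the published flowchart figure is not fully recoverable from the text,
# so the order below is an implementation choice: more specific diagnostics
# (e.g. the dimer half-mass rule) are checked before broader ones, and pure
# absence-style rules (aporphine's missing low-mass region) come last.
#
# Rule kinds:
#   precursor_loss            one named loss directly off the precursor
#   loss_chain                successive named losses chained from the precursor
#   any_loss                  the named loss anywhere in the fragment graph
#   losses_present            all named losses present somewhere in the graph
#   paired_precursor_losses   all named losses directly off the precursor
#   marker_any                a peak at any of the listed absolute m/z values
#   no_significant_peaks_below  no peak below mz_cutoff at >= the significance floor
#   half_mass_peak            a peak at (precursor - 1.0078) / 2
#   single_h2o_loss           exactly one H2O edge, and it starts at the precursor
#   fallback                  fires when no other subtype in the category fired
#
# Score per subtype = sum of fired rule weights / sum of all its rule weights.

subtypes:
  # ---- category I: high-abundance [M-NHR1R2]+ -----------------------------
  - subtype: chelidonine
    rules:
      - id: chelidonine_water_loss
        kind: precursor_loss
        loss: H2O
        weight: 1.0
        description: "[M+H-H2O]+ ion distinguishes chelidonine within category I"
  - subtype: ipecac
    rules:
      - id: ipecac_nh3_ethene_chain
        kind: loss_chain
        losses: [NH3, C2H4]
        weight: 1.0
        description: "successive NH3 then CH2=CH2 losses from the precursor"
  - subtype: bisbenzyltetrahydroisoquinoline
    rules:
      - id: bisbenzyl_rda_loss
        kind: precursor_loss
        loss: C2H5N
        weight: 1.0
        description: "retro-Diels-Alder loss of CH3N=CH2 from the B-ring"
  - subtype: benzyltetrahydroisoquinoline
    rules:
      - id: benzyl_beta_cleavage_markers
        kind: marker_any
        mz: [107.0448, 123.0440, 137.0592]
        weight: 1.0
        description: "low-mass beta-cleavage marker ions of the benzyl moiety"
  - subtype: aporphine
    rules:
      - id: aporphine_no_low_mass
        kind: no_significant_peaks_below
        mz_cutoff: 200.0
        weight: 1.0
        description: "conjugated skeleton yields no characteristic fragments below m/z 200"

  # ---- category II: low-abundance [M-NHR1R2]+ -----------------------------
  - subtype: protopine
    rules:
      - id: protopine_water_loss
        kind: precursor_loss
        loss: H2O
        weight: 1.0
        description: "neutral loss of H2O from the [M+H]+ ion"
      - id: protopine_alpha_cleavage_markers
        kind: marker_any
        mz: [165.0539, 181.0850]
        weight: 1.0
        description: "alpha-cleavage skeleton fragments"
  - subtype: n_methyltetrahydroprotoberberine
    rules:
      - id: nmthpb_methane_loss
        kind: precursor_loss
        loss: CH4
        weight: 1.0
        description: "[M-CH4]+ from N-methyl plus vicinal hydrogen"
      - id: nmthpb_b_ring_marker
        kind: marker_any
        mz: [190.0861]
        weight: 1.0
        description: "B-ring cleavage fragment of the N-methyl form"
  - subtype: tetrahydroprotoberberine
    rules:
      - id: thpb_b_ring_marker
        kind: marker_any
        mz: [176.0704]
        weight: 1.0
        description: "B-ring cleavage fragment (NH form)"
  - subtype: morphinan
    rules:
      - id: morphinan_12_cleavage_marker
        kind: marker_any
        mz: [58.0651]
        tol_da: 0.01
        weight: 1.0
        description: "m/z 58.06 ion from the 1,2-cleavage reaction"
      - id: morphinan_amine_ethene_chain
        kind: loss_chain
        losses: [CH5N, C2H4]
        weight: 1.0
        description: "combined loss of NH2CH3 and CH2=CH2"
  - subtype: phthalideisoquinoline
    rules:
      - id: phthalide_12_cleavage_marker
        kind: marker_any
        mz: [58.0651]
        tol_da: 0.01
        weight: 1.0
        description: "m/z 58.06 ion from the 1,2-cleavage reaction"

  # ---- category III: [M-NHR1R2]+ absent (p-pi conjugated nitrogen) --------
  - subtype: benzophenanthridine_dimer
    rules:
      - id: dimer_half_mass
        kind: half_mass_peak
        weight: 1.0
        description: "[1/2(M-1.0078)]+ ion from symmetric cleavage of the dimer"
  - subtype: narciclasine
    rules:
      - id: narciclasine_double_water_loss
        kind: loss_chain
        losses: [H2O, H2O]
        weight: 1.0
        description: "two successive H2O losses from the precursor"
      - id: narciclasine_rda_marker
        kind: marker_any
        mz: [248.0542]
        weight: 1.0
        description: "retro-Diels-Alder ion"
  - subtype: anortianamide
    rules:
      - id: anortianamide_single_water_loss
        kind: single_h2o_loss
        weight: 1.0
        description: "only a single H2O loss from the precursor is observed"
  - subtype: dihydrobenzophenanthridine
    rules:
      - id: dihydrobenzo_hr3_pair
        kind: paired_precursor_losses
        losses: [C3H6O, C4H8O]
        weight: 1.0
        description: "paired [M-HR3]+ / [M-CH3R3]+ losses differing by CH2"
  - subtype: dihydroprotoberberine_7_8
    rules:
      - id: dihydroproto_methane_loss
        kind: precursor_loss
        loss: CH4
        weight: 1.0
        description: "[M-CH4]+ from N-methyl plus vicinal H on a conjugated core"
  - subtype: protoberberine
    rules:
      - id: protoberberine_dehydro_pairs
        kind: any_loss
        loss: H2
        weight: 1.0
        description: "[fragment-2H]+ pairs from aromatization at C5-C6"
  - subtype: benzophenanthridine
    rules:
      - id: benzophen_methylenedioxy_losses
        kind: losses_present
        losses: [CH2O, CO]
        weight: 1.0
        description: "[fragment-CH2O]+ ions appearing together with CO losses"
  - subtype: benzoquinoline
    rules:
      - id: benzoquinoline_co2_loss
        kind: any_loss
        loss: CO2
        weight: 1.0
        description: "[fragment-CO2]+ ions from the carboxyl group"
  - subtype: tetrahydrobenzoquinoline
    rules:
      - id: tetrahydrobenzoquinoline_fallback
        kind: fallback
        weight: 1.0
        description: "category III spectrum matching no other diagnostic pattern"
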
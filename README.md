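# isofrag

Rule-based structural classification of isoquinoline alkaloids from
positive-mode ESI-MS/MS spectra.

Isoquinoline alkaloids (benzylisoquinolines, aporphines, protoberberines,
benzophenanthridines, ...) are tyrosine-derived plant metabolites with strong
pharmacological activity. Analogues sharing a skeleton fragment alike under
collision-induced dissociation, so a well-characterised rule base over
reference compounds lets you assign the skeleton of an unknown from its
MS/MS spectrum alone. `isofrag` implements such a rule base for 19
structural subtypes across 66 reference alkaloids, for analysts annotating
plant-extract metabolomics data.

## The method

Everything hinges on exact-mass neutral-loss arithmetic. For a singly
charged cation with elemental formula *F*, the theoretical m/z is
Σᵢ nᵢ·mᵢ − mₑ (monoisotopic atomic masses, one electron subtracted), and an
observed ion is accepted for a candidate at the signed error

> ppm = (m/z_obs − m/z_theo) / m/z_theo × 10⁶,

with the theoretical value taken at 4-decimal display precision. Losses are
matched between ion pairs at a 10 ppm default tolerance (accepted
assignments in the underlying study sit within ~3 ppm; a known spurious
candidate at ~76 ppm must stay rejected).

Classification then follows a two-stage flowchart:

1. **Category** from the abundance tier of the amine-loss ion
   [M−NHR₁R₂]⁺ (R₁, R₂ = N-substituents; the loss is NH₃, CH₃NH₂ or
   (CH₃)₂NH): **I** if the ion is high-abundance (≥5 % of base peak),
   **II** if present but weak, **III** if absent — a p-π conjugated nitrogen
   cannot expel its amine.
2. **Subtype** (19 labels) from diagnostic patterns evaluated on the
   fragment graph: e.g. [M+H−H₂O]⁺ for chelidonine, chained NH₃ → C₂H₄
   losses for ipecac alkaloids, the retro-Diels-Alder CH₃N=CH₂ loss for
   bisbenzyltetrahydroisoquinolines, β-cleavage marker ions at m/z 107/123/137
   for benzyltetrahydroisoquinolines, the [½(M−1.0078)]⁺ half-mass ion for
   benzophenanthridine dimers, [fragment−2H]⁺ pairs for protoberberines, and
   so on. Each subtype scores the fired fraction of its rule weights.

Characteristic losses also reveal substituents: CH₃OH → vicinal methoxy +
hydroxy; CH₄ → vicinal methoxys (or N-methyl + vicinal H); CH₂O/CO →
methylenedioxy; CH₃• then CO → methoxy; CH₃• off an intrinsic cation →
quaternary N-methyl; CO₂ → carboxyl.

## Worked example

```python
from isofrag import (Peak, PrecursorIon, Spectrum, build_fragment_graph,
                     classify_spectrum, infer_substituents, ppm_error,
                     ion_mz, parse_formula)

# coclaurine-like spectrum: [M+H]+ 286.1445, base-peak amine loss, beta marker
s = Spectrum(PrecursorIon(286.1445),
             (Peak(107.0448, 55.0), Peak(269.1180, 100.0)), "demo")

print(round(ppm_error(269.1180, ion_mz(parse_formula("C17H17O3+"))), 2))
result = classify_spectrum(s)
print(result.category.value, result.subtype, round(result.score, 2))
for h in infer_substituents(build_fragment_graph(s)):
    print(h.substituent)
```

prints

```
2.97
I benzyltetrahydroisoquinoline 1.0
```

i.e. the amine-loss ion sits 2.97 ppm from its electron-corrected
theoretical mass, the base-peak amine loss puts the spectrum in category I,
and the m/z 107.0448 marker selects the benzyltetrahydroisoquinoline
subtype with full rule support (no substituent-diagnostic losses are present
in this two-peak demo).

The same pipeline is scriptable from the shell:

```bash
isofrag simulate --out-dir corpus --n-per-subtype 2 --seed 7
isofrag classify corpus/corpus.mgf
isofrag annotate corpus/corpus.mgf
isofrag kb-export
```

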
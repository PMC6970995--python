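"""Seedable generator of rule-conformant MS/MS spectra with ground truth.

No raw spectra of the 66 reference alkaloids are publicly deposited, so every
pipeline stage is exercised against synthetic spectra instead.  Each of the
19 subtypes has a template anchored on a reference compound from the
knowledge base: the precursor ion plus the subtype's characteristic
fragments, expressed as chains of library losses (masses are therefore
formula-exact by construction) or as fixed marker m/z values.

Peaks are perturbed by a Gaussian ppm mass-error model (default sd 2 ppm,
matching the few-ppm accuracy of a calibrated Q-TOF), intensities are drawn
per tier -- high: 40-100, low: 0.5-4.9 relative to a base peak of 100
(synthetic conventions; the qualitative high/low distinction is real, the
numbers are ours) -- with multiplicative log-normal noise, and uniform decoy
peaks are added away from any true fragment.  Everything is reproducible
from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .chem_formula import ElementalFormula, ion_mz, parse_formula
from .knowledge_base import load_reference_compounds
from .loss_annotation import NeutralLossEntry, default_loss_library
from .spectrum_io import IonSpecies, Peak, PrecursorIon, Spectrum, write_mgf
from .taxonomy import Category, SUBTYPE_CATEGORY, SUBTYPES

__all__ = [
    "GenerationSpec",
    "GroundTruth",
    "SubtypeTemplate",
    "TEMPLATES",
    "generate_spectrum",
    "generate_corpus",
    "write_corpus",
    "evaluate_corpus",
    "recovery_rates",
]

#: Relative-intensity ranges per tier (base peak = 100).
TIER_RANGES: dict[str, tuple[float, float]] = {"high": (40.0, 100.0), "low": (0.5, 4.9)}

#: Decoys are kept at least this many ppm away from every true peak.
DECOY_EXCLUSION_PPM = 25.0


@dataclass(frozen=True)
class _Frag:
    """One template fragment: a loss chain off a base ion, or a fixed m/z."""

    losses: tuple[str, ...] = ()
    base: str = "precursor"  # "precursor" or a cation formula string
    mz: float | None = None  # fixed-position peak (marker or unassigned ion)
    role: str = "diagnostic"  # "amine_loss" | "diagnostic" | "marker"
    tier: str = "high"


@dataclass(frozen=True)
class SubtypeTemplate:
    subtype: str
    exemplar_index: int  # reference compound the precursor is anchored on
    fragments: tuple[_Frag, ...]


def _t(subtype: str, exemplar: int, *frags: _Frag) -> SubtypeTemplate:
    return SubtypeTemplate(subtype, exemplar, tuple(frags))


#: Fragmentation templates, one per subtype.  Loss chains mirror each
#: subtype's characteristic scheme; marker m/z values are the printed
#: skeleton-cleavage ions.
TEMPLATES: dict[str, SubtypeTemplate] = {
    t.subtype: t
    for t in (
        # -- category I -----------------------------------------------------
        _t("benzyltetrahydroisoquinoline", 1,
           _Frag(("NH3",), role="amine_loss"),
           _Frag(("NH3", "CH4O")),
           _Frag(mz=107.0448, role="marker"),
           _Frag(mz=137.0592, role="marker")),
        _t("aporphine", 9,
           _Frag(("CH5N",), role="amine_loss"),
           _Frag(("CH5N", "CH4O"))),
        _t("ipecac", 10,
           _Frag(("NH3",), role="amine_loss"),
           _Frag(("NH3", "C2H4")),
           _Frag(("NH3", "CH4"))),
        _t("chelidonine", 12,
           _Frag(("H2O",)),
           _Frag(("CH5N",), role="amine_loss"),
           _Frag(("H2O", "CH2O")),
           _Frag(("H2O", "CH2O", "CO"))),
        _t("bisbenzyltetrahydroisoquinoline", 13,
           _Frag(("CH5N",), role="amine_loss"),
           _Frag(("C2H5N",)),
           _Frag(("CH4",))),
        # -- category II ----------------------------------------------------
        _t("tetrahydroprotoberberine", 16,
           _Frag(("NH3",), role="amine_loss", tier="low"),
           _Frag(mz=176.0704, role="marker")),
        _t("n_methyltetrahydroprotoberberine", 20,
           _Frag(("CH5N",), role="amine_loss", tier="low"),
           _Frag(("CH4",), tier="low"),
           _Frag(mz=190.0861, role="marker")),
        _t("protopine", 25,
           _Frag(("CH5N",), role="amine_loss", tier="low"),
           _Frag(("H2O",)),
           _Frag(mz=165.0539, role="marker")),
        _t("morphinan", 27,
           _Frag(("CH5N",), role="amine_loss", tier="low"),
           _Frag(("CH5N", "C2H4")),
           _Frag(mz=58.0651, role="marker")),
        _t("phthalideisoquinoline", 29,
           _Frag(("CH5N",), role="amine_loss", tier="low"),
           _Frag(("CH3",)),
           _Frag(mz=58.0651, role="marker")),
        # -- category III ---------------------------------------------------
        _t("benzophenanthridine_dimer", 32,
           _Frag(base="C20H14NO4+"),              # the [1/2(M-1.0078)]+ ion
           _Frag(base="C20H14NO4+", losses=("CH3",))),
        _t("narciclasine", 30,
           _Frag(("H2O",)),
           _Frag(("H2O", "H2O")),
           _Frag(mz=248.0542, role="marker")),
        _t("anortianamide", 31,
           _Frag(("H2O",))),
        _t("dihydrobenzophenanthridine", 33,
           _Frag(("C3H6O",)),
           _Frag(("C4H8O",)),
           _Frag(("C3H6O", "CH3"))),
        _t("dihydroprotoberberine_7_8", 58,
           _Frag(("CH4",)),
           # the "suspected" amine-loss ion sitting ~76 ppm off its candidate
           _Frag(mz=305.1039, role="marker", tier="low")),
        _t("protoberberine", 59,
           _Frag(("H2",)),
           _Frag(("CH3",)),
           _Frag(("CH3", "CO"))),
        _t("benzophenanthridine", 61,
           _Frag(("CH3",)),
           _Frag(("CH2O",)),
           _Frag(("CH2O", "CO"))),
        _t("benzoquinoline", 65,
           _Frag(("CH3",)),
           _Frag(("CO2",)),
           _Frag(("CH3", "CO2"))),
        _t("tetrahydrobenzoquinoline", 66,
           _Frag(("CH3",)),
           _Frag(("C2H4",))),
    )
}


@dataclass(frozen=True)
class GenerationSpec:
    """Parameters for one synthetic spectrum.

    ``template`` is a subtype label or a reference-compound index (resolved
    to the compound's subtype).  ``tier_plan`` overrides the intensity tier
    per fragment role ('amine_loss', 'diagnostic', 'marker'); the value
    'absent' omits those fragments entirely.
    """

    template: str | int = "benzyltetrahydroisoquinoline"
    mass_error_sd: float = 2.0  # ppm
    decoy_count: int = 10
    intensity_cv: float = 0.2  # multiplicative coefficient of variation
    seed: int = 0
    tier_plan: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mass_error_sd < 0 or self.decoy_count < 0 or self.intensity_cv < 0:
            raise ValueError("mass_error_sd, decoy_count and intensity_cv must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually put into a spectrum."""

    subtype: str
    category: Category
    loss_names: tuple[str, ...]  # template chain losses actually emitted
    edges: tuple[tuple[float, float, str], ...]  # exact (parent, child, loss)
    identifier: str


def _resolve_template(template: str | int) -> SubtypeTemplate:
    if isinstance(template, int):
        matches = [c for c in load_reference_compounds() if c.index == template]
        if not matches:
            raise ValueError(f"no reference compound with index {template}")
        return TEMPLATES[matches[0].subtype]
    if template not in TEMPLATES:
        raise ValueError(f"unknown subtype template {template!r}")
    return TEMPLATES[template]


def _formula_edges(
    ions: Sequence[tuple[float, ElementalFormula | None]],
    library: Sequence[NeutralLossEntry],
) -> tuple[tuple[float, float, str], ...]:
    """All exact loss relations among formula-bearing ions.

    An edge exists wherever the elemental difference between two ions equals
    a library loss exactly; this includes composite coincidences (e.g. an
    NH3 chain followed by C2H4 also spans a single C2H7N loss), so it is the
    complete ground truth an ideal annotator should recover.
    """
    edges = []
    for pm, pf in ions:
        for cm, cf in ions:
            if pf is None or cf is None or pm <= cm:
                continue
            diff = {s: pf.counts.get(s, 0) - cf.counts.get(s, 0) for s in set(pf.counts) | set(cf.counts)}
            if any(v < 0 for v in diff.values()):
                continue
            diff = {s: v for s, v in diff.items() if v}
            for entry in library:
                if diff == dict(entry.formula.counts):
                    edges.append((pm, cm, entry.name))
    return tuple(sorted(edges))


def generate_spectrum(spec: GenerationSpec) -> tuple[Spectrum, GroundTruth]:
    """Generate one synthetic spectrum and its ground truth.

    Deterministic for a fixed spec (same seed -> identical spectrum); decoys
    are rejection-sampled so that none falls within
    :data:`DECOY_EXCLUSION_PPM` of any true peak.
    """
    template = _resolve_template(spec.template)
    library = default_loss_library()
    by_name = {e.name: e for e in library}
    compound = next(c for c in load_reference_compounds() if c.index == template.exemplar_index)
    prec_formula = compound.precursor_formula
    assert prec_formula is not None, "template exemplars always carry a formula"
    prec_mz = ion_mz(prec_formula)

    # Theoretical true ions: (mz, formula-or-None, tier); precursor included.
    ions: list[tuple[float, ElementalFormula | None, str]] = [(prec_mz, prec_formula, "high")]
    chain_losses: list[str] = []
    for frag in template.fragments:
        tier = spec.tier_plan.get(frag.role, frag.tier)
        if tier == "absent":
            continue
        if tier not in TIER_RANGES:
            raise ValueError(f"unknown tier {tier!r}")
        if frag.mz is not None:
            ions.append((frag.mz, None, tier))
            continue
        f = prec_formula if frag.base == "precursor" else parse_formula(frag.base)
        for name in frag.losses:
            f = f - by_name[name].formula
        ions.append((ion_mz(f), f, tier))
        chain_losses += list(frag.losses)

    gt_edges = _formula_edges([(mz, f) for mz, f, _ in ions], library)

    rng = np.random.default_rng(spec.seed)
    mzs = np.array([mz for mz, _, _ in ions])
    observed_mz = mzs * (1.0 + rng.normal(0.0, spec.mass_error_sd, size=len(mzs)) * 1e-6)
    # Tier values are percentages of the base peak; pin the base to 100 so
    # low-tier ions stay inside their stated relative range before noise.
    intensities = np.array([rng.uniform(*TIER_RANGES[tier]) for _, _, tier in ions])
    intensities[int(np.argmax(intensities))] = 100.0
    if spec.intensity_cv > 0:
        sigma = float(np.sqrt(np.log1p(spec.intensity_cv**2)))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(intensities))
        intensities = intensities * noise

    # Decoys: uniform over (50, precursor), rejected near any true peak.
    decoys: list[float] = []
    guard = 0
    while len(decoys) < spec.decoy_count and guard < 10000:
        guard += 1
        cand = rng.uniform(50.0, prec_mz)
        if all(abs(cand - t) > t * DECOY_EXCLUSION_PPM * 1e-6 for t in mzs):
            decoys.append(cand)
    decoy_int = rng.uniform(*TIER_RANGES["low"], size=len(decoys))

    identifier = f"{template.subtype}|exemplar={template.exemplar_index}|seed={spec.seed}"
    peaks = tuple(
        Peak(float(mz), float(it)) for mz, it in zip(observed_mz, intensities)
    ) + tuple(Peak(float(mz), float(it)) for mz, it in zip(decoys, decoy_int))
    spectrum = Spectrum(
        precursor=PrecursorIon(float(observed_mz[0]), compound.species, prec_formula),
        peaks=peaks,
        identifier=identifier,
    )
    truth = GroundTruth(
        subtype=template.subtype,
        category=SUBTYPE_CATEGORY[template.subtype],
        loss_names=tuple(chain_losses),
        edges=gt_edges,
        identifier=identifier,
    )
    return spectrum, truth


def generate_corpus(
    n_per_subtype: int,
    seed: int = 0,
    **overrides,
) -> list[tuple[Spectrum, GroundTruth]]:
    """A balanced corpus: ``n_per_subtype`` spectra for each of the 19 subtypes.

    Per-spectrum seeds are derived deterministically from the master seed;
    ``overrides`` are forwarded to every :class:`GenerationSpec`.
    """
    if n_per_subtype < 1:
        raise ValueError("n_per_subtype must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(SUBTYPES) * n_per_subtype)
    out = []
    k = 0
    for subtype in SUBTYPES:
        for _ in range(n_per_subtype):
            child_seed = int(children[k].generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
            out.append(generate_spectrum(GenerationSpec(template=subtype, seed=child_seed, **overrides)))
            k += 1
    return out


def write_corpus(
    corpus: Sequence[tuple[Spectrum, GroundTruth]],
    out_dir: str | Path,
    params: Mapping | None = None,
) -> None:
    """Write a corpus as MGF + ground-truth TSV (+ a parameter sidecar)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_mgf([s for s, _ in corpus], out_dir / "corpus.mgf")
    pd.DataFrame(
        [
            {
                "identifier": t.identifier,
                "subtype": t.subtype,
                "category": t.category.value,
                "true_losses": ",".join(t.loss_names),
            }
            for _, t in corpus
        ]
    ).to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)
    if params is not None:
        (out_dir / "generation_params.yaml").write_text(yaml.safe_dump(dict(params), sort_keys=True))


# ---------------------------------------------------------------------------
# Corpus-level evaluation
# ---------------------------------------------------------------------------

def evaluate_corpus(corpus, config=None, rule_set=None) -> pd.DataFrame:
    """Classify every spectrum and tabulate predictions against ground truth."""
    from .rule_classifier import ClassifierConfig, classify_spectrum, load_rule_set

    config = config or ClassifierConfig()
    rule_set = rule_set or load_rule_set()
    library = default_loss_library()
    rows = []
    for s, t in corpus:
        result = classify_spectrum(s, config, library, rule_set)
        rows.append(
            {
                "identifier": t.identifier,
                "true_subtype": t.subtype,
                "true_category": t.category.value,
                "predicted_subtype": result.subtype,
                "predicted_category": result.category.value,
                "score": result.score,
            }
        )
    return pd.DataFrame(rows)


def recovery_rates(results: pd.DataFrame) -> dict[str, float]:
    """Fractions of spectra whose subtype / category were recovered."""
    return {
        "subtype_recovery": float((results.true_subtype == results.predicted_subtype).mean()),
        "category_recovery": float((results.true_category == results.predicted_category).mean()),
    }
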
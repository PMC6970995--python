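"""The category/subtype decision flowchart and substituent inference.

Classification proceeds in two stages:

1. **Category** from the abundance tier of the amine-loss ion
   [M-NHR1R2]+ (searched as precursor minus NH3, CH3NH2 or (CH3)2NH):
   a high-abundance ion (>= ``high_threshold`` of the base peak) gives
   category I, a detectable but weaker ion category II, and no ion within
   tolerance category III -- the hallmark of a p-pi conjugated nitrogen that
   cannot expel its amine.
2. **Subtype** by scoring each of the 19 structural subtypes' diagnostic
   rules (characteristic losses, marker ions, chained losses, the dimer
   half-mass ion, ...) against the fragment graph.  Rules live in a
   human-editable YAML config; each subtype's score is the fired fraction of
   its total rule weight, and ties go to the earlier flowchart branch.

Substituent hypotheses come from the recurring neutral-loss pathways:
methanol (vicinal methoxy + hydroxy), methane (vicinal methoxys or N-methyl
with vicinal H), CH2O/CO (methylenedioxy), methyl radical then CO (methoxy),
methyl radical off an intrinsic cation (quaternary N-methyl), and CO2
(carboxyl).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import yaml

from .loss_annotation import (
    DEFAULT_TOL_PPM,
    FragmentGraph,
    LossMatch,
    NeutralLossEntry,
    build_fragment_graph,
    default_loss_library,
)
from .spectrum_io import IonSpecies, Peak, Spectrum, base_peak
from .taxonomy import Category, SUBTYPE_CATEGORY, subtypes_in

__all__ = [
    "AMINE_LOSSES",
    "ClassifierConfig",
    "AbundanceTier",
    "DiagnosticEvidence",
    "TypeAssignment",
    "SubstituentHypothesis",
    "RuleSet",
    "load_rule_set",
    "nhr_loss_tier",
    "classify_category",
    "classify_subtype",
    "classify_spectrum",
    "infer_substituents",
]

#: The three amine losses that define the category split, by N-substitution.
AMINE_LOSSES = ("NH3", "CH5N", "C2H7N")

#: m/z of a hydrogen atom as conventionally printed in the half-mass rule.
_H_ATOM = 1.0078


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable classification parameters.

    ``high_threshold`` separates "high-abundance" from "low-abundance"
    amine-loss ions as a fraction of the base peak.  The source study never
    quantifies the distinction; 0.05 separates base-peak-scale ions from
    trace ions and is freely configurable.  ``significance_floor`` plays the
    same role for the absence-style aporphine rule.
    """

    tol_ppm: float = DEFAULT_TOL_PPM
    high_threshold: float = 0.05
    significance_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0 or not (0 < self.high_threshold < 1):
            raise ValueError("tol_ppm must be > 0 and high_threshold in (0, 1)")


@dataclass(frozen=True)
class AbundanceTier:
    tier: str  # "high" | "low" | "absent"
    relative_intensity: float | None = None  # fraction of base peak, [0, 1]


@dataclass(frozen=True)
class DiagnosticEvidence:
    rule_id: str
    description: str
    matched: tuple[str, ...] = ()
    weight: float = 1.0


@dataclass(frozen=True)
class TypeAssignment:
    category: Category
    subtype: str  # one of the 19 labels or "undetermined"
    score: float
    evidence: tuple[DiagnosticEvidence, ...] = ()
    alternatives: tuple[tuple[str, float], ...] = ()
    tier: AbundanceTier | None = None


@dataclass(frozen=True)
class SubstituentHypothesis:
    substituent: str
    description: str
    edges: tuple[LossMatch, ...] = ()


# ---------------------------------------------------------------------------
# Rule set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Rule:
    rule_id: str
    kind: str
    params: dict
    weight: float
    description: str


@dataclass(frozen=True)
class _SubtypeRules:
    subtype: str
    category: Category
    rules: tuple[_Rule, ...]

    @property
    def total_weight(self) -> float:
        return sum(r.weight for r in self.rules)


@dataclass(frozen=True)
class RuleSet:
    subtypes: tuple[_SubtypeRules, ...]

    def for_category(self, category: Category) -> tuple[_SubtypeRules, ...]:
        return tuple(s for s in self.subtypes if s.category is category)


def load_rule_set(path: str | Path | None = None) -> RuleSet:
    """Load the subtype rule config (packaged default, or a user override)."""
    if path is None:
        ref = importlib.resources.files("isofrag.data").joinpath("rules.yaml")
        with importlib.resources.as_file(ref) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    entries: list[_SubtypeRules] = []
    for block in raw["subtypes"]:
        subtype = block["subtype"]
        if subtype not in SUBTYPE_CATEGORY:
            raise ValueError(f"rule config names unknown subtype {subtype!r}")
        rules = tuple(
            _Rule(
                rule_id=r["id"],
                kind=r["kind"],
                params={k: v for k, v in r.items() if k not in {"id", "kind", "weight", "description"}},
                weight=float(r.get("weight", 1.0)),
                description=r.get("description", ""),
            )
            for r in block["rules"]
        )
        entries.append(_SubtypeRules(subtype, SUBTYPE_CATEGORY[subtype], rules))
    return RuleSet(tuple(entries))


# ---------------------------------------------------------------------------
# Category: amine-loss abundance tier
# ---------------------------------------------------------------------------

def _peaks_near(s: Spectrum, target_mz: float, tol_ppm: float) -> list[Peak]:
    half = target_mz * tol_ppm * 1e-6
    return [p for p in s.peaks if abs(p.mz - target_mz) <= half]


def nhr_loss_tier(
    s: Spectrum,
    library: Sequence[NeutralLossEntry] | None = None,
    tol_ppm: float = DEFAULT_TOL_PPM,
    high_threshold: float = 0.05,
) -> tuple[AbundanceTier, str | None]:
    """Abundance tier of the amine-loss ion and which amine loss matched.

    Searches the precursor minus each of NH3 / CH5N / C2H7N within the ppm
    tolerance.  If several amine losses match, the most intense peak wins.
    """
    if library is None:
        library = default_loss_library()
    by_name = {e.name: e for e in library}
    hits: list[tuple[Peak, str]] = []
    for name in AMINE_LOSSES:
        entry = by_name.get(name)
        if entry is None:
            continue
        for p in _peaks_near(s, s.precursor.mz - entry.mass, tol_ppm):
            hits.append((p, name))
    if not hits or not s.peaks:
        return AbundanceTier("absent", None), None
    peak, name = max(hits, key=lambda t: (t[0].intensity, -t[0].mz))
    rel = s.relative_intensity(peak)
    tier = "high" if rel >= high_threshold else "low"
    return AbundanceTier(tier, rel), name


def classify_category(
    s: Spectrum,
    config: ClassifierConfig = ClassifierConfig(),
    library: Sequence[NeutralLossEntry] | None = None,
) -> tuple[Category, DiagnosticEvidence]:
    """Category I/II/III from the amine-loss tier (high/low/absent)."""
    tier, loss_name = nhr_loss_tier(s, library, config.tol_ppm, config.high_threshold)
    category = {"high": Category.I, "low": Category.II, "absent": Category.III}[tier.tier]
    if tier.tier == "absent":
        desc = "no amine-loss ion within tolerance (p-pi conjugated nitrogen)"
        matched: tuple[str, ...] = ()
    else:
        desc = (
            f"{tier.tier}-abundance [M-{loss_name}]+ ion at "
            f"{tier.relative_intensity:.3f} of base peak"
        )
        matched = (loss_name,)
    return category, DiagnosticEvidence("amine_loss_tier", desc, matched)


# ---------------------------------------------------------------------------
# Subtype rules
# ---------------------------------------------------------------------------

def _eval_rule(
    rule: _Rule, s: Spectrum, graph: FragmentGraph, config: ClassifierConfig
) -> tuple[bool, tuple[str, ...]]:
    kind, p = rule.kind, rule.params
    if kind == "precursor_loss":
        edges = [e for e in graph.edges_named(p["loss"]) if e.parent_is_precursor]
        return bool(edges), tuple(f"{e.parent_mz:.4f}->{e.child_mz:.4f} {e.loss_name}" for e in edges)
    if kind == "any_loss":
        edges = list(graph.edges_named(p["loss"]))
        return bool(edges), tuple(f"{e.parent_mz:.4f}->{e.child_mz:.4f} {e.loss_name}" for e in edges)
    if kind == "losses_present":
        names = list(p["losses"])
        if all(graph.edges_named(n) for n in names):
            return True, tuple(names)
        return False, ()
    if kind == "paired_precursor_losses":
        names = list(p["losses"])
        ok = all(
            any(e.parent_is_precursor for e in graph.edges_named(n)) for n in names
        )
        return ok, tuple(names) if ok else ()
    if kind == "loss_chain":
        names = list(p["losses"])
        ok = graph.has_chain(names)
        return ok, tuple(names) if ok else ()
    if kind == "marker_any":
        matched: list[str] = []
        for target in p["mz"]:
            if "tol_da" in p:
                found = [pk for pk in s.peaks if abs(pk.mz - target) <= float(p["tol_da"])]
            else:
                found = _peaks_near(s, float(target), config.tol_ppm)
            matched += [f"marker {target} ~ {pk.mz:.4f}" for pk in found]
        return bool(matched), tuple(matched)
    if kind == "no_significant_peaks_below":
        cutoff = float(p["mz_cutoff"])
        offenders = [
            pk for pk in s.peaks
            if pk.mz < cutoff and s.relative_intensity(pk) >= config.significance_floor
        ]
        return (not offenders), (f"no significant peak below m/z {cutoff:g}",) if not offenders else ()
    if kind == "half_mass_peak":
        target = (s.precursor.mz - _H_ATOM) / 2.0
        found = _peaks_near(s, target, config.tol_ppm)
        return bool(found), tuple(f"half-mass {target:.4f} ~ {pk.mz:.4f}" for pk in found)
    if kind == "single_h2o_loss":
        edges = graph.edges_named("H2O")
        ok = len(edges) == 1 and edges[0].parent_is_precursor
        return ok, tuple(f"{e.parent_mz:.4f}->{e.child_mz:.4f} H2O" for e in edges) if ok else ()
    if kind == "fallback":
        # handled by classify_subtype once the other subtypes are scored
        return False, ()
    raise ValueError(f"unknown rule kind {kind!r}")


def classify_subtype(
    s: Spectrum,
    category: Category,
    graph: FragmentGraph,
    config: ClassifierConfig = ClassifierConfig(),
    rule_set: RuleSet | None = None,
) -> TypeAssignment:
    """Best-scoring subtype of *category* with its full evidence trail.

    Evaluates each subtype's rules in flowchart order; the score is the
    fired fraction of the subtype's total rule weight.  In category III a
    spectrum firing no diagnostic at all falls back to
    tetrahydrobenzoquinoline (the one subtype defined by the absence of the
    others' patterns), provided the spectrum has fragments to reason about.
    """
    if rule_set is None:
        rule_set = load_rule_set()
    if category is Category.UNDETERMINED:
        return TypeAssignment(category, "undetermined", 0.0)

    scored: list[tuple[str, float, tuple[DiagnosticEvidence, ...]]] = []
    fallback_block: _SubtypeRules | None = None
    any_fired = False
    for block in rule_set.for_category(category):
        if any(r.kind == "fallback" for r in block.rules):
            fallback_block = block
            continue
        fired_weight = 0.0
        evidence: list[DiagnosticEvidence] = []
        for rule in block.rules:
            fired, matched = _eval_rule(rule, s, graph, config)
            if fired:
                fired_weight += rule.weight
                evidence.append(DiagnosticEvidence(rule.rule_id, rule.description, matched, rule.weight))
        score = fired_weight / block.total_weight if block.total_weight else 0.0
        if score > 0:
            any_fired = True
        scored.append((block.subtype, score, tuple(evidence)))

    if not any_fired and fallback_block is not None and len(s.peaks) > 0:
        rule = next(r for r in fallback_block.rules if r.kind == "fallback")
        ev = DiagnosticEvidence(rule.rule_id, rule.description, ("no other category-III diagnostic fired",), rule.weight)
        alternatives = tuple((st, sc) for st, sc, _ in scored)
        return TypeAssignment(category, fallback_block.subtype, 1.0, (ev,), alternatives)

    if not any_fired:
        return TypeAssignment(category, "undetermined", 0.0, (), tuple((st, 0.0) for st, _, _ in scored))

    best = max(scored, key=lambda t: t[1])  # max() keeps the earliest on ties
    alternatives = tuple((st, sc) for st, sc, _ in scored if st != best[0] and sc > 0)
    return TypeAssignment(category, best[0], best[1], best[2], alternatives)


def classify_spectrum(
    s: Spectrum,
    config: ClassifierConfig = ClassifierConfig(),
    library: Sequence[NeutralLossEntry] | None = None,
    rule_set: RuleSet | None = None,
    graph: FragmentGraph | None = None,
) -> TypeAssignment:
    """Full pipeline: amine-loss tier -> category -> subtype assignment."""
    if library is None:
        library = default_loss_library()
    tier, _ = nhr_loss_tier(s, library, config.tol_ppm, config.high_threshold)
    category, cat_evidence = classify_category(s, config, library)
    if graph is None:
        graph = build_fragment_graph(s, library, config.tol_ppm)
    result = classify_subtype(s, category, graph, config, rule_set)
    return replace(result, evidence=(cat_evidence,) + result.evidence, tier=tier)


# ---------------------------------------------------------------------------
# Substituent inference from the common fragmentation pathways
# ---------------------------------------------------------------------------

def infer_substituents(graph: FragmentGraph) -> list[SubstituentHypothesis]:
    """Structural-substituent hypotheses implied by the annotated losses."""
    out: list[SubstituentHypothesis] = []

    def grab(name: str) -> tuple[LossMatch, ...]:
        return graph.edges_named(name)

    if grab("CH4O"):
        out.append(SubstituentHypothesis(
            "vicinal methoxy + hydroxy", "neutral loss of a CH3OH molecule", grab("CH4O")))
    if grab("CH4"):
        out.append(SubstituentHypothesis(
            "vicinal methoxy groups or N-methyl with vicinal H", "elimination of a CH4 moiety", grab("CH4")))
    md = grab("CH2O") + grab("CO")
    if md:
        out.append(SubstituentHypothesis(
            "methylenedioxy", "loss of a CH2O moiety or CO molecule", md))
    # methyl radical then CO on a chained path -> methoxy
    ch3_children = {e.child_mz for e in grab("CH3")}
    methoxy_chain = tuple(
        e for e in grab("CO") if not e.parent_is_precursor and e.parent_mz in ch3_children
    )
    if methoxy_chain:
        ch3_part = tuple(e for e in grab("CH3") if e.child_mz in {c.parent_mz for c in methoxy_chain})
        out.append(SubstituentHypothesis(
            "methoxy", "ejection of a methyl radical followed by a CO molecule",
            ch3_part + methoxy_chain))
    if graph.spectrum.precursor.species is IonSpecies.INTRINSIC_CATION:
        quat = tuple(e for e in grab("CH3") if e.parent_is_precursor)
        if quat:
            out.append(SubstituentHypothesis(
                "quaternary N-methyl", "[M-CH3]+ radical loss from the quaternary nitrogen", quat))
    if grab("CO2"):
        out.append(SubstituentHypothesis(
            "carboxyl", "[fragment-CO2]+ ions indicate a -COOH group", grab("CO2")))
    return out
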
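"""Neutral-loss matching and fragment-graph construction.

A mass difference between two ions (precursor -> fragment, or fragment ->
fragment) is annotated by comparing it against a library of characteristic
neutral losses at a ppm tolerance.  The resulting :class:`FragmentGraph` is
the evidence structure the classifier reasons over: nodes are the precursor
and the peaks, edges are matched losses with their signed ppm errors.

The ppm error of a candidate match is expressed relative to the *child's*
theoretical position (parent m/z minus the loss mass), since the fragment is
the mass-measured quantity.  Matches outside tolerance are rejected outright
-- e.g. a putative methylamine loss that lands ~76 ppm away is not an edge at
any sensible tolerance.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .chem_formula import ElementalFormula, monoisotopic_mass, parse_formula
from .spectrum_io import Peak, Spectrum

__all__ = [
    "DEFAULT_TOL_PPM",
    "NeutralLossEntry",
    "LossMatch",
    "FragmentGraph",
    "LossLibraryError",
    "default_loss_library",
    "load_loss_library",
    "save_loss_library",
    "match_loss",
    "build_fragment_graph",
]

#: Default matching tolerance.  Accepted assignments in the underlying
#: fragmentation study cluster within ~3 ppm while the one explicitly
#: rejected candidate sits at ~76 ppm; 10 ppm leaves headroom for instrument
#: drift without admitting such outliers.
DEFAULT_TOL_PPM = 10.0


class LossLibraryError(ValueError):
    """Corrupt or inconsistent loss-library file."""


@dataclass(frozen=True)
class NeutralLossEntry:
    """A named characteristic neutral loss.

    ``mass`` is derived from the formula at load time; a stored mass that
    disagrees with the formula's monoisotopic mass (4-decimal display) is a
    load error.
    """

    name: str
    formula: ElementalFormula
    substituent_tag: str = ""
    diagnostic_roles: frozenset[str] = frozenset()
    description: str = ""

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @property
    def radical(self) -> bool:
        return self.formula.radical

    @property
    def n_atoms(self) -> int:
        return sum(self.formula.counts.values())


@dataclass(frozen=True)
class LossMatch:
    """One annotated mass difference: parent ion -> child ion via a loss."""

    parent_mz: float
    child_mz: float
    entry: NeutralLossEntry
    ppm: float
    parent_is_precursor: bool

    @property
    def loss_name(self) -> str:
        return self.entry.name


@dataclass(frozen=True)
class FragmentGraph:
    """Peaks linked by matched neutral losses.

    Edges always run from higher to lower m/z, so the graph is acyclic by
    construction.  ``unmatched`` lists peaks with no incident edge.  Radical
    parity of fragment nodes is not tracked here because peak formulas are
    unknown; the radical flag travels on each edge's library entry.
    """

    spectrum: Spectrum
    edges: tuple[LossMatch, ...]
    unmatched: tuple[Peak, ...]
    tol_ppm: float = DEFAULT_TOL_PPM

    def edges_from_precursor(self) -> tuple[LossMatch, ...]:
        return tuple(e for e in self.edges if e.parent_is_precursor)

    def edges_named(self, loss_name: str) -> tuple[LossMatch, ...]:
        return tuple(e for e in self.edges if e.loss_name == loss_name)

    def has_chain(self, loss_names: Sequence[str]) -> bool:
        """True if successive losses ``loss_names`` chain from the precursor."""
        frontier = {None}  # None stands for the precursor node
        for name in loss_names:
            nxt: set[float] = set()
            for e in self.edges:
                if e.loss_name != name:
                    continue
                if None in frontier and e.parent_is_precursor:
                    nxt.add(e.child_mz)
                elif not e.parent_is_precursor and e.parent_mz in frontier:
                    nxt.add(e.child_mz)
            if not nxt:
                return False
            frontier = nxt  # type: ignore[assignment]
        return True

    def to_table(self) -> pd.DataFrame:
        """Edge table: parent_mz, child_mz, loss, ppm, parent_is_precursor."""
        return pd.DataFrame(
            [
                {
                    "parent_mz": round(e.parent_mz, 6),
                    "child_mz": round(e.child_mz, 6),
                    "loss": e.loss_name,
                    "ppm": round(e.ppm, 2),
                    "parent_is_precursor": e.parent_is_precursor,
                }
                for e in self.edges
            ],
            columns=["parent_mz", "child_mz", "loss", "ppm", "parent_is_precursor"],
        )


# ---------------------------------------------------------------------------
# Library I/O
# ---------------------------------------------------------------------------

def _parse_library_frame(df: pd.DataFrame, origin: str) -> list[NeutralLossEntry]:
    required = {"name", "formula"}
    if not required.issubset(df.columns):
        raise LossLibraryError(f"{origin}: loss library needs columns {sorted(required)}")
    entries: list[NeutralLossEntry] = []
    for _, row in df.iterrows():
        formula = parse_formula(str(row["formula"]))
        entry = NeutralLossEntry(
            name=str(row["name"]),
            formula=formula,
            substituent_tag="" if pd.isna(row.get("substituent_tag")) else str(row.get("substituent_tag", "")),
            diagnostic_roles=frozenset(
                r for r in str(row.get("diagnostic_roles", "") or "").split(",") if r
            ),
            description="" if pd.isna(row.get("description")) else str(row.get("description", "")),
        )
        if "mass" in df.columns and not pd.isna(row["mass"]):
            stored = float(row["mass"])
            if abs(stored - round(entry.mass, 4)) > 5e-5:
                raise LossLibraryError(
                    f"{origin}: stored mass {stored} for {entry.name} disagrees with "
                    f"formula mass {entry.mass:.4f}"
                )
        entries.append(entry)
    if len({e.name for e in entries}) != len(entries):
        raise LossLibraryError(f"{origin}: duplicate loss names")
    return entries


def load_loss_library(path: str | Path) -> list[NeutralLossEntry]:
    """Load a user loss library from a tab-delimited file."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return _parse_library_frame(df, str(path))


def default_loss_library() -> list[NeutralLossEntry]:
    """The packaged library of characteristic isoquinoline-alkaloid losses."""
    ref = importlib.resources.files("isofrag.data").joinpath("losses.tsv")
    with importlib.resources.as_file(ref) as p:
        return load_loss_library(p)


def save_loss_library(entries: Iterable[NeutralLossEntry], path: str | Path) -> None:
    """Write a loss library as a tab-delimited file (mass column included)."""
    rows = [
        {
            "name": e.name,
            "formula": e.formula.hill() + ("." if e.radical else ""),
            "mass": round(e.mass, 4),
            "substituent_tag": e.substituent_tag,
            "diagnostic_roles": ",".join(sorted(e.diagnostic_roles)),
            "description": e.description,
        }
        for e in entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def match_loss(
    parent_mz: float,
    child_mz: float,
    library: Sequence[NeutralLossEntry],
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> list[tuple[NeutralLossEntry, float]]:
    """Rank library losses consistent with the difference parent - child.

    Returns ``(entry, ppm)`` pairs with ``|ppm| <= tol_ppm``, sorted by
    ``|ppm|`` then by fewer atoms; empty when nothing matches.  The ppm is
    relative to the child's theoretical position (parent minus loss mass).
    """
    if parent_mz <= child_mz:
        raise ValueError(f"parent m/z ({parent_mz}) must exceed child m/z ({child_mz})")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    out: list[tuple[NeutralLossEntry, float]] = []
    for entry in library:
        expected_child = parent_mz - entry.mass
        if expected_child <= 0:
            continue
        ppm = (child_mz - expected_child) / expected_child * 1e6
        if abs(ppm) <= tol_ppm:
            out.append((entry, ppm))
    out.sort(key=lambda t: (abs(t[1]), t[0].n_atoms, t[0].name))
    return out


def build_fragment_graph(
    s: Spectrum,
    library: Sequence[NeutralLossEntry] | None = None,
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> FragmentGraph:
    """Annotate a spectrum's mass differences into a :class:`FragmentGraph`.

    Edges run from the precursor to each matched peak and between peak pairs.
    For each (child, loss name) only the smallest-|ppm| incoming edge is kept;
    two *different* losses matching the same parent/child pair are both kept.
    Construction is deterministic and invariant to the input peak order.
    """
    if library is None:
        library = default_loss_library()
    parents: list[tuple[float, bool]] = [(s.precursor.mz, True)]
    parents += [(p.mz, False) for p in s.peaks]

    best: dict[tuple[float, str], LossMatch] = {}
    for parent_mz, is_prec in parents:
        for child in s.peaks:
            if child.mz >= parent_mz:
                continue
            for entry, ppm in match_loss(parent_mz, child.mz, library, tol_ppm):
                key = (child.mz, entry.name)
                cur = best.get(key)
                if cur is None or abs(ppm) < abs(cur.ppm) or (
                    abs(ppm) == abs(cur.ppm) and parent_mz < cur.parent_mz
                ):
                    best[key] = LossMatch(parent_mz, child.mz, entry, ppm, is_prec)

    edges = tuple(sorted(best.values(), key=lambda e: (e.parent_mz, e.child_mz, e.loss_name)))
    touched = {e.child_mz for e in edges} | {e.parent_mz for e in edges if not e.parent_is_precursor}
    unmatched = tuple(p for p in s.peaks if p.mz not in touched)
    return FragmentGraph(spectrum=s, edges=edges, unmatched=unmatched, tol_ppm=tol_ppm)
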
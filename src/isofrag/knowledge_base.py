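"""Queryable reference data: the 66 study compounds and the DFT energetics.

The compound table records each reference alkaloid's subtype, precursor
species ([M+H]+ vs intrinsic [M]+), molecular formula (standard published
identity where assignable) and every m/z value printed for it, verbatim.
The DFT table stores relative energies of protonation sites, fragmentation
pathway intermediates and bond-dissociation energies -- reference numbers
only, never recomputed here.

Integrity is validated at load: unique indices 1-66, known subtype labels,
parsable formulas, and <= 20 ppm agreement between each printed precursor
m/z and its formula's theoretical value.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chem_formula import ElementalFormula, ion_mz, parse_formula, ppm_error
from .spectrum_io import IonSpecies
from .taxonomy import SUBTYPE_CATEGORY

__all__ = [
    "PrintedIon",
    "ReferenceCompound",
    "DftReferenceRecord",
    "KnowledgeBaseError",
    "load_reference_compounds",
    "get_compound",
    "load_dft_records",
    "compounds_table",
]

#: Printed precursor m/z must agree with the assigned formula within this bound.
PRECURSOR_AGREEMENT_PPM = 20.0


class KnowledgeBaseError(ValueError):
    """Packaged reference data failed its integrity checks."""


@dataclass(frozen=True)
class PrintedIon:
    mz: float
    role: str
    section: str


@dataclass(frozen=True)
class ReferenceCompound:
    index: int
    name: str
    subtype: str
    species: IonSpecies
    formula: ElementalFormula | None = None
    printed_precursor_mz: float | None = None
    note: str = ""
    printed_ions: tuple[PrintedIon, ...] = ()

    @property
    def precursor_formula(self) -> ElementalFormula | None:
        """The +1 precursor cation formula ([M+H]+ or [M]+), if known."""
        if self.formula is None:
            return None
        if self.species is IonSpecies.INTRINSIC_CATION:
            return self.formula
        return self.formula + ElementalFormula({"H": 1}, charge=1)

    @property
    def theoretical_precursor_mz(self) -> float | None:
        f = self.precursor_formula
        return None if f is None else ion_mz(f)


@dataclass(frozen=True)
class DftReferenceRecord:
    label: str
    relative_energy: float  # kcal/mol
    context: str  # protonation_site | pathway | bond_dissociation
    derived: bool = False
    note: str = ""


def _data_path(name: str):
    return importlib.resources.files("isofrag.data").joinpath(name)


def _read_tsv(name: str) -> pd.DataFrame:
    ref = _data_path(name)
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_reference_compounds() -> list[ReferenceCompound]:
    """Load and validate all 66 reference compounds with their printed ions."""
    comp = _read_tsv("compounds.tsv")
    ions = _read_tsv("printed_ions.tsv")
    by_index: dict[int, list[PrintedIon]] = {}
    for _, row in ions.iterrows():
        by_index.setdefault(int(row["index"]), []).append(
            PrintedIon(float(row["mz"]), str(row["role"]), str(row["section"]))
        )

    out: list[ReferenceCompound] = []
    for _, row in comp.iterrows():
        idx = int(row["index"])
        subtype = str(row["subtype"])
        if subtype not in SUBTYPE_CATEGORY:
            raise KnowledgeBaseError(f"compound {idx}: unknown subtype {subtype!r}")
        species = IonSpecies.INTRINSIC_CATION if row["species"] == "intrinsic_cation" else IonSpecies.PROTONATED
        raw_formula = row.get("formula")
        formula = None
        if isinstance(raw_formula, str) and raw_formula.strip():
            formula = parse_formula(raw_formula.strip())
            if species is IonSpecies.INTRINSIC_CATION and formula.charge != 1:
                raise KnowledgeBaseError(f"compound {idx}: intrinsic cation needs a '+' formula")
            if species is IonSpecies.PROTONATED and formula.charge != 0:
                raise KnowledgeBaseError(f"compound {idx}: protonated species needs a neutral formula")
        printed = row.get("printed_precursor_mz")
        printed_mz = None if pd.isna(printed) else float(printed)
        rc = ReferenceCompound(
            index=idx,
            name=str(row["name"]),
            subtype=subtype,
            species=species,
            formula=formula,
            printed_precursor_mz=printed_mz,
            note="" if pd.isna(row.get("note")) else str(row.get("note", "")),
            printed_ions=tuple(by_index.get(idx, ())),
        )
        if rc.printed_precursor_mz is not None and rc.theoretical_precursor_mz is not None:
            err = ppm_error(rc.printed_precursor_mz, rc.theoretical_precursor_mz)
            if abs(err) > PRECURSOR_AGREEMENT_PPM:
                raise KnowledgeBaseError(
                    f"compound {idx} ({rc.name}): printed precursor {rc.printed_precursor_mz} "
                    f"is {err:.1f} ppm from formula value"
                )
        out.append(rc)

    indices = [c.index for c in out]
    if sorted(indices) != list(range(1, 67)):
        raise KnowledgeBaseError("compound table must contain indices 1..66 exactly once each")
    return out


def get_compound(index: int) -> ReferenceCompound:
    """Fetch one reference compound by its 1-66 index."""
    for c in load_reference_compounds():
        if c.index == index:
            return c
    raise KeyError(f"no reference compound with index {index} (valid: 1-66)")


def load_dft_records() -> list[DftReferenceRecord]:
    """Verbatim DFT reference energies (kcal/mol)."""
    df = _read_tsv("dft_records.tsv")
    records = [
        DftReferenceRecord(
            label=str(row["label"]),
            relative_energy=float(row["relative_energy_kcal_mol"]),
            context=str(row["context"]),
            derived=bool(int(row["derived"])),
            note="" if pd.isna(row.get("note")) else str(row.get("note", "")),
        )
        for _, row in df.iterrows()
    ]
    nitrogen = [r for r in records if r.context == "protonation_site" and r.label == "Nitrogen"]
    if not nitrogen or nitrogen[0].relative_energy != 0.0:
        raise KnowledgeBaseError("protonation-site table must anchor Nitrogen at 0.0 kcal/mol")
    return records


def compounds_table() -> pd.DataFrame:
    """The compound knowledge base as a flat DataFrame (for export)."""
    rows = []
    for c in load_reference_compounds():
        rows.append(
            {
                "index": c.index,
                "name": c.name,
                "subtype": c.subtype,
                "species": c.species.value,
                "formula": c.formula.hill() if c.formula else "",
                "printed_precursor_mz": c.printed_precursor_mz,
                "theoretical_precursor_mz": (
                    round(c.theoretical_precursor_mz, 4) if c.theoretical_precursor_mz else None
                ),
                "n_printed_ions": len(c.printed_ions),
                "note": c.note,
            }
        )
    return pd.DataFrame(rows)
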
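"""Elemental formulas and exact-mass arithmetic for singly charged alkaloid ions.

Every quantity in this package ultimately reduces to monoisotopic formula
arithmetic: neutral-loss masses, theoretical ion m/z values (with the
one-electron correction for cations), and the signed ppm mass errors used to
accept or reject a fragment assignment.

Conventions
-----------
* Atomic masses are fixed monoisotopic values frozen in :data:`ATOMIC_MASSES`
  (8-decimal precision) so that every derived number is bit-reproducible.
* Only charge states 0 (neutral losses) and +1 (all ions in scope) are
  supported; positive ESI of these alkaloids yields exclusively singly
  charged [M+H]+ or intrinsic [M]+ species.
* Theoretical m/z values are *displayed* at 4 decimals, and the ppm error is
  computed against the 4-decimal-rounded theoretical value.  This convention
  reproduces published error annotations (e.g. an observed 328.1542 against
  theoretical 328.1543 gives -0.30 ppm) which unrounded division does not.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "ATOMIC_MASSES",
    "ELECTRON_MASS",
    "ElementalFormula",
    "FormulaError",
    "InfeasibleLossError",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_error",
    "formula_add",
    "formula_subtract",
]

#: Monoisotopic atomic masses in Da (CODATA/IUPAC), frozen at 8 decimals.
ATOMIC_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    # Extensions beyond the core alkaloid elements; same source precision.
    "S": 31.97207117,
    "P": 30.97376200,
    "Na": 22.98976928,
    "Cl": 34.96885268,
}

#: Electron rest mass in Da; subtracted once for every +1 cation.
ELECTRON_MASS = 0.00054858

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed or chemically unknown formula text."""


class InfeasibleLossError(ValueError):
    """Subtraction would drive an element count negative.

    Raised when a candidate neutral loss cannot be carved out of a parent
    formula; the annotator uses this to prune impossible assignments.
    """


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> count map with charge and radical-parity bookkeeping.

    Parameters
    ----------
    counts
        Mapping from element symbol to a non-negative integer count.  Zero
        counts are dropped on construction; the all-zero formula is the
        additive identity.
    charge
        0 for neutral species, +1 for the cations in scope.
    radical
        True for odd-electron species (e.g. the CH3 radical, or the radical
        cation left behind after its loss).  Parity flips whenever a radical
        species is added to or subtracted from an even-electron one.
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0
    radical: bool = False

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for sym, n in self.counts.items():
            if sym not in ATOMIC_MASSES:
                raise FormulaError(f"unknown element symbol {sym!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"count for {sym} must be a non-negative integer, got {n!r}")
            if n > 0:
                clean[sym] = n
        object.__setattr__(self, "counts", clean)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return ElementalFormula(merged, self.charge + other.charge, self.radical ^ other.radical)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            left = merged.get(sym, 0) - n
            if left < 0:
                raise InfeasibleLossError(
                    f"cannot subtract {other.hill()} from {self.hill()}: {sym} count would go negative"
                )
            merged[sym] = left
        return ElementalFormula(merged, self.charge - other.charge, self.radical ^ other.radical)

    def __bool__(self) -> bool:
        return bool(self.counts)

    # -- presentation -------------------------------------------------------

    def hill(self) -> str:
        """Hill-notation string (C first, H second, then alphabetical)."""
        order = sorted(self.counts, key=lambda s: (s != "C", s != "H", s))
        body = "".join(f"{s}{self.counts[s] if self.counts[s] != 1 else ''}" for s in order)
        return body + ("+" if self.charge == 1 else "")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-notation formula string, e.g. ``"C17H20NO3+"``.

    A single trailing ``+`` sets charge +1; a trailing ``.`` marks an
    odd-electron (radical) species.  Unknown element symbols and malformed
    counts are rejected with the offending token and position named.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    body = text.strip()
    radical = False
    charge = 0
    if body.endswith("."):
        radical = True
        body = body[:-1]
    if body.endswith("+"):
        charge = 1
        body = body[:-1]
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(body):
        m = _TOKEN.match(body, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        sym, digits = m.groups()
        if sym not in ATOMIC_MASSES:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementalFormula(counts, charge, radical)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic mass in Da of a *neutral* formula.

    The empty formula weighs exactly 0.  Charged input is a contract
    violation -- use :func:`ion_mz`, which applies the electron correction.
    """
    if f.charge != 0:
        raise ValueError("monoisotopic_mass is defined for neutral formulas; use ion_mz for cations")
    return sum(ATOMIC_MASSES[sym] * n for sym, n in f.counts.items())


def ion_mz(f: ElementalFormula) -> float:
    """Theoretical m/z of a +1 cation: atomic mass sum minus one electron."""
    if f.charge != 1:
        raise ValueError("ion_mz requires charge +1; use monoisotopic_mass for neutrals")
    return sum(ATOMIC_MASSES[sym] * n for sym, n in f.counts.items()) - ELECTRON_MASS


def ppm_error(observed: float, theoretical: float, decimals: int = 4) -> float:
    """Signed mass error in parts-per-million.

    The theoretical value is first rounded to ``decimals`` places (the display
    precision of published m/z values) before division:
    ``(observed - round(theoretical)) / round(theoretical) * 1e6``.
    """
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    t = round(theoretical, decimals)
    return (observed - t) / t * 1e6


def formula_add(a: ElementalFormula, b: ElementalFormula) -> ElementalFormula:
    """Elementwise sum of two formulas (charges add, radical parity XORs)."""
    return a + b


def formula_subtract(a: ElementalFormula, b: ElementalFormula) -> ElementalFormula:
    """Elementwise difference ``a - b``; infeasible losses raise."""
    return a - b
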
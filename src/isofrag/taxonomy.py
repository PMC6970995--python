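"""Canonical names for the three categories and 19 structural subtypes.

Category membership follows the abundance tier of the amine-loss ion
[M-NHR1R2]+: high-abundance -> category I, low-abundance -> category II,
absent (p-pi conjugated nitrogen) -> category III.
"""

from __future__ import annotations

from enum import Enum

__all__ = ["Category", "SUBTYPE_CATEGORY", "SUBTYPES", "subtypes_in"]


class Category(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    UNDETERMINED = "undetermined"


#: Subtype label -> parent category, in flowchart evaluation order.
SUBTYPE_CATEGORY: dict[str, Category] = {
    # category I: high-abundance amine loss
    "chelidonine": Category.I,
    "ipecac": Category.I,
    "bisbenzyltetrahydroisoquinoline": Category.I,
    "benzyltetrahydroisoquinoline": Category.I,
    "aporphine": Category.I,
    # category II: low-abundance amine loss
    "protopine": Category.II,
    "n_methyltetrahydroprotoberberine": Category.II,
    "tetrahydroprotoberberine": Category.II,
    "morphinan": Category.II,
    "phthalideisoquinoline": Category.II,
    # category III: amine loss absent
    "benzophenanthridine_dimer": Category.III,
    "narciclasine": Category.III,
    "anortianamide": Category.III,
    "dihydrobenzophenanthridine": Category.III,
    "dihydroprotoberberine_7_8": Category.III,
    "protoberberine": Category.III,
    "benzophenanthridine": Category.III,
    "benzoquinoline": Category.III,
    "tetrahydrobenzoquinoline": Category.III,
}

SUBTYPES: tuple[str, ...] = tuple(SUBTYPE_CATEGORY)


def subtypes_in(category: Category) -> tuple[str, ...]:
    """Subtype labels belonging to *category*, in flowchart order."""
    return tuple(s for s, c in SUBTYPE_CATEGORY.items() if c is category)
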
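"""Reading and writing centroided MS/MS spectra with precursor metadata.

Supported on-disk forms are MGF (Mascot Generic Format, via pyteomics) and
plain two-column delimited peak tables.  The in-memory container is
:class:`Spectrum`: a precursor descriptor plus an m/z-sorted centroided peak
list.  Intensities are kept as read; relative abundances (fractions of the
base peak) are computed on demand because the classification rules reason in
relative terms.

MGF dialect: one precursor m/z on the PEPMASS line, CHARGE fixed at ``1+``
(everything in scope is singly charged), and an optional ``SPECIES=M+`` tag
inside TITLE marking an intrinsic cation (quaternary nitrogen) rather than a
protonated molecule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from pyteomics import mgf as _mgf

from .chem_formula import ElementalFormula, ion_mz, ppm_error

__all__ = [
    "IonSpecies",
    "Peak",
    "PrecursorIon",
    "Spectrum",
    "SpectrumFormatError",
    "read_mgf",
    "write_mgf",
    "read_peak_table",
    "base_peak",
]

log = logging.getLogger(__name__)

#: Peaks above precursor m/z plus this tolerance are dropped with a warning.
PRECURSOR_OVERSHOOT_PPM = 20.0


class SpectrumFormatError(ValueError):
    """Structurally invalid spectrum file."""


class IonSpecies(str, Enum):
    """Charge carrier of the precursor."""

    PROTONATED = "[M+H]+"
    INTRINSIC_CATION = "[M]+"


@dataclass(frozen=True, order=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class PrecursorIon:
    """Precursor descriptor: measured m/z, charge-carrier species, optional formula.

    When a formula is supplied, its theoretical m/z must agree with the
    measured value within ``sanity_ppm`` (default 20 ppm) -- a coarse guard
    against mismatched metadata, deliberately looser than any matching
    tolerance used downstream.
    """

    mz: float
    species: IonSpecies = IonSpecies.PROTONATED
    formula: ElementalFormula | None = None
    sanity_ppm: float = 20.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("precursor m/z must be positive")
        if self.formula is not None:
            err = ppm_error(self.mz, ion_mz(self.formula))
            if abs(err) > self.sanity_ppm:
                raise ValueError(
                    f"precursor m/z {self.mz} disagrees with formula "
                    f"{self.formula.hill()} by {err:.1f} ppm (> {self.sanity_ppm} ppm)"
                )


@dataclass(frozen=True)
class Spectrum:
    """A centroided MS/MS spectrum: precursor + m/z-sorted peak list."""

    precursor: PrecursorIon
    peaks: tuple[Peak, ...]
    identifier: str = ""
    collision_energy: float | None = None

    def __post_init__(self) -> None:
        limit = self.precursor.mz * (1.0 + PRECURSOR_OVERSHOOT_PPM * 1e-6)
        kept = tuple(sorted((p for p in self.peaks), key=lambda p: p.mz))
        dropped = [p for p in kept if p.mz > limit]
        if dropped:
            log.warning(
                "spectrum %r: dropping %d peak(s) above precursor m/z %.4f",
                self.identifier, len(dropped), self.precursor.mz,
            )
            kept = tuple(p for p in kept if p.mz <= limit)
        object.__setattr__(self, "peaks", kept)

    def __len__(self) -> int:
        return len(self.peaks)

    def relative_intensity(self, peak: Peak) -> float:
        """Intensity of *peak* as a fraction of the base peak, in [0, 1]."""
        return peak.intensity / base_peak(self).intensity


def base_peak(s: Spectrum) -> Peak:
    """Most intense peak; ties broken toward lower m/z."""
    if not s.peaks:
        raise ValueError("base_peak of an empty spectrum")
    return max(s.peaks, key=lambda p: (p.intensity, -p.mz))


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def _species_from_title(title: str) -> IonSpecies:
    if "SPECIES=M+" in title.upper().replace(" ", ""):
        return IonSpecies.INTRINSIC_CATION
    return IonSpecies.PROTONATED


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    One spectrum per BEGIN IONS block.  A block without PEPMASS, or with a
    non-numeric peak line, raises :class:`SpectrumFormatError` naming the
    offending block.
    """
    spectra: list[Spectrum] = []
    try:
        with _mgf.MGF(str(path)) as reader:
            for idx, entry in enumerate(reader):
                params = entry.get("params", {})
                if "pepmass" not in params or params["pepmass"] is None:
                    raise SpectrumFormatError(f"MGF block {idx} ({path}): missing PEPMASS")
                pepmass = params["pepmass"]
                prec_mz = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
                title = str(params.get("title", f"spectrum_{idx}"))
                species = _species_from_title(title)
                ce = params.get("collision_energy")
                peaks = tuple(
                    Peak(float(mz), float(it))
                    for mz, it in zip(entry["m/z array"], entry["intensity array"])
                )
                spectra.append(
                    Spectrum(
                        precursor=PrecursorIon(prec_mz, species),
                        peaks=peaks,
                        identifier=title,
                        collision_energy=float(ce) if ce is not None else None,
                    )
                )
    except SpectrumFormatError:
        raise
    except (ValueError, KeyError) as exc:
        raise SpectrumFormatError(f"malformed MGF file {path}: {exc}") from exc
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF; round-trip safe to 6 decimals in m/z and intensity.

    Output is byte-deterministic for fixed input (fixed float formats, no
    timestamps).
    """
    path = Path(path)
    with path.open("w") as fh:
        for s in spectra:
            title = s.identifier or "spectrum"
            if s.precursor.species is IonSpecies.INTRINSIC_CATION and "SPECIES=M+" not in title:
                title = f"{title} SPECIES=M+"
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={title}\n")
            fh.write(f"PEPMASS={s.precursor.mz:.6f}\n")
            fh.write("CHARGE=1+\n")
            if s.collision_energy is not None:
                fh.write(f"COLLISION_ENERGY={s.collision_energy:.1f}\n")
            for p in s.peaks:
                fh.write(f"{p.mz:.6f} {p.intensity:.6f}\n")
            fh.write("END IONS\n\n")


# ---------------------------------------------------------------------------
# Delimited peak tables
# ---------------------------------------------------------------------------

def read_peak_table(
    path: str | Path,
    precursor_mz: float,
    species: IonSpecies | str = IonSpecies.PROTONATED,
    identifier: str | None = None,
) -> Spectrum:
    """Read a two-column (m/z, intensity) delimited text file as one spectrum.

    The delimiter (tab, comma or whitespace) is auto-detected; lines starting
    with ``#`` are comments.  An empty table is an error.
    """
    if isinstance(species, str):
        species = IonSpecies(species)
    peaks: list[Peak] = []
    path = Path(path)
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").replace("\t", " ").split()
        if len(parts) < 2:
            raise SpectrumFormatError(f"{path}:{lineno}: expected two columns, got {raw!r}")
        try:
            peaks.append(Peak(float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise SpectrumFormatError(f"{path}:{lineno}: non-numeric peak line {raw!r}") from exc
    if not peaks:
        raise SpectrumFormatError(f"{path}: no peaks found")
    return Spectrum(
        precursor=PrecursorIon(float(precursor_mz), species),
        peaks=tuple(peaks),
        identifier=identifier or path.stem,
    )
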
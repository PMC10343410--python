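"""Molecular formulas, monoisotopic masses and adduct m/z arithmetic.

Every screening decision downstream (extracted-ion-chromatogram windows,
fragment matching, confidence assignment) rests on exact-mass arithmetic for
singly charged adducts of small molecules.  Masses are monoisotopic (most
abundant isotope) and the charge carrier is the proton, so protonation adds
1.007276 Da (the hydrogen atom minus one electron) rather than 1.007825 Da.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "WATER_MASS",
    "AMMONIUM_MASS",
    "GLUCOSE_CONDENSATION_MASS",
    "METHYLENE_MASS",
    "MolecularFormula",
    "AdductSpec",
    "MassError",
    "ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "mass_error",
]

# Most-abundant-isotope masses (Da).  Embedded so the core arithmetic has no
# runtime dependency; values from the standard atomic mass evaluation.
MONOISOTOPIC_MASS: Dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "Na": 22.98976928,
    "K": 38.9637069,
    "Cl": 34.96885271,
    "F": 18.9984032,
}

ELECTRON_MASS = 0.00054857990907
#: Mass of the proton: H atom minus one electron.  This is the (de)protonation
#: delta for [M+H]+ / [M-H]-.
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS  # 1.0072764520
WATER_MASS = 2 * MONOISOTOPIC_MASS["H"] + MONOISOTOPIC_MASS["O"]  # 18.0105647
#: NH4+ cation mass (N + 4H - e).
AMMONIUM_MASS = MONOISOTOPIC_MASS["N"] + 4 * MONOISOTOPIC_MASS["H"] - ELECTRON_MASS
#: Net mass added per glucose unit under condensation (glucose - water), C6H10O5.
GLUCOSE_CONDENSATION_MASS = (
    6 * MONOISOTOPIC_MASS["C"] + 10 * MONOISOTOPIC_MASS["H"] + 5 * MONOISOTOPIC_MASS["O"]
)
#: Net mass added per methylation (CH2).
METHYLENE_MASS = MONOISOTOPIC_MASS["C"] + 2 * MONOISOTOPIC_MASS["H"]


class FormulaError(ValueError):
    """Raised for malformed or chemically invalid formula strings."""


_SUBSCRIPT_TRANS = str.maketrans("₀₁₂₃₄₅₆₇₈₉", "0123456789")
_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """An element → count map; the unit of all mass arithmetic.

    Counts are strictly positive (zero-count elements are dropped); all
    symbols must exist in the embedded monoisotopic mass table.  Instances
    are immutable and hashable on the canonical Hill string.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean: Dict[str, int] = {}
        for el, n in self.counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"invalid count for {el}: {n!r}")
            if n > 0:
                clean[el] = n
        object.__setattr__(self, "counts", dict(sorted(clean.items(), key=_hill_key)))

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            left = merged.get(el, 0) - n
            if left < 0:
                raise FormulaError(
                    f"subtraction yields negative count for {el}: {merged.get(el, 0)} - {n}"
                )
            merged[el] = left
        return MolecularFormula(merged)

    def scaled(self, k: int) -> "MolecularFormula":
        if k < 0:
            raise FormulaError("negative multiplier")
        return MolecularFormula({el: n * k for el, n in self.counts.items()})

    def hill(self) -> str:
        """Canonical Hill-notation string (C, H, then alphabetical)."""
        return "".join(
            el + (str(n) if n != 1 else "") for el, n in self.counts.items()
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()

    def __hash__(self) -> int:
        return hash(self.hill())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MolecularFormula) and self.counts == other.counts


def _hill_key(item):
    el = item[0]
    # Hill order: carbon first, hydrogen second, the rest alphabetical.
    return {"C": (0, ""), "H": (1, "")}.get(el, (2, el))


def parse_formula(text: str) -> MolecularFormula:
    """Parse a molecular formula string into canonical element counts.

    Three dialects are accepted and normalised: plain Hill notation
    (``C6H8O7``), Unicode subscript digits (``C₆H₈O₇``) and the
    underscore-delimited dialect (``C_6_H_8_O_7_``) that appears in
    typeset tables.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    normal = text.translate(_SUBSCRIPT_TRANS).replace("_", "").replace(" ", "")
    pos = 0
    counts: Dict[str, int] = {}
    while pos < len(normal):
        m = _TOKEN_RE.match(normal, pos)
        if m is None or m.end() == pos:
            raise FormulaError(f"malformed formula {text!r} at {normal[pos:]!r}")
        el, digits = m.groups()
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if not counts:
        raise FormulaError(f"no elements in formula {text!r}")
    return MolecularFormula(counts)


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Neutral monoisotopic mass in Da (sum of most-abundant-isotope masses)."""
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.counts.items())


@dataclass(frozen=True)
class AdductSpec:
    """A named ionization adduct: signed mass delta applied to the neutral mass.

    The delta carries the charge-agent bookkeeping (proton convention, with
    the electron mass on the charge carrier), so ``m/z = M + mass_delta`` for
    singly charged species.
    """

    name: str
    mass_delta: float
    polarity: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"invalid polarity {self.polarity!r}")


ADDUCTS: Dict[str, AdductSpec] = {
    "[M-H]-": AdductSpec("[M-H]-", -PROTON_MASS, "negative"),
    "[M+H]+": AdductSpec("[M+H]+", +PROTON_MASS, "positive"),
    "[M-H2O+H]+": AdductSpec("[M-H2O+H]+", -WATER_MASS + PROTON_MASS, "positive"),
    "[M+NH4]+": AdductSpec("[M+NH4]+", +AMMONIUM_MASS, "positive"),
}

# Unicode-dash aliases as typeset tables print them.
_ADDUCT_ALIASES = {
    "[M−H]−": "[M-H]-",
    "[M−H]-": "[M-H]-",
    "[M-H]−": "[M-H]-",
    "[M−H2O+H]+": "[M-H2O+H]+",
    "[M−H₂O+H]+": "[M-H2O+H]+",
    "[M-H₂O+H]+": "[M-H2O+H]+",
}


def get_adduct(name: str) -> AdductSpec:
    key = _ADDUCT_ALIASES.get(name, name)
    try:
        return ADDUCTS[key]
    except KeyError:
        raise KeyError(f"unsupported adduct {name!r}") from None


def adduct_mz(formula: MolecularFormula, adduct: AdductSpec | str) -> float:
    """Theoretical m/z of the singly charged adduct of ``formula``."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    return monoisotopic_mass(formula) + adduct.mass_delta


@dataclass(frozen=True)
class MassError:
    """Signed mass error between an experimental and a theoretical m/z."""

    delta_da: float
    delta_ppm: float


def mass_error(experimental_mz: float, theoretical_mz: float) -> MassError:
    """Signed experimental − theoretical difference, in Da and ppm."""
    if experimental_mz <= 0 or theoretical_mz <= 0:
        raise ValueError("m/z values must be positive")
    d = experimental_mz - theoretical_mz
    return MassError(delta_da=d, delta_ppm=d / theoretical_mz * 1e6)
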
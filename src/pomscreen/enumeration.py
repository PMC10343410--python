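"""Combinatorial enumeration of virtual metabolites.

Scaffolds (already-identified natural products) are combined with small
building blocks — one or two glucose units and/or a methyl group, plus
hydrogen to retain the parent — to predict plausible phase-II style
metabolites (glycosylation, methylation).  Mass bookkeeping follows
condensation chemistry: each glucose adds C6H10O5 (162.0528 Da, glucose minus
water) and each methylation adds CH2 (14.0157 Da).

The enumerated products carry diagnostic ions: for glycosides in negative
mode, the deprotonated aglycone and the neutral-loss series at multiples of
the glucose condensation mass.  These stand in for library MS/MS spectra,
which do not exist for virtual metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as iter_product
from typing import List, Optional, Sequence, Tuple

from .chem import (
    GLUCOSE_CONDENSATION_MASS,
    AdductSpec,
    MolecularFormula,
    adduct_mz,
    get_adduct,
    parse_formula,
)

__all__ = [
    "Scaffold",
    "BuildingBlockCombo",
    "EnumeratedProduct",
    "enumerate_products",
    "diagnostic_ions",
    "products_to_suspects",
]

_GLUCOSE_UNIT = parse_formula("C6H10O5")
_METHYLENE = parse_formula("CH2")


@dataclass(frozen=True)
class Scaffold:
    """A parent compound used as an enumeration scaffold."""

    name: str
    formula: MolecularFormula
    smiles: Optional[str] = None  # carried through, never interpreted


@dataclass(frozen=True)
class BuildingBlockCombo:
    """Number of glucose units and methyl groups attached; (0, 0) = hydrogen
    block, i.e. the parent compound itself."""

    n_glucose: int
    n_methyl: int

    def __post_init__(self) -> None:
        if self.n_glucose < 0 or self.n_methyl < 0:
            raise ValueError("building-block counts must be non-negative")


@dataclass(frozen=True)
class EnumeratedProduct:
    name: str
    formula: MolecularFormula
    parent: str
    combo: BuildingBlockCombo
    smiles: Optional[str] = None
    diagnostic: Tuple[Tuple[str, float, str], ...] = field(default_factory=tuple)


def _product_name(parent: str, combo: BuildingBlockCombo) -> str:
    g, m = combo.n_glucose, combo.n_methyl
    if (g, m) == (0, 0):
        return parent
    if m == 0:
        return f"{parent} {'glucoside' if g == 1 else 'diglucoside' if g == 2 else f'+{g}Glc'}"
    parts = []
    if g == 1:
        parts.append("+Glc")
    elif g > 1:
        parts.append(f"+{g}Glc")
    parts.append("+Me" if m == 1 else f"+{m}Me")
    return f"{parent} {''.join(parts)}"


def enumerate_products(
    scaffolds: Sequence[Scaffold],
    max_glucose: int = 2,
    max_methyl: int = 1,
) -> List[EnumeratedProduct]:
    """Enumerate all scaffold × building-block combinations.

    Returns exactly ``len(scaffolds) * (max_glucose+1) * (max_methyl+1)``
    products, ordered by scaffold, then glucose count, then methyl count.
    The (0, 0) combo retains the parent unchanged.
    """
    if not scaffolds:
        raise ValueError("scaffold list is empty")
    if max_glucose < 0 or max_methyl < 0:
        raise ValueError("building-block limits must be non-negative")
    names = [s.name for s in scaffolds]
    if len(set(names)) != len(names):
        raise ValueError("duplicate scaffold names")

    products: List[EnumeratedProduct] = []
    for scaffold in scaffolds:
        for g, m in iter_product(range(max_glucose + 1), range(max_methyl + 1)):
            combo = BuildingBlockCombo(g, m)
            formula = scaffold.formula + _GLUCOSE_UNIT.scaled(g) + _METHYLENE.scaled(m)
            products.append(
                EnumeratedProduct(
                    name=_product_name(scaffold.name, combo),
                    formula=formula,
                    parent=scaffold.name,
                    combo=combo,
                    smiles=scaffold.smiles,
                )
            )
    return products


def diagnostic_ions(
    product: EnumeratedProduct, polarity: str = "negative"
) -> List[Tuple[str, float]]:
    """Characteristic ions expected from the fragmentation of a virtual
    metabolite.

    For glycosides in negative mode: the deprotonated aglycone (parent plus
    any methyls, [M-H]-) and the neutral-loss series precursor − k×162.0528
    for k = 1..n_glucose (numerically identical to the aglycone ion for the
    final k, listed once each), plus a labeled sugar-moiety fragment.  For a
    parent-only product the supplement is empty — its fragmentation is not
    predicted here.
    """
    g = product.combo.n_glucose
    if g == 0:
        return []
    adduct = get_adduct("[M-H]-" if polarity == "negative" else "[M+H]+")
    aglycone_formula = product.formula - _GLUCOSE_UNIT.scaled(g)
    precursor = adduct_mz(product.formula, adduct)
    ions: List[Tuple[str, float]] = [
        ("aglycone", adduct_mz(aglycone_formula, adduct))
    ]
    for k in range(1, g + 1):
        ions.append((f"loss_{k}xGlc", precursor - k * GLUCOSE_CONDENSATION_MASS))
    # The dehydrated sugar oxocarbenium-style marker; optional corroborating ion.
    sugar = adduct_mz(_GLUCOSE_UNIT, adduct)
    ions.append(("sugar_moiety", sugar))
    return ions


def products_to_suspects(
    products: Sequence[EnumeratedProduct],
    adducts: Sequence[AdductSpec | str],
):
    """Formalize the hand-off to the suspect-list machinery: one SuspectEntry
    per product per compatible adduct, tagged VMSL."""
    from .suspects import SuspectEntry  # local import to avoid a cycle

    entries = []
    for product in products:
        for adduct in adducts:
            spec = get_adduct(adduct) if isinstance(adduct, str) else adduct
            ions = diagnostic_ions(product, spec.polarity)
            aglycone = tuple(mz for label, mz in ions if label == "aglycone")
            entries.append(
                SuspectEntry(
                    name=product.name,
                    formula=product.formula,
                    adduct=spec,
                    precursor_mz=adduct_mz(product.formula, spec),
                    sources=("VMSL",),
                    smiles=product.smiles,
                    diagnostic_ions=aglycone or None,
                )
            )
    return entries
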
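"""Suspect-list data model, CSV and MSP I/O, and list algebra.

A suspect list is a table of candidate compounds (name, formula, adduct,
precursor m/z, optional predicted retention time) tagged with its provenance:
BDSL (bioactivity-driven), LBL (literature-based) or VMSL (virtual
metabolites from combinatorial enumeration).  An MSP database is the same
idea with reference fragment spectra attached — "a database which is
essentially a suspect list" — and is what the fragmentation-driven workflow
matches against.

The MSP dialect here is the GNPS / MS-DIAL-compatible key set
(NAME/FORMULA/PRECURSORMZ/PRECURSORTYPE/IONMODE/RETENTIONTIME/Num Peaks,
case-insensitive) with peak lines "mz<whitespace>intensity".  Unknown keys
round-trip untouched as opaque metadata.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .chem import (
    AdductSpec,
    MolecularFormula,
    adduct_mz,
    get_adduct,
    parse_formula,
)

__all__ = [
    "SuspectEntry",
    "MspRecord",
    "MspFormatError",
    "read_suspect_csv",
    "write_suspect_csv",
    "read_msp",
    "write_msp",
    "merge_lists",
    "intersect_lists",
    "dedupe_key",
]

VALID_SOURCES = ("BDSL", "LBL", "VMSL")


@dataclass(frozen=True)
class SuspectEntry:
    """A candidate compound on a suspect list."""

    name: str
    formula: MolecularFormula
    adduct: AdductSpec
    precursor_mz: float
    sources: Tuple[str, ...]
    predicted_rt: Optional[float] = None  # minutes
    smiles: Optional[str] = None
    diagnostic_ions: Optional[Tuple[float, ...]] = None
    in_silico_fragments: Optional[Tuple[float, ...]] = None
    reference_standard_available: bool = False

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError(f"{self.name}: source tag set is empty")
        theo = adduct_mz(self.formula, self.adduct)
        if abs(self.precursor_mz - theo) > 0.002:
            raise ValueError(
                f"{self.name}: precursor m/z {self.precursor_mz:.4f} inconsistent "
                f"with {self.adduct.name} of {self.formula.hill()} ({theo:.4f})"
            )


@dataclass(frozen=True)
class MspRecord:
    """One MSP database entry: a compound with a reference fragment spectrum."""

    name: str
    formula: MolecularFormula
    precursor_mz: float
    precursor_type: str  # adduct label
    ion_mode: str  # "positive" | "negative"
    peaks: Tuple[Tuple[float, float], ...]
    retention_time: Optional[float] = None
    extra: Tuple[Tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        mzs = [p[0] for p in self.peaks]
        if mzs != sorted(mzs):
            raise ValueError(f"{self.name}: peaks not sorted by m/z")
        if any(i <= 0 for _, i in self.peaks):
            raise ValueError(f"{self.name}: non-positive peak intensity")


class MspFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# CSV I/O


def read_suspect_csv(path) -> List[SuspectEntry]:
    """Read a suspect list from CSV.

    Required columns: ``name``, ``formula``.  Optional: ``adduct``,
    ``exact_mass``/``precursor_mz``, ``smiles``, ``predicted_rt``,
    ``source`` (semicolon-separated multi-tag), ``diagnostic_ions`` and
    ``in_silico_fragments`` (semicolon-separated m/z), ``reference_standard``
    (0/1).  A missing precursor m/z is recomputed from the formula and
    adduct (default [M-H]-).
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, no header")
        fields = {f.strip().lower() for f in reader.fieldnames}
        for required in ("name", "formula"):
            if required not in fields:
                raise ValueError(f"{path}: missing required column {required!r}")
        entries: List[SuspectEntry] = []
        for idx, row in enumerate(reader, start=2):
            row = {(k or "").strip().lower(): (v or "").strip() for k, v in row.items()}
            try:
                formula = parse_formula(row["formula"])
            except ValueError as exc:
                raise ValueError(f"{path} row {idx}: {exc}") from exc
            adduct = get_adduct(row.get("adduct") or "[M-H]-")
            if row.get("precursor_mz"):
                precursor = float(row["precursor_mz"])
            elif row.get("exact_mass"):
                # neutral monoisotopic mass deposited in the CSV
                precursor = float(row["exact_mass"]) + adduct.mass_delta
            else:
                precursor = adduct_mz(formula, adduct)
            sources = tuple(
                s for s in (row.get("source") or "BDSL").split(";") if s
            )
            rt = row.get("predicted_rt") or ""

            def _mz_list(key: str) -> Optional[Tuple[float, ...]]:
                text = row.get(key) or ""
                values = tuple(float(v) for v in text.split(";") if v)
                return values or None

            entries.append(
                SuspectEntry(
                    name=row["name"],
                    formula=formula,
                    adduct=adduct,
                    precursor_mz=precursor,
                    sources=sources,
                    predicted_rt=float(rt) if rt else None,
                    smiles=row.get("smiles") or None,
                    diagnostic_ions=_mz_list("diagnostic_ions"),
                    in_silico_fragments=_mz_list("in_silico_fragments"),
                    reference_standard_available=row.get("reference_standard") in ("1", "true", "True"),
                )
            )
    return entries


def write_suspect_csv(entries: Sequence[SuspectEntry], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "name", "formula", "adduct", "precursor_mz", "predicted_rt",
                "source", "smiles", "diagnostic_ions", "in_silico_fragments",
                "reference_standard",
            ]
        )
        for e in entries:
            writer.writerow(
                [
                    e.name,
                    e.formula.hill(),
                    e.adduct.name,
                    f"{e.precursor_mz:.4f}",
                    "" if e.predicted_rt is None else f"{e.predicted_rt:g}",
                    ";".join(e.sources),
                    e.smiles or "",
                    ";".join(f"{mz:.4f}" for mz in e.diagnostic_ions or ()),
                    ";".join(f"{mz:.4f}" for mz in e.in_silico_fragments or ()),
                    "1" if e.reference_standard_available else "0",
                ]
            )


# ---------------------------------------------------------------------------
# MSP I/O

_KNOWN_KEYS = {
    "name": "NAME",
    "formula": "FORMULA",
    "precursormz": "PRECURSORMZ",
    "precursortype": "PRECURSORTYPE",
    "ionmode": "IONMODE",
    "retentiontime": "RETENTIONTIME",
}


def read_msp(path) -> List[MspRecord]:
    """Parse an MSP spectral database.

    Records are blocks of ``KEY: value`` lines terminated by a ``Num Peaks``
    line followed by exactly that many ``mz intensity`` peak lines.  Keys are
    case-insensitive; unknown keys are preserved verbatim.
    """
    records: List[MspRecord] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    i, n = 0, len(lines)
    while i < n:
        if not lines[i].strip():
            i += 1
            continue
        fields: Dict[str, str] = {}
        extra: List[Tuple[str, str]] = []
        num_peaks = None
        while i < n and lines[i].strip():
            line = lines[i]
            if ":" not in line:
                raise MspFormatError(f"{path}: expected 'key: value', got {line!r}")
            key, _, value = line.partition(":")
            key_norm = key.strip().lower().replace(" ", "")
            value = value.strip()
            i += 1
            if key_norm == "numpeaks":
                num_peaks = int(value)
                break
            if key_norm in _KNOWN_KEYS:
                fields[key_norm] = value
            else:
                extra.append((key.strip(), value))
        if num_peaks is None:
            raise MspFormatError(f"{path}: record without 'Num Peaks' line")
        peaks: List[Tuple[float, float]] = []
        for _ in range(num_peaks):
            if i >= n or not lines[i].strip():
                raise MspFormatError(
                    f"{path}: peak count mismatch, expected {num_peaks} got {len(peaks)}"
                )
            parts = lines[i].split()
            if len(parts) < 2:
                raise MspFormatError(f"{path}: unparseable peak line {lines[i]!r}")
            try:
                peaks.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise MspFormatError(f"{path}: unparseable peak line {lines[i]!r}") from exc
            i += 1
        if i < n and lines[i].strip():
            raise MspFormatError(
                f"{path}: peak count mismatch, more peaks than 'Num Peaks: {num_peaks}'"
            )
        rt = fields.get("retentiontime")
        records.append(
            MspRecord(
                name=fields.get("name", ""),
                formula=parse_formula(fields["formula"]),
                precursor_mz=float(fields["precursormz"]),
                precursor_type=fields.get("precursortype", ""),
                ion_mode=fields.get("ionmode", ""),
                retention_time=float(rt) if rt else None,
                peaks=tuple(peaks),
                extra=tuple(extra),
            )
        )
    return records


def write_msp(records: Sequence[MspRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f"NAME: {rec.name}\n")
            fh.write(f"FORMULA: {rec.formula.hill()}\n")
            fh.write(f"PRECURSORMZ: {rec.precursor_mz:.4f}\n")
            fh.write(f"PRECURSORTYPE: {rec.precursor_type}\n")
            fh.write(f"IONMODE: {rec.ion_mode}\n")
            if rec.retention_time is not None:
                fh.write(f"RETENTIONTIME: {rec.retention_time:g}\n")
            for key, value in rec.extra:
                fh.write(f"{key}: {value}\n")
            fh.write(f"Num Peaks: {len(rec.peaks)}\n")
            for mz, intensity in rec.peaks:
                fh.write(f"{mz:.4f}\t{intensity:g}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# List algebra


def dedupe_key(entry: SuspectEntry) -> Tuple[str, str]:
    """Compound identity for merge/intersect: canonical Hill formula plus
    case-folded name.  Exact mass is deliberately excluded (floating)."""
    return (entry.formula.hill(), entry.name.casefold())


def merge_lists(lists: Sequence[Sequence[SuspectEntry]]) -> List[SuspectEntry]:
    """Union of suspect lists with source tags unioned on the dedupe key.

    First occurrence wins for all other fields; order is deterministic
    (first-seen order).  Entries sharing a name but not a formula remain
    distinct.
    """
    merged: Dict[Tuple[str, str], SuspectEntry] = {}
    for lst in lists:
        for entry in lst:
            key = dedupe_key(entry)
            if key in merged:
                kept = merged[key]
                sources = kept.sources + tuple(
                    s for s in entry.sources if s not in kept.sources
                )
                updates = {"sources": sources}
                if kept.diagnostic_ions is None and entry.diagnostic_ions:
                    updates["diagnostic_ions"] = entry.diagnostic_ions
                if kept.in_silico_fragments is None and entry.in_silico_fragments:
                    updates["in_silico_fragments"] = entry.in_silico_fragments
                if entry.reference_standard_available:
                    updates["reference_standard_available"] = True
                merged[key] = replace(kept, **updates)
            else:
                merged[key] = entry
    return list(merged.values())


def intersect_lists(
    a: Sequence[SuspectEntry], b: Sequence[SuspectEntry]
) -> List[SuspectEntry]:
    """Entries of ``a`` whose compound identity also appears in ``b``."""
    keys_b = {dedupe_key(e) for e in b}
    return [e for e in a if dedupe_key(e) in keys_b]
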
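"""In-memory model of centroided LC-MS runs, with mzML and JSON I/O.

A Run is a time-ordered list of centroided spectra from one sample in one
polarity.  Acquisition labels distinguish survey scans (MS1), data-dependent
MS2 scans (DDA_MS2, with an isolated precursor), and the alternating
low/high collision-energy scans of broadband DIA (DIA_LOW / DIA_HIGH, no
precursor isolation — all ions are fragmented in the high-energy scans).

Interchange formats: mzML (read via pyteomics; written minimally by the
synthetic-data module) and a compact versioned JSON schema used for
dependency-free fixtures.
"""

from __future__ import annotations

import base64
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

__all__ = [
    "MS1",
    "DDA_MS2",
    "DIA_LOW",
    "DIA_HIGH",
    "SpectrumRecord",
    "Run",
    "read_run_json",
    "write_run_json",
    "read_mzml",
    "write_mzml",
]

MS1 = "MS1"
DDA_MS2 = "DDA_MS2"
DIA_LOW = "DIA_LOW"
DIA_HIGH = "DIA_HIGH"
_ACQUISITIONS = (MS1, DDA_MS2, DIA_LOW, DIA_HIGH)

JSON_SCHEMA = "pomscreen-run:1"


@dataclass
class SpectrumRecord:
    """One centroided scan."""

    scan_id: str
    ms_level: int
    acquisition: str
    rt: float  # minutes
    polarity: str  # "positive" | "negative"
    peaks: np.ndarray  # shape (n, 2): m/z, intensity; sorted by m/z
    precursor_mz: Optional[float] = None  # DDA_MS2 only
    isolation_width: Optional[float] = None  # DDA_MS2 only

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if self.acquisition not in _ACQUISITIONS:
            raise ValueError(f"unknown acquisition label {self.acquisition!r}")
        if self.rt < 0:
            raise ValueError("negative retention time")
        if self.peaks.size and np.any(np.diff(self.peaks[:, 0]) < 0):
            raise ValueError(f"scan {self.scan_id}: peaks not sorted by m/z")
        if self.acquisition == DDA_MS2 and self.precursor_mz is None:
            raise ValueError(f"scan {self.scan_id}: DDA_MS2 requires precursor_mz")
        if self.acquisition == DIA_HIGH and self.precursor_mz is not None:
            raise ValueError(f"scan {self.scan_id}: DIA_HIGH has no precursor")

    @property
    def tic(self) -> float:
        return float(self.peaks[:, 1].sum()) if self.peaks.size else 0.0


@dataclass
class Run:
    """A single-polarity LC-MS acquisition of one sample."""

    sample_id: str
    spectra: List[SpectrumRecord]
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError(f"run {self.sample_id}: retention times not ordered")
        pols = {s.polarity for s in self.spectra}
        if len(pols) > 1:
            raise ValueError(f"run {self.sample_id}: mixed polarity {pols}")

    @property
    def polarity(self) -> Optional[str]:
        return self.spectra[0].polarity if self.spectra else None

    def scans(self, *acquisitions: str) -> List[SpectrumRecord]:
        return [s for s in self.spectra if s.acquisition in acquisitions]

    @property
    def tic(self) -> float:
        return float(sum(s.tic for s in self.spectra))


# ---------------------------------------------------------------------------
# JSON run format


def write_run_json(run: Run, path) -> None:
    payload = {
        "schema": JSON_SCHEMA,
        "sample_id": run.sample_id,
        "metadata": run.metadata,
        "spectra": [
            {
                "scan_id": s.scan_id,
                "ms_level": s.ms_level,
                "acquisition": s.acquisition,
                "rt": s.rt,
                "polarity": s.polarity,
                "precursor_mz": s.precursor_mz,
                "isolation_width": s.isolation_width,
                "peaks": [[float(mz), float(i)] for mz, i in s.peaks],
            }
            for s in run.spectra
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def read_run_json(path) -> Run:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("schema") != JSON_SCHEMA:
        raise ValueError(
            f"{path}: schema mismatch, expected {JSON_SCHEMA!r} got {payload.get('schema')!r}"
        )
    spectra = [
        SpectrumRecord(
            scan_id=s["scan_id"],
            ms_level=s["ms_level"],
            acquisition=s["acquisition"],
            rt=s["rt"],
            polarity=s["polarity"],
            peaks=np.array(s["peaks"], dtype=float).reshape(-1, 2),
            precursor_mz=s.get("precursor_mz"),
            isolation_width=s.get("isolation_width"),
        )
        for s in payload["spectra"]
    ]
    return Run(payload["sample_id"], spectra, dict(payload.get("metadata", {})))


# ---------------------------------------------------------------------------
# mzML


def _decode_binary(array_el, ns: str) -> np.ndarray:
    accs = {
        cv.get("accession") for cv in array_el.findall(f"{ns}cvParam")
    }
    binary = array_el.find(f"{ns}binary")
    raw = base64.b64decode(binary.text or "")
    if "MS:1000574" in accs:  # zlib compression
        import zlib

        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path, dia_high_energy_min: float = 15.0) -> Run:
    """Read a centroided mzML file into a Run.

    A compact reader for the subset of mzML that centroided small-molecule
    screening needs: spectrum cvParams (ms level, centroid/profile flag,
    polarity, scan start time), DDA precursor isolation, collision energy
    (cvParam or userParam), and 32/64-bit float binary arrays with optional
    zlib compression.

    Acquisition labels are inferred: ms level 2 with a selected precursor →
    DDA_MS2; ms level 1 carrying a collision energy ≥ ``dia_high_energy_min``
    (eV) → DIA_HIGH, with the interleaved low-energy survey scans labelled
    DIA_LOW when any high-energy scan is present, MS1 otherwise.  Vendors
    annotate bbCID energies differently, hence the configurable threshold.
    Profile-mode spectra are rejected: screening assumes centroided peaks.
    """
    from lxml import etree

    tree = etree.parse(str(path))
    root = tree.getroot()
    ns = root.tag.split("}")[0] + "}" if root.tag.startswith("{") else ""

    def cvmap(el):
        return {
            cv.get("accession"): cv.get("value", "")
            for cv in el.findall(f"{ns}cvParam")
        }

    spectra: List[SpectrumRecord] = []
    has_high = False
    for spec_el in root.iter(f"{ns}spectrum"):
        params = cvmap(spec_el)
        if "MS:1000128" in params:
            raise ValueError(f"{path}: profile-mode data; centroided spectra required")
        ms_level = int(params.get("MS:1000511", 1))
        polarity = "negative" if "MS:1000129" in params else "positive"
        rt = 0.0
        for scan_el in spec_el.iter(f"{ns}scan"):
            for cv in scan_el.findall(f"{ns}cvParam"):
                if cv.get("accession") == "MS:1000016":
                    rt = float(cv.get("value"))
                    if cv.get("unitName") == "second":
                        rt /= 60.0
            break
        ce = None
        precursor_mz = None
        isolation = None
        for prec_el in spec_el.iter(f"{ns}precursor"):
            for ion_el in prec_el.iter(f"{ns}selectedIon"):
                ion_params = cvmap(ion_el)
                if "MS:1000744" in ion_params:
                    precursor_mz = float(ion_params["MS:1000744"])
            for act_el in prec_el.iter(f"{ns}activation"):
                act_params = cvmap(act_el)
                if "MS:1000045" in act_params:
                    ce = float(act_params["MS:1000045"])
            for iso_el in prec_el.iter(f"{ns}isolationWindow"):
                iso_params = cvmap(iso_el)
                lo = iso_params.get("MS:1000828")
                hi = iso_params.get("MS:1000829")
                if lo is not None and hi is not None:
                    isolation = float(lo) + float(hi)
                if precursor_mz is None and "MS:1000827" in iso_params:
                    precursor_mz = float(iso_params["MS:1000827"])
            break
        for user_el in spec_el.findall(f"{ns}userParam"):
            if ce is None and user_el.get("name") == "collision_energy":
                ce = float(user_el.get("value"))
        mzs = np.empty(0)
        ints = np.empty(0)
        for arr_el in spec_el.iter(f"{ns}binaryDataArray"):
            arr_params = cvmap(arr_el)
            if "MS:1000514" in arr_params:
                mzs = _decode_binary(arr_el, ns)
            elif "MS:1000515" in arr_params:
                ints = _decode_binary(arr_el, ns)
        if ms_level == 2 and precursor_mz is not None:
            acquisition = DDA_MS2
        elif ce is not None and ce >= dia_high_energy_min:
            acquisition = DIA_HIGH
            precursor_mz = None
        else:
            acquisition = MS1
        spectra.append(
            SpectrumRecord(
                scan_id=str(spec_el.get("id", len(spectra))),
                ms_level=ms_level,
                acquisition=acquisition,
                rt=rt,
                polarity=polarity,
                peaks=np.column_stack([mzs, ints]) if mzs.size else np.empty((0, 2)),
                precursor_mz=precursor_mz,
                isolation_width=isolation,
            )
        )
        if acquisition == DIA_HIGH:
            has_high = True
    if has_high:
        for s in spectra:
            if s.acquisition == MS1:
                s.acquisition = DIA_LOW
    return Run(Path(path).stem, spectra, {})


def _encode_floats(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *map(float, values))
    return base64.b64encode(raw).decode("ascii")


def write_mzml(run: Run, path) -> None:
    """Write a minimal centroided mzML file.

    Covers exactly what :func:`read_mzml` (and pyteomics) needs: spectrum
    cvParams for ms level, centroiding and polarity, scan start time in
    minutes, DDA precursor isolation, a collision-energy userParam for
    bbCID high-energy scans, and uncompressed 64-bit binary arrays.
    """
    from lxml import etree

    NS = "http://psi.hupo.org/ms/mzml"
    root = etree.Element(f"{{{NS}}}mzML", version="1.1.0")
    etree.SubElement(root, f"{{{NS}}}cvList", count="1")
    run_el = etree.SubElement(root, f"{{{NS}}}run", id=run.sample_id)
    speclist = etree.SubElement(
        run_el, f"{{{NS}}}spectrumList", count=str(len(run.spectra))
    )

    def cv(parent, accession, name, value=None, unit=None):
        attrs = {"cvRef": "MS", "accession": accession, "name": name}
        attrs["value"] = "" if value is None else str(value)
        if unit:
            attrs.update(
                unitCvRef="UO", unitAccession=unit[0], unitName=unit[1]
            )
        etree.SubElement(parent, f"{{{NS}}}cvParam", **attrs)

    for index, s in enumerate(run.spectra):
        spec = etree.SubElement(
            speclist,
            f"{{{NS}}}spectrum",
            index=str(index),
            id=s.scan_id,
            defaultArrayLength=str(len(s.peaks)),
        )
        cv(spec, "MS:1000511", "ms level", s.ms_level)
        cv(spec, "MS:1000127", "centroid spectrum")
        if s.polarity == "negative":
            cv(spec, "MS:1000129", "negative scan")
        else:
            cv(spec, "MS:1000130", "positive scan")
        if s.acquisition == DIA_HIGH:
            etree.SubElement(
                spec,
                f"{{{NS}}}userParam",
                name="collision_energy",
                value="30.0",
                type="xsd:float",
            )
        scanlist = etree.SubElement(spec, f"{{{NS}}}scanList", count="1")
        scan = etree.SubElement(scanlist, f"{{{NS}}}scan")
        cv(
            scan,
            "MS:1000016",
            "scan start time",
            f"{s.rt:.6f}",
            unit=("UO:0000031", "minute"),
        )
        if s.acquisition == DDA_MS2:
            plist = etree.SubElement(spec, f"{{{NS}}}precursorList", count="1")
            prec = etree.SubElement(plist, f"{{{NS}}}precursor")
            ilist = etree.SubElement(prec, f"{{{NS}}}selectedIonList", count="1")
            ion = etree.SubElement(ilist, f"{{{NS}}}selectedIon")
            cv(ion, "MS:1000744", "selected ion m/z", f"{s.precursor_mz:.4f}")
            act = etree.SubElement(prec, f"{{{NS}}}activation")
            cv(act, "MS:1000045", "collision energy", "30.0")
        blist = etree.SubElement(spec, f"{{{NS}}}binaryDataArrayList", count="2")
        for col, (acc, name) in enumerate(
            [("MS:1000514", "m/z array"), ("MS:1000515", "intensity array")]
        ):
            values = s.peaks[:, col] if s.peaks.size else np.empty(0)
            encoded = _encode_floats(values)
            arr = etree.SubElement(
                blist, f"{{{NS}}}binaryDataArray", encodedLength=str(len(encoded))
            )
            cv(arr, "MS:1000523", "64-bit float")
            cv(arr, "MS:1000576", "no compression")
            cv(arr, acc, name)
            binary = etree.SubElement(arr, f"{{{NS}}}binary")
            binary.text = encoded
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)
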
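"""MS1-driven targeted screening: EICs, peak detection, prioritization,
procedure-blank filtering.

For each suspect, an extracted ion chromatogram (EIC) is built by summing
MS1 (or DIA low-energy) intensity inside an absolute ±0.005 Da window around
the suspect's precursor m/z.  Chromatographic peaks are detected on the EIC
and prioritized by area under the curve — antioxidants must be present in
quantity to act, so the most abundant candidates (MAA) are what feed the
fragmentation-driven stage.  Features whose procedure-blank area is not at
least five-fold below the sample area are excluded as false positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .model import DIA_LOW, MS1, Run
from .suspects import SuspectEntry

__all__ = [
    "EIC",
    "Feature",
    "extract_eic",
    "detect_peaks",
    "select_most_abundant",
    "blank_filter",
    "BlankExclusion",
]

DEFAULT_MZ_TOL_DA = 0.005


@dataclass(frozen=True)
class EIC:
    """Intensity-vs-time trace of a narrow m/z window."""

    target_mz: float
    tol_da: float
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rt", np.asarray(self.rt, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity length mismatch")
        if self.rt.size > 1 and np.any(np.diff(self.rt) <= 0):
            raise ValueError("rt not strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")


@dataclass(frozen=True)
class Feature:
    """A detected chromatographic peak tied to a suspect and a sample."""

    suspect: Optional[SuspectEntry]
    sample_id: str
    rt_apex: float
    height: float
    area: float
    rt_bounds: Tuple[float, float]
    measured_mz: Optional[float] = None

    def __post_init__(self) -> None:
        lo, hi = self.rt_bounds
        if not (lo <= self.rt_apex <= hi):
            raise ValueError("rt bounds do not contain the apex")
        if self.area <= 0 or self.height <= 0:
            raise ValueError("non-positive feature height/area")


def extract_eic(run: Run, target_mz: float, tol_da: float = DEFAULT_MZ_TOL_DA) -> EIC:
    """Per-scan summed intensity within ``target_mz ± tol_da`` over the MS1
    level of the run (survey MS1 scans, or DIA low-energy scans)."""
    scans = run.scans(MS1, DIA_LOW)
    if not scans:
        raise ValueError(f"run {run.sample_id}: no MS1-level scans")
    rts = np.array([s.rt for s in scans])
    intensities = np.zeros(len(scans))
    lo, hi = target_mz - tol_da, target_mz + tol_da
    for i, scan in enumerate(scans):
        if not scan.peaks.size:
            continue
        mz = scan.peaks[:, 0]
        a, b = np.searchsorted(mz, (lo, hi))
        if b > a:
            intensities[i] = scan.peaks[a:b, 1].sum()
    return EIC(target_mz=target_mz, tol_da=tol_da, rt=rts, intensity=intensities)


def _noise_sigma(y: np.ndarray) -> float:
    """Robust noise scale: 1.4826 × MAD of the trace."""
    med = np.median(y)
    return 1.4826 * float(np.median(np.abs(y - med)))


def detect_peaks(
    eic: EIC,
    sample_id: str = "",
    suspect: Optional[SuspectEntry] = None,
    min_height_snr: float = 3.0,
    min_points: int = 3,
    bound_fraction: float = 0.05,
) -> List[Feature]:
    """Detect chromatographic peaks on an EIC.

    Local maxima above ``min_height_snr`` times the robust noise level are
    kept if at least ``min_points`` consecutive points exceed the threshold
    (single-scan spikes are not peaks).  Peak bounds extend from the apex to
    the first descent below ``bound_fraction`` of the apex height or to a
    local minimum; the area is the trapezoid integral over the bounds.
    """
    y, rt = eic.intensity, eic.rt
    if y.size < 5:
        return []
    threshold = min_height_snr * _noise_sigma(y)
    apex_idx = [
        i
        for i in range(1, y.size - 1)
        if y[i] > threshold and y[i] >= y[i - 1] and y[i] > y[i + 1]
    ]
    features: List[Feature] = []
    for i in apex_idx:
        floor = max(threshold, bound_fraction * y[i])
        lo = i
        while lo > 0 and y[lo - 1] > floor and y[lo - 1] <= y[lo]:
            lo -= 1
        hi = i
        while hi < y.size - 1 and y[hi + 1] > floor and y[hi + 1] <= y[hi]:
            hi += 1
        if hi - lo + 1 < min_points:
            continue
        area = float(np.trapezoid(y[lo : hi + 1], rt[lo : hi + 1]))
        if area <= 0:
            continue
        features.append(
            Feature(
                suspect=suspect,
                sample_id=sample_id,
                rt_apex=float(rt[i]),
                height=float(y[i]),
                area=area,
                rt_bounds=(float(rt[lo]), float(rt[hi])),
            )
        )
    return features


def select_most_abundant(features: Sequence[Feature], k: int) -> List[Feature]:
    """Top-k features by area; ties broken by earlier apex RT, then name."""
    if k < 0:
        raise ValueError("k must be non-negative")
    ordered = sorted(
        features,
        key=lambda f: (-f.area, f.rt_apex, f.suspect.name if f.suspect else ""),
    )
    return ordered[:k]


@dataclass(frozen=True)
class BlankExclusion:
    """Record of a feature removed by the procedure-blank rule."""

    feature: Feature
    sample_area: float
    blank_area: float
    ratio: float


def blank_filter(
    sample_features: Sequence[Feature],
    blank_features: Sequence[Feature],
    min_ratio: float = 5.0,
    rt_tol: float = 0.2,
) -> Tuple[List[Feature], List[BlankExclusion]]:
    """Drop features whose sample area is not ``min_ratio``-fold above the
    matching procedure-blank feature.

    Matching is by suspect identity and apex RT within ``rt_tol`` minutes.
    Features with no blank counterpart are kept.  Returns (kept, exclusions).
    """
    kept: List[Feature] = []
    excluded: List[BlankExclusion] = []
    for feat in sample_features:
        blank_area = 0.0
        for bf in blank_features:
            same_suspect = (
                feat.suspect is not None
                and bf.suspect is not None
                and feat.suspect.name == bf.suspect.name
            )
            if same_suspect and abs(bf.rt_apex - feat.rt_apex) <= rt_tol:
                blank_area = max(blank_area, bf.area)
        if blank_area == 0.0 or feat.area >= min_ratio * blank_area:
            kept.append(feat)
        else:
            excluded.append(
                BlankExclusion(
                    feature=feat,
                    sample_area=feat.area,
                    blank_area=blank_area,
                    ratio=feat.area / blank_area,
                )
            )
    return kept, excluded
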
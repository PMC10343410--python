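"""Fragmentation-driven matching: DDA/DIA spectrum acquisition, cosine
similarity against MSP library spectra, and diagnostic-ion checks.

DDA yields clean per-precursor MS/MS spectra; a suspect's spectrum is the
DDA scan whose isolated precursor matches its m/z nearest the feature apex.
DIA fragments everything at once, so a pseudo-spectrum is assembled by
correlation: a fragment trace in the high-energy scans is attributed to the
precursor when it co-elutes (Pearson correlation of the traces above a gate,
apex within 0.1 min).  This correlation gating is a simple, testable
pseudo-spectrum construction in the spirit of DIA deconvolution tools, not a
full deconvolution.

Similarity is the plain intensity cosine over greedily matched peak pairs:
unmatched peaks contribute to the norms only, so extraneous fragments lower
the score symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .model import DDA_MS2, DIA_HIGH, Run, SpectrumRecord
from .screening import EIC, Feature

__all__ = [
    "PeakMatchSet",
    "SimilarityResult",
    "match_peaks",
    "cosine_score",
    "select_dda_spectrum",
    "dia_pseudo_spectrum",
    "diagnostic_ion_check",
]

DEFAULT_FRAG_TOL_DA = 0.01

Peaks = Sequence[Tuple[float, float]]


@dataclass(frozen=True)
class PeakMatchSet:
    """Greedy one-to-one pairing of query and library peaks within tolerance."""

    pairs: Tuple[Tuple[Tuple[float, float], Tuple[float, float], float], ...]
    unmatched_query: Tuple[Tuple[float, float], ...]
    unmatched_library: Tuple[Tuple[float, float], ...]


@dataclass(frozen=True)
class SimilarityResult:
    score: float
    n_matched: int
    matched_mzs: Tuple[float, ...]


def match_peaks(
    query: Peaks, library: Peaks, tol_da: float = DEFAULT_FRAG_TOL_DA
) -> PeakMatchSet:
    """Pair peaks across two centroided spectra.

    Candidate pairs within ``tol_da`` are accepted greedily by smallest
    |Δm/z| (ties: lower query m/z first); each peak joins at most one pair.
    On well-separated spectra this equals the optimal assignment.
    """
    candidates = []
    for qi, (qmz, _) in enumerate(query):
        for li, (lmz, _) in enumerate(library):
            d = qmz - lmz
            if abs(d) <= tol_da:
                candidates.append((abs(d), qi, li, d))
    candidates.sort()
    used_q: set = set()
    used_l: set = set()
    pairs = []
    for _, qi, li, d in candidates:
        if qi in used_q or li in used_l:
            continue
        used_q.add(qi)
        used_l.add(li)
        pairs.append((tuple(query[qi]), tuple(library[li]), d))
    pairs.sort(key=lambda p: p[0][0])
    return PeakMatchSet(
        pairs=tuple(pairs),
        unmatched_query=tuple(
            tuple(p) for i, p in enumerate(query) if i not in used_q
        ),
        unmatched_library=tuple(
            tuple(p) for i, p in enumerate(library) if i not in used_l
        ),
    )


def cosine_score(
    query: Peaks, library: Peaks, tol_da: float = DEFAULT_FRAG_TOL_DA
) -> SimilarityResult:
    """Normalized dot product of intensity vectors over matched peak pairs.

    Scale-invariant in each argument and symmetric under swap.  An empty
    spectrum scores 0.
    """
    if not len(query) or not len(library):
        return SimilarityResult(score=0.0, n_matched=0, matched_mzs=())
    matches = match_peaks(query, library, tol_da)
    if not matches.pairs:
        return SimilarityResult(score=0.0, n_matched=0, matched_mzs=())
    dot = sum(q[1] * l[1] for q, l, _ in matches.pairs)
    norm_q = np.sqrt(sum(i * i for _, i in query))
    norm_l = np.sqrt(sum(i * i for _, i in library))
    score = float(dot / (norm_q * norm_l)) if norm_q and norm_l else 0.0
    return SimilarityResult(
        score=min(score, 1.0),
        n_matched=len(matches.pairs),
        matched_mzs=tuple(q[0] for q, _, _ in matches.pairs),
    )


def select_dda_spectrum(
    run: Run,
    precursor_mz: float,
    rt_window: Tuple[float, float],
    tol_da: float = 0.005,
) -> Optional[SpectrumRecord]:
    """The DDA MS2 scan isolated on ``precursor_mz`` nearest the center of
    ``rt_window``; None when no matching scan exists."""
    center = 0.5 * (rt_window[0] + rt_window[1])
    best = None
    best_dist = None
    for scan in run.scans(DDA_MS2):
        if scan.precursor_mz is None:
            continue
        if abs(scan.precursor_mz - precursor_mz) > tol_da:
            continue
        if not (rt_window[0] <= scan.rt <= rt_window[1]):
            continue
        dist = abs(scan.rt - center)
        if best_dist is None or dist < best_dist:
            best, best_dist = scan, dist
    return best


def dia_pseudo_spectrum(
    run: Run,
    precursor_eic: EIC,
    feature: Feature,
    frag_tol_da: float = DEFAULT_FRAG_TOL_DA,
    min_corr: float = 0.8,
    apex_tol: float = 0.1,
) -> List[Tuple[float, float]]:
    """Assemble a fragment spectrum for a precursor from DIA high-energy scans.

    Every distinct fragment m/z observed in high-energy scans inside the
    feature's RT bounds is traced; it enters the pseudo-spectrum iff its
    trace correlates with the precursor trace (Pearson r ≥ ``min_corr``) and
    its apex lies within ``apex_tol`` minutes of the feature apex.  The
    reported intensity is the fragment trace apex.
    """
    high = run.scans(DIA_HIGH)
    if not high:
        raise ValueError(f"run {run.sample_id}: no DIA high-energy scans")
    lo_rt, hi_rt = feature.rt_bounds
    window = [s for s in high if lo_rt <= s.rt <= hi_rt]
    if not window:
        return []
    # Cluster the m/z values present in the window into fragment channels.
    window_mzs = [s.peaks[:, 0] for s in window if s.peaks.size]
    if not window_mzs:
        return []
    all_mz = np.sort(np.concatenate(window_mzs))
    channels: List[float] = []
    for mz in all_mz:
        if not channels or mz - channels[-1] > frag_tol_da:
            channels.append(float(mz))
    rts = np.array([s.rt for s in window])
    # Precursor trace restricted to the same window.
    mask = (precursor_eic.rt >= lo_rt) & (precursor_eic.rt <= hi_rt)
    prec_rt = precursor_eic.rt[mask]
    prec_y = precursor_eic.intensity[mask]
    if prec_rt.size < 3:
        return []
    spectrum: List[Tuple[float, float]] = []
    for channel in channels:
        trace = np.zeros(len(window))
        for i, scan in enumerate(window):
            if not scan.peaks.size:
                continue
            mzs = scan.peaks[:, 0]
            a, b = np.searchsorted(mzs, (channel - frag_tol_da, channel + frag_tol_da))
            if b > a:
                trace[i] = scan.peaks[a:b, 1].sum()
        if np.count_nonzero(trace) < 3:
            continue
        apex_rt = float(rts[int(np.argmax(trace))])
        if abs(apex_rt - feature.rt_apex) > apex_tol:
            continue
        # Align the fragment trace onto the precursor RT grid.
        aligned = np.interp(prec_rt, rts, trace)
        if np.std(aligned) == 0 or np.std(prec_y) == 0:
            continue
        corr = float(np.corrcoef(aligned, prec_y)[0, 1])
        if corr >= min_corr:
            spectrum.append((channel, float(trace.max())))
    spectrum.sort()
    return spectrum


def diagnostic_ion_check(
    spectrum: Peaks, ions: Sequence[float], tol_da: float = DEFAULT_FRAG_TOL_DA
) -> Tuple[bool, List[float]]:
    """True iff every required diagnostic ion has a peak within ``tol_da``.

    Returns (all_present, matched ion list).  An empty ion list is an error:
    a diagnostic check needs something to check.
    """
    if not ions:
        raise ValueError("empty diagnostic ion list")
    matched = []
    for ion in ions:
        if any(abs(mz - ion) <= tol_da for mz, _ in spectrum):
            matched.append(ion)
    return len(matched) == len(ions), matched
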
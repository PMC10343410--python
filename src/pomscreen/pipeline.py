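"""End-to-end orchestration of the dual suspect/target screening workflow.

Stages, each independently runnable and serializable:

1. :func:`screen_stage` — MS1-driven targeted screening: EIC per suspect,
   peak detection, procedure-blank filtering.
2. :func:`match_stage` — fragmentation-driven matching: the most abundant
   candidates (top ``maa_k`` by area) take the DDA route, the rest the DIA
   pseudo-spectrum route; spectra are scored against the MSP library and
   reference-standard spectra, and diagnostic / in-silico ions are checked.
3. :func:`annotate_stage` — evidence assembly and Schymanski-level
   assignment, with formula-isomer collapse.

:func:`run_screening` composes the three.  Everything is deterministic
under a fixed seed and config.

Suspects that are formula isomers hitting the same chromatographic feature
(same formula, polarity and retention time) cannot be distinguished by
exact mass; they are collapsed into one reported compound — the candidate
with the strongest evidence — with the rest carried as co-candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .annotation import (
    Annotation,
    Evidence,
    LevelThresholds,
    annotate_dataset,
    best_level,
)
from .matching import (
    cosine_score,
    dia_pseudo_spectrum,
    diagnostic_ion_check,
    match_peaks,
    select_dda_spectrum,
)
from .model import DIA_HIGH, Run
from .screening import BlankExclusion, Feature, blank_filter, detect_peaks, extract_eic
from .suspects import SuspectEntry

__all__ = [
    "PipelineParams",
    "MatchReport",
    "ScreeningResult",
    "screen_stage",
    "match_stage",
    "annotate_stage",
    "run_screening",
    "index_runs",
]

BLANK_ID = "blank"


@dataclass(frozen=True)
class PipelineParams:
    """Every tolerance and gate of the workflow in one place."""

    mz_tol_da: float = 0.005
    frag_tol_da: float = 0.01
    rt_tol_min: float = 0.5
    dia_min_corr: float = 0.8
    score_2a: float = 0.7
    score_level1: float = 0.6
    blank_ratio: float = 5.0
    blank_rt_tol: float = 0.2
    loq_mg_kg: float = 0.5
    maa_k: int = 10
    in_silico_min_fraction: float = 0.5
    seed: int = 0

    def thresholds(self) -> LevelThresholds:
        return LevelThresholds(
            rt_tol_min=self.rt_tol_min,
            level1_score_min=self.score_level1,
            library_score_min=self.score_2a,
            mass_tol_da=self.mz_tol_da,
        )


@dataclass
class MatchReport:
    """Per-compound, per-sample fragmentation-matching outcome."""

    suspect_name: str
    sample_id: str
    route: Optional[str]  # "DDA" | "DIA" | None
    spectrum: Tuple[Tuple[float, float], ...]
    library_score: Optional[float]
    standard_score: Optional[float]
    n_matched: int
    diagnostic_ok: Optional[bool]
    in_silico_ok: Optional[bool]


@dataclass
class ScreeningResult:
    features: Dict[Tuple[str, str], Feature]  # (suspect name, sample) -> feature
    exclusions: List[BlankExclusion]
    match_reports: Dict[Tuple[str, str], MatchReport]
    annotations: List[Annotation]
    compound_levels: Dict[str, str]  # primary compounds only
    co_candidates: Dict[str, List[str]]  # primary -> isomeric co-candidates
    histogram: Dict[str, int]

    @property
    def n_compounds(self) -> int:
        return len(self.compound_levels)


def index_runs(runs: Sequence[Run]) -> Dict[Tuple[str, str, str], Run]:
    """Key runs by (sample id, polarity, acquisition kind)."""
    by_key: Dict[Tuple[str, str, str], Run] = {}
    for run in runs:
        acq = "DIA" if run.scans(DIA_HIGH) else "DDA"
        by_key[(run.sample_id, run.polarity or "negative", acq)] = run
    return by_key


def _is_blank(run: Run) -> bool:
    return bool(run.metadata.get("blank")) or run.sample_id == BLANK_ID


def _measure_mz(run: Run, feature: Feature, target_mz: float, tol: float) -> Optional[float]:
    """Intensity-weighted m/z of the peaks inside the window at the apex scan."""
    best_scan = None
    best_dt = None
    for scan in run.scans("MS1", "DIA_LOW"):
        dt = abs(scan.rt - feature.rt_apex)
        if best_dt is None or dt < best_dt:
            best_scan, best_dt = scan, dt
    if best_scan is None or not best_scan.peaks.size:
        return None
    mzs = best_scan.peaks[:, 0]
    ints = best_scan.peaks[:, 1]
    mask = (mzs >= target_mz - tol) & (mzs <= target_mz + tol)
    if not mask.any():
        return None
    return float((mzs[mask] * ints[mask]).sum() / ints[mask].sum())


def _best_feature(
    run: Run, suspect: SuspectEntry, sample_id: str, params: PipelineParams
) -> Optional[Feature]:
    eic = extract_eic(run, suspect.precursor_mz, params.mz_tol_da)
    feats = detect_peaks(eic, sample_id=sample_id, suspect=suspect)
    if not feats:
        return None
    best = max(feats, key=lambda f: f.area)
    measured = _measure_mz(run, best, suspect.precursor_mz, params.mz_tol_da)
    return Feature(
        suspect=best.suspect,
        sample_id=best.sample_id,
        rt_apex=best.rt_apex,
        height=best.height,
        area=best.area,
        rt_bounds=best.rt_bounds,
        measured_mz=measured,
    )


# ---------------------------------------------------------------------------
# Stage 1: MS1 screening


def screen_stage(
    runs: Sequence[Run],
    suspects: Sequence[SuspectEntry],
    params: PipelineParams = PipelineParams(),
) -> Tuple[Dict[Tuple[str, str], Feature], List[BlankExclusion]]:
    """Targeted feature detection for every suspect in every sample run,
    followed by the five-fold procedure-blank exclusion rule.

    Returns the kept features keyed by (suspect name, sample id) and the
    exclusion report.
    """
    by_key = index_runs(runs)
    blanks = {k: r for k, r in by_key.items() if _is_blank(r)}
    samples = sorted({k[0] for k, r in by_key.items() if not _is_blank(r)})

    blank_feats: Dict[str, List[Feature]] = {}
    seen_blank = set()
    for (sid, pol, acq), run in sorted(blanks.items()):
        if (sid, pol) in seen_blank:
            continue  # one blank acquisition per polarity suffices for MS1
        seen_blank.add((sid, pol))
        for suspect in suspects:
            if suspect.adduct.polarity != pol:
                continue
            feat = _best_feature(run, suspect, sid, params)
            if feat is not None:
                blank_feats.setdefault(pol, []).append(feat)

    features: Dict[Tuple[str, str], Feature] = {}
    exclusions: List[BlankExclusion] = []
    for sample in samples:
        for pol in ("negative", "positive"):
            run = by_key.get((sample, pol, "DDA")) or by_key.get((sample, pol, "DIA"))
            if run is None:
                continue
            found: List[Feature] = []
            for suspect in suspects:
                if suspect.adduct.polarity != pol:
                    continue
                feat = _best_feature(run, suspect, sample, params)
                if feat is not None:
                    found.append(feat)
            kept, excl = blank_filter(
                found,
                blank_feats.get(pol, []),
                min_ratio=params.blank_ratio,
                rt_tol=params.blank_rt_tol,
            )
            exclusions.extend(excl)
            for feat in kept:
                features[(feat.suspect.name, sample)] = feat
    return features, exclusions


# ---------------------------------------------------------------------------
# Stage 2: fragmentation matching


def _acquire_spectrum(
    suspect: SuspectEntry,
    feature: Feature,
    dda_run: Optional[Run],
    dia_run: Optional[Run],
    prefer: str,
    params: PipelineParams,
) -> Tuple[Optional[str], Tuple[Tuple[float, float], ...]]:
    """Fragmentation-derived spectrum via the preferred route, falling back
    to the other when the preferred one yields nothing."""

    def try_dda():
        if dda_run is None:
            return None
        scan = select_dda_spectrum(
            dda_run,
            suspect.precursor_mz,
            (feature.rt_bounds[0] - 0.05, feature.rt_bounds[1] + 0.05),
            tol_da=params.mz_tol_da,
        )
        if scan is None or not scan.peaks.size:
            return None
        return tuple((float(mz), float(i)) for mz, i in scan.peaks)

    def try_dia():
        if dia_run is None or not dia_run.scans(DIA_HIGH):
            return None
        eic = extract_eic(dia_run, suspect.precursor_mz, params.mz_tol_da)
        feats = detect_peaks(eic, sample_id=feature.sample_id, suspect=suspect)
        near = [f for f in feats if abs(f.rt_apex - feature.rt_apex) <= 0.2]
        if not near:
            return None
        dia_feat = max(near, key=lambda f: f.area)
        spec = dia_pseudo_spectrum(
            dia_run,
            eic,
            dia_feat,
            frag_tol_da=params.frag_tol_da,
            min_corr=params.dia_min_corr,
        )
        return tuple(spec) if spec else None

    routes = ("DDA", "DIA") if prefer == "DDA" else ("DIA", "DDA")
    for route in routes:
        spectrum = try_dda() if route == "DDA" else try_dia()
        if spectrum:
            return route, spectrum
    return None, ()


def match_stage(
    runs: Sequence[Run],
    features: Dict[Tuple[str, str], Feature],
    msp_library: Sequence,
    standards: Dict[str, Dict],
    params: PipelineParams = PipelineParams(),
) -> Dict[Tuple[str, str], MatchReport]:
    """Acquire and score a fragmentation-derived spectrum for every kept
    feature.

    Per sample and polarity, the top ``maa_k`` features by area take the
    DDA route (the most abundant compounds), the rest the DIA route; either
    falls back to the other when its run or scans are missing.
    """
    by_key = index_runs(runs)
    library_by_name = {rec.name.casefold(): rec for rec in msp_library}
    standards_by_name = {name.casefold(): entry for name, entry in standards.items()}

    dda_route: Dict[Tuple[str, str], bool] = {}
    groups: Dict[Tuple[str, str], List[Feature]] = {}
    for (name, sample), feat in features.items():
        groups.setdefault((sample, feat.suspect.adduct.polarity), []).append(feat)
    for (sample, pol), feats in groups.items():
        ranked = sorted(feats, key=lambda f: (-f.area, f.rt_apex, f.suspect.name))
        top = {f.suspect.name for f in ranked[: params.maa_k]}
        for f in feats:
            dda_route[(f.suspect.name, sample)] = f.suspect.name in top

    reports: Dict[Tuple[str, str], MatchReport] = {}
    for (name, sample), feat in sorted(features.items()):
        suspect = feat.suspect
        pol = suspect.adduct.polarity
        prefer = "DDA" if dda_route[(name, sample)] else "DIA"
        route, spectrum = _acquire_spectrum(
            suspect,
            feat,
            by_key.get((sample, pol, "DDA")),
            by_key.get((sample, pol, "DIA")),
            prefer,
            params,
        )
        library_score = None
        standard_score = None
        n_matched = 0
        diagnostic_ok = None
        in_silico_ok = None
        if spectrum:
            record = library_by_name.get(name.casefold())
            if record is not None:
                res = cosine_score(spectrum, record.peaks, params.frag_tol_da)
                library_score, n_matched = res.score, res.n_matched
            standard = standards_by_name.get(name.casefold())
            if standard is not None and standard.get("peaks"):
                res = cosine_score(spectrum, standard["peaks"], params.frag_tol_da)
                standard_score = res.score
                n_matched = max(n_matched, res.n_matched)
            if suspect.diagnostic_ions:
                diagnostic_ok, _ = diagnostic_ion_check(
                    spectrum, suspect.diagnostic_ions, params.frag_tol_da
                )
            if suspect.in_silico_fragments:
                pairs = match_peaks(
                    spectrum,
                    [(mz, 1.0) for mz in suspect.in_silico_fragments],
                    params.frag_tol_da,
                ).pairs
                in_silico_ok = (
                    len(pairs) / len(suspect.in_silico_fragments)
                    >= params.in_silico_min_fraction
                )
        reports[(name, sample)] = MatchReport(
            suspect_name=name,
            sample_id=sample,
            route=route,
            spectrum=spectrum,
            library_score=library_score,
            standard_score=standard_score,
            n_matched=n_matched,
            diagnostic_ok=diagnostic_ok,
            in_silico_ok=in_silico_ok,
        )
    return reports


# ---------------------------------------------------------------------------
# Stage 3: annotation


def annotate_stage(
    features: Dict[Tuple[str, str], Feature],
    match_reports: Dict[Tuple[str, str], MatchReport],
    suspects: Sequence[SuspectEntry],
    standards: Dict[str, Dict],
    params: PipelineParams = PipelineParams(),
) -> Tuple[List[Annotation], Dict[str, str], Dict[str, List[str]], Dict[str, int]]:
    """Assemble per-(compound, sample) evidence, assign levels, collapse
    formula isomers, and build the level histogram over reported compounds."""
    standards_by_name = {name.casefold(): entry for name, entry in standards.items()}

    evidence: Dict[Tuple[str, str], Evidence] = {}
    for (name, sample), feat in features.items():
        suspect = feat.suspect
        report = match_reports.get((name, sample))
        mass_ok = (
            feat.measured_mz is not None
            and abs(feat.measured_mz - suspect.precursor_mz) <= params.mz_tol_da
        )
        if not mass_ok:
            continue
        standard = standards_by_name.get(name.casefold())
        evidence[(name, sample)] = Evidence(
            mass_match=True,
            formula_confirmed=True,  # exact-mass fit; no isotope scoring
            spectrum_route=report.route if report else None,
            library_score=report.library_score if report and report.route else None,
            standard_available=standard is not None,
            standard_rt=standard["rt"] if standard else None,
            standard_score=report.standard_score if report else None,
            rt_observed=feat.rt_apex,
            predicted_rt=suspect.predicted_rt,
            diagnostic_ions_ok=report.diagnostic_ok if report else None,
            in_silico_support=report.in_silico_ok if report else None,
        )
    annotations, per_compound, _ = annotate_dataset(evidence, params.thresholds())

    # Isomer collapse: same formula, polarity and RT cannot be told apart by
    # exact mass; report one primary per group.
    suspect_by_name = {s.name: s for s in suspects}
    info = []
    for name, level in per_compound.items():
        suspect = suspect_by_name[name]
        rts = sorted(f.rt_apex for (n, _), f in features.items() if n == name)
        info.append(
            (suspect.formula.hill(), suspect.adduct.polarity, rts[len(rts) // 2], name, level)
        )
    info.sort()
    compound_levels: Dict[str, str] = {}
    co_candidates: Dict[str, List[str]] = {}
    i = 0
    while i < len(info):
        j = i
        group = [info[i]]
        while (
            j + 1 < len(info)
            and info[j + 1][0] == info[i][0]
            and info[j + 1][1] == info[i][1]
            and info[j + 1][2] - info[j][2] <= 0.2
        ):
            j += 1
            group.append(info[j])
        strongest = best_level([g[4] for g in group])
        primary = min(group, key=lambda g: (g[4] != strongest, g[3]))
        compound_levels[primary[3]] = primary[4]
        others = [g[3] for g in group if g[3] != primary[3]]
        if others:
            co_candidates[primary[3]] = others
        i = j + 1

    histogram: Dict[str, int] = {}
    for level in compound_levels.values():
        histogram[level] = histogram.get(level, 0) + 1
    return annotations, compound_levels, co_candidates, histogram


def run_screening(
    runs: Sequence[Run],
    suspects: Sequence[SuspectEntry],
    msp_library: Sequence,
    standards: Dict[str, Dict],
    params: PipelineParams = PipelineParams(),
) -> ScreeningResult:
    """Execute screen → match → annotate over a set of runs.

    ``runs`` mixes samples and procedure blanks (identified by a truthy
    ``blank`` metadata flag or sample id "blank"), DDA and DIA acquisitions,
    both polarities.  ``standards`` maps compound name → {"rt", "peaks"} for
    the reference standards at hand.
    """
    features, exclusions = screen_stage(runs, suspects, params)
    reports = match_stage(runs, features, msp_library, standards, params)
    annotations, compound_levels, co_candidates, histogram = annotate_stage(
        features, reports, suspects, standards, params
    )
    return ScreeningResult(
        features=features,
        exclusions=exclusions,
        match_reports=reports,
        annotations=annotations,
        compound_levels=compound_levels,
        co_candidates=co_candidates,
        histogram=histogram,
    )
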
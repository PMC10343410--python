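"""Identification-confidence assignment on the Schymanski 1–5 scale.

The rules, strongest first:

* **1** — a reference standard is available, the observed retention time
  agrees with the standard's within tolerance, and the acquired spectrum
  matches the standard's spectrum (score ≥ 0.6).
* **2a** — a spectral-library spectrum matches with cosine score > 0.7.
* **2b** — no usable library spectrum, but all diagnostic ions are present
  (e.g. the aglycone ion of a glycoside).
* **3** — tentative: fragmentation is consistent with an in-silico fragment
  list.
* **4** — the molecular formula is confirmed (here: exact-mass fit, since
  the synthetic fixtures carry no isotope patterns).
* **5** — exact mass of interest only.

The 0.7 gate applies to library matches (2a) specifically; level 1
confirmation uses the laxer 0.6 gate against the standard's own spectrum
plus the RT requirement.  Each annotation carries a machine-readable
rationale naming exactly the rule that fired.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

__all__ = [
    "LEVELS",
    "Evidence",
    "Annotation",
    "LevelThresholds",
    "assign_level",
    "annotate_dataset",
    "best_level",
]

#: Levels in decreasing evidence strength; index = rank (lower is stronger).
LEVELS = ("1", "2a", "2b", "3", "4", "5")
_RANK = {lvl: i for i, lvl in enumerate(LEVELS)}


@dataclass(frozen=True)
class LevelThresholds:
    rt_tol_min: float = 0.5
    level1_score_min: float = 0.6
    library_score_min: float = 0.7  # strict gate for 2a
    mass_tol_da: float = 0.005


@dataclass(frozen=True)
class Evidence:
    """Everything gathered about one suspect in one sample."""

    mass_match: bool
    formula_confirmed: bool = False
    spectrum_route: Optional[str] = None  # "DDA" | "DIA"
    library_score: Optional[float] = None
    standard_available: bool = False
    standard_rt: Optional[float] = None
    standard_score: Optional[float] = None
    rt_observed: Optional[float] = None
    predicted_rt: Optional[float] = None
    diagnostic_ions_ok: Optional[bool] = None
    in_silico_support: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.library_score is not None and self.spectrum_route is None:
            raise ValueError("library score without an acquired spectrum")
        if self.standard_rt is not None and not self.standard_available:
            raise ValueError("standard RT given but no standard available")


@dataclass(frozen=True)
class Annotation:
    suspect_name: str
    sample_id: str
    level: str
    score: Optional[float]
    rationale: str


def assign_level(
    evidence: Evidence,
    thresholds: LevelThresholds = LevelThresholds(),
    suspect_name: str = "",
    sample_id: str = "",
) -> Annotation:
    """Apply the level rules in order of evidence strength; first hit wins."""
    if not evidence.mass_match:
        raise ValueError("no annotation without an exact-mass match")
    ev, th = evidence, thresholds
    if (
        ev.standard_available
        and ev.standard_rt is not None
        and ev.rt_observed is not None
        and abs(ev.rt_observed - ev.standard_rt) <= th.rt_tol_min
        and ev.standard_score is not None
        and ev.standard_score >= th.level1_score_min
    ):
        return Annotation(
            suspect_name,
            sample_id,
            "1",
            ev.standard_score,
            f"L1: standard match score {ev.standard_score:.2f} >= "
            f"{th.level1_score_min}, |dRT| "
            f"{abs(ev.rt_observed - ev.standard_rt):.2f} <= {th.rt_tol_min}",
        )
    if ev.library_score is not None and ev.library_score > th.library_score_min:
        return Annotation(
            suspect_name,
            sample_id,
            "2a",
            ev.library_score,
            f"L2a: library score {ev.library_score:.2f} > {th.library_score_min}",
        )
    if ev.diagnostic_ions_ok:
        return Annotation(
            suspect_name, sample_id, "2b", None, "L2b: all diagnostic ions present"
        )
    if ev.in_silico_support:
        return Annotation(
            suspect_name, sample_id, "3", None, "L3: in-silico fragmentation consistent"
        )
    if ev.formula_confirmed:
        return Annotation(
            suspect_name, sample_id, "4", None, "L4: molecular formula confirmed"
        )
    return Annotation(suspect_name, sample_id, "5", None, "L5: exact mass only")


def best_level(levels: Sequence[str]) -> str:
    """The strongest (lowest-rank) of a set of levels."""
    return min(levels, key=_RANK.__getitem__)


def annotate_dataset(
    evidence_by_compound_sample: Dict[Tuple[str, str], Evidence],
    thresholds: LevelThresholds = LevelThresholds(),
) -> Tuple[List[Annotation], Dict[str, str], Dict[str, int]]:
    """Annotate every (compound, sample) evidence record.

    Returns per-sample annotations, the per-compound dataset-level
    (best across samples), and the level histogram over compounds.
    """
    annotations = [
        assign_level(ev, thresholds, suspect_name=name, sample_id=sample)
        for (name, sample), ev in sorted(evidence_by_compound_sample.items())
    ]
    per_compound: Dict[str, List[str]] = {}
    for ann in annotations:
        per_compound.setdefault(ann.suspect_name, []).append(ann.level)
    compound_level = {name: best_level(lvls) for name, lvls in per_compound.items()}
    histogram = dict(Counter(compound_level.values()))
    return annotations, compound_level, histogram
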
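"""Target quantification with external calibration curves.

Curves are unweighted ordinary least squares fits y = a·x + b over the
working-solution levels, reported as a ± Sa and b ± Sb with the
determination coefficient R².  Sample responses are inverted through the
curve, averaged over replicates, converted mg/L → mg/kg through an explicit
sample-preparation factor (default 1, i.e. responses calibrated directly in
the drink-mass scale), and flagged when below the limit of quantification
(LOQ, default 0.5 mg/kg).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "QuantResult",
    "fit_calibration",
    "invert_concentration",
    "quantify_samples",
    "DEFAULT_LOQ_MG_KG",
]

DEFAULT_LOQ_MG_KG = 0.5


@dataclass(frozen=True)
class CalibrationCurve:
    analyte: str
    slope: float  # a, response per mg/L
    slope_se: float  # Sa
    intercept: float  # b
    intercept_se: float  # Sb
    r2: float
    levels: Tuple[Tuple[float, float], ...]  # (concentration mg/L, response)


@dataclass(frozen=True)
class QuantResult:
    analyte: str
    sample_id: str
    concentration: float  # mg/kg
    sd: float
    n: int
    below_loq: bool


def fit_calibration(
    levels: Sequence[Tuple[float, float]], analyte: str = ""
) -> CalibrationCurve:
    """Unweighted OLS fit of response vs concentration.

    Requires at least three distinct concentrations.  Standard errors are
    the classical OLS formulas; on exactly collinear points they collapse to
    zero and R² is 1.
    """
    conc = np.array([c for c, _ in levels], dtype=float)
    resp = np.array([r for _, r in levels], dtype=float)
    if len(set(conc.tolist())) < 3:
        raise ValueError("calibration requires >= 3 distinct concentration levels")
    fit = stats.linregress(conc, resp)
    # r can be nan on degenerate y; guard r2 into [0, 1]
    r2 = 0.0 if np.isnan(fit.rvalue) else float(fit.rvalue**2)
    return CalibrationCurve(
        analyte=analyte,
        slope=float(fit.slope),
        slope_se=float(fit.stderr),
        intercept=float(fit.intercept),
        intercept_se=float(fit.intercept_stderr),
        r2=r2,
        levels=tuple((float(c), float(r)) for c, r in levels),
    )


def invert_concentration(curve: CalibrationCurve, response: float) -> float:
    """Concentration (mg/L) giving ``response`` on the curve: (y − b)/a."""
    if curve.slope == 0:
        raise ZeroDivisionError(f"{curve.analyte}: zero calibration slope")
    return (response - curve.intercept) / curve.slope


def quantify_samples(
    curves: Dict[str, CalibrationCurve],
    responses: Dict[Tuple[str, str], Sequence[float]],
    prep_factor: float = 1.0,
    loq: float = DEFAULT_LOQ_MG_KG,
) -> List[QuantResult]:
    """Quantify replicate responses grouped by (analyte, sample).

    Each replicate response is inverted through the analyte's curve and
    scaled by ``prep_factor`` (mg/L → mg/kg); the result is the replicate
    mean with sample standard deviation (ddof=1, zero for n=1), flagged
    below the LOQ on the mean.
    """
    results: List[QuantResult] = []
    for (analyte, sample_id), reps in sorted(responses.items()):
        if analyte not in curves:
            raise KeyError(f"no calibration curve for analyte {analyte!r}")
        if not len(reps):
            raise ValueError(f"{analyte}/{sample_id}: no replicates")
        curve = curves[analyte]
        concs = np.array(
            [invert_concentration(curve, r) * prep_factor for r in reps]
        )
        mean = float(concs.mean())
        sd = float(concs.std(ddof=1)) if len(concs) > 1 else 0.0
        results.append(
            QuantResult(
                analyte=analyte,
                sample_id=sample_id,
                concentration=mean,
                sd=sd,
                n=len(concs),
                below_loq=mean < loq,
            )
        )
    return results
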
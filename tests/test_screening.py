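"""EIC extraction, peak detection, prioritization, blank filtering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pomscreen.model import MS1, Run, SpectrumRecord
from pomscreen.screening import (
    EIC,
    Feature,
    blank_filter,
    detect_peaks,
    extract_eic,
    select_most_abundant,
)


def _run_from_trace(rts, peaks_per_scan, sample="s"):
    spectra = [
        SpectrumRecord(f"s{i}", 1, MS1, rt, "negative", peaks)
        for i, (rt, peaks) in enumerate(zip(rts, peaks_per_scan))
    ]
    return Run(sample, spectra)


def _gaussian_run(mz=191.0, area=1e6, apex=2.0, sigma=0.05, interval=0.01, length=4.0):
    rts = np.arange(0.0, length, interval)
    h = area / (sigma * np.sqrt(2 * np.pi))
    peaks = [
        [[mz, h * np.exp(-0.5 * ((t - apex) / sigma) ** 2)]] if abs(t - apex) < 4 * sigma else []
        for t in rts
    ]
    return _run_from_trace(rts, peaks)


def test_extract_eic_window_and_outside():
    run = _gaussian_run()
    inside = extract_eic(run, 191.0, 0.005)
    assert inside.intensity.max() > 0
    outside = extract_eic(run, 191.0 + 0.010, 0.005)
    assert np.all(outside.intensity == 0)


def test_extract_eic_sums_coeluting_ions():
    rts = [0.0, 0.1, 0.2]
    peaks = [[[191.000, 10.0], [191.002, 5.0]], [[191.001, 7.0]], []]
    run = _run_from_trace(rts, peaks)
    eic = extract_eic(run, 191.001, 0.005)
    assert eic.intensity.tolist() == [15.0, 7.0, 0.0]


def test_extract_eic_requires_ms1():
    run = Run("x", [SpectrumRecord("a", 2, "DDA_MS2", 0.0, "negative",
                                   [[100.0, 1.0]], precursor_mz=100.0)])
    with pytest.raises(ValueError, match="MS1"):
        extract_eic(run, 100.0)


def test_eic_extraction_is_additive_over_concatenated_runs():
    run1 = _gaussian_run(apex=1.0, length=2.0)
    run2 = _gaussian_run(apex=1.0, length=2.0)
    shifted = [
        SpectrumRecord(s.scan_id + "b", 1, MS1, s.rt + 2.0, "negative", s.peaks)
        for s in run2.spectra
    ]
    combined = Run("s", list(run1.spectra) + shifted)
    e1 = extract_eic(run1, 191.0, 0.005)
    ec = extract_eic(combined, 191.0, 0.005)
    np.testing.assert_allclose(ec.intensity[: len(e1.intensity)], e1.intensity)
    np.testing.assert_allclose(ec.intensity[len(e1.intensity):], e1.intensity)


def test_detect_peak_recovers_planted_gaussian_area():
    run = _gaussian_run(area=1e6)
    eic = extract_eic(run, 191.0, 0.005)
    (feat,) = detect_peaks(eic, sample_id="s")
    assert feat.area == pytest.approx(1e6, rel=0.02)
    assert feat.rt_apex == pytest.approx(2.0, abs=0.011)
    assert feat.rt_bounds[0] < 2.0 < feat.rt_bounds[1]


def test_detect_peak_flat_trace_and_short_trace():
    flat = EIC(100.0, 0.005, np.arange(10) * 0.1, np.zeros(10))
    assert detect_peaks(flat) == []
    short = EIC(100.0, 0.005, np.arange(3) * 0.1, np.array([0.0, 5.0, 0.0]))
    assert detect_peaks(short) == []


def test_detect_peak_resolves_two_gaussians_in_order():
    rts = np.arange(0.0, 4.0, 0.01)
    trace = 1000 * np.exp(-0.5 * ((rts - 1.0) / 0.05) ** 2) + 2000 * np.exp(
        -0.5 * ((rts - 3.0) / 0.05) ** 2
    )
    eic = EIC(100.0, 0.005, rts, trace)
    feats = detect_peaks(eic)
    assert len(feats) == 2
    assert feats[0].rt_apex < feats[1].rt_apex
    assert feats[1].height > feats[0].height


def test_single_scan_spike_is_not_a_peak():
    y = np.zeros(50)
    y[25] = 1e5
    eic = EIC(100.0, 0.005, np.arange(50) * 0.01, y)
    assert detect_peaks(eic) == []


def _feat(name, area, rt=1.0, sample="s"):
    from pomscreen.chem import adduct_mz, get_adduct, parse_formula
    from pomscreen.suspects import SuspectEntry

    f = parse_formula("C6H8O7")
    suspect = SuspectEntry(
        name=name, formula=f, adduct=get_adduct("[M-H]-"),
        precursor_mz=adduct_mz(f, "[M-H]-"), sources=("BDSL",),
    )
    return Feature(
        suspect=suspect, sample_id=sample, rt_apex=rt, height=area / 0.1,
        area=area, rt_bounds=(rt - 0.1, rt + 0.1),
    )


def test_select_most_abundant_examples():
    feats = [_feat("a", 5.0), _feat("b", 9.0), _feat("c", 1.0)]
    top = select_most_abundant(feats, 2)
    assert [f.area for f in top] == [9.0, 5.0]
    assert len(select_most_abundant(feats, 10)) == 3
    with pytest.raises(ValueError):
        select_most_abundant(feats, -1)


def test_select_most_abundant_tie_breaks_on_earlier_rt():
    feats = [_feat("late", 5.0, rt=2.0), _feat("early", 5.0, rt=1.0)]
    assert select_most_abundant(feats, 1)[0].suspect.name == "early"


@pytest.mark.parametrize(
    "sample_area, blank_area, kept",
    [(100.0, 10.0, True), (100.0, 25.0, False), (100.0, None, True), (100.0, 20.0, True)],
)
def test_blank_filter_five_fold_rule(sample_area, blank_area, kept):
    sample = [_feat("x", sample_area)]
    blanks = [] if blank_area is None else [_feat("x", blank_area, sample="blank")]
    out, excl = blank_filter(sample, blanks, min_ratio=5.0)
    assert bool(out) is kept
    if not kept:
        assert excl[0].ratio == pytest.approx(sample_area / blank_area)


@given(st.lists(st.floats(min_value=1.0, max_value=1000.0), min_size=1, max_size=8),
       st.floats(min_value=1.0, max_value=20.0))
def test_blank_filter_output_subset_and_monotone(areas, ratio):
    sample = [_feat(f"c{i}", a) for i, a in enumerate(areas)]
    blanks = [_feat(f"c{i}", 10.0, sample="blank") for i in range(len(areas))]
    kept_lo, _ = blank_filter(sample, blanks, min_ratio=ratio)
    kept_hi, _ = blank_filter(sample, blanks, min_ratio=ratio * 2)
    names = lambda fs: {f.suspect.name for f in fs}
    assert names(kept_lo) <= names(sample)
    assert names(kept_hi) <= names(kept_lo)
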
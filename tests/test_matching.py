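"""Peak matching, cosine similarity, DDA selection, DIA pseudo-spectra."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pomscreen.matching import (
    cosine_score,
    dia_pseudo_spectrum,
    diagnostic_ion_check,
    match_peaks,
    select_dda_spectrum,
)
from pomscreen.model import DDA_MS2, DIA_HIGH, DIA_LOW, Run, SpectrumRecord
from pomscreen.screening import Feature, detect_peaks, extract_eic


def test_match_peaks_pairs_printed_fragments():
    query = [(151.0042, 100.0), (169.0170, 80.0), (179.0004, 60.0)]
    library = [(151.0037, 100.0), (169.0135, 80.0), (178.9996, 60.0)]
    matches = match_peaks(query, library, 0.01)
    assert len(matches.pairs) == 3
    assert not matches.unmatched_query and not matches.unmatched_library


def test_match_peaks_identical_and_disjoint():
    peaks = [(100.0, 1.0), (200.0, 2.0)]
    same = match_peaks(peaks, peaks, 0.01)
    assert all(d == 0.0 for _, _, d in same.pairs)
    far = match_peaks(peaks, [(150.0, 1.0)], 0.01)
    assert far.pairs == ()


def _brute_force_max_pairs(query, library, tol):
    """Exhaustive maximum one-to-one matching (oracle for small instances)."""

    def rec(qi, used):
        if qi == len(query):
            return 0
        best = rec(qi + 1, used)  # leave query peak unmatched
        for li in range(len(library)):
            if li not in used and abs(query[qi][0] - library[li][0]) <= tol:
                best = max(best, 1 + rec(qi + 1, used | {li}))
        return best

    return rec(0, frozenset())


@given(
    st.lists(st.floats(min_value=50, max_value=500), min_size=1, max_size=5),
    st.lists(st.floats(min_value=50, max_value=500), min_size=1, max_size=5),
)
def test_match_peaks_equals_optimal_assignment_on_separated_spectra(q_mzs, l_mzs):
    # well-separated: snap m/z to a 0.1 grid so greedy and optimal coincide
    q = sorted({round(mz, 1) for mz in q_mzs})
    l = sorted({round(mz, 1) for mz in l_mzs})
    query = [(mz, 1.0) for mz in q]
    library = [(mz, 1.0) for mz in l]
    matches = match_peaks(query, library, 0.01)
    assert len(matches.pairs) == _brute_force_max_pairs(query, library, 0.01)


def test_cosine_identity_disjoint_and_hand_value():
    s = [(100.0, 1.0), (200.0, 0.5)]
    assert cosine_score(s, s).score == pytest.approx(1.0)
    assert cosine_score(s, [(300.0, 1.0)]).score == 0.0
    # hand computation: (1*0.5 + 0.5*1) / (1.118^2) = 1.0 / 1.25
    res = cosine_score([(100.0, 1.0), (200.0, 0.5)], [(100.0, 0.5), (200.0, 1.0)])
    assert res.score == pytest.approx(0.8)
    assert res.n_matched == 2


def test_cosine_scale_invariance_and_symmetry():
    a = [(100.0, 10.0), (150.0, 5.0), (200.0, 1.0)]
    b = [(100.0, 3.0), (150.0, 9.0)]
    base = cosine_score(a, b).score
    assert cosine_score([(mz, i * 37.0) for mz, i in a], b).score == pytest.approx(base)
    assert cosine_score(b, a).score == pytest.approx(base)


def test_cosine_empty_spectrum_scores_zero():
    assert cosine_score([], [(100.0, 1.0)]).score == 0.0


@given(
    st.lists(
        st.tuples(st.floats(min_value=50, max_value=500), st.floats(min_value=0.1, max_value=100)),
        min_size=1,
        max_size=6,
        unique_by=lambda p: round(p[0], 1),
    )
)
def test_cosine_agrees_with_matchms(peaks):
    matchms = pytest.importorskip("matchms")
    from matchms.similarity import CosineGreedy

    peaks = sorted((round(mz, 1), i) for mz, i in peaks)
    query = [(mz, i) for mz, i in peaks]
    library = [(mz + 0.001, i * 2.0) for mz, i in peaks]
    mine = cosine_score(query, library, 0.01).score
    s1 = matchms.Spectrum(
        mz=np.array([p[0] for p in query]), intensities=np.array([p[1] for p in query]),
        metadata={}, metadata_harmonization=False,
    )
    s2 = matchms.Spectrum(
        mz=np.array([p[0] for p in library]), intensities=np.array([p[1] for p in library]),
        metadata={}, metadata_harmonization=False,
    )
    theirs = float(CosineGreedy(tolerance=0.01).pair(s1, s2)["score"])
    assert mine == pytest.approx(theirs, abs=1e-6)


# --- DDA selection ----------------------------------------------------------


def _dda_run():
    mk = lambda sid, rt, prec: SpectrumRecord(
        sid, 2, DDA_MS2, rt, "negative", [[87.0, 10.0], [111.0, 5.0]], precursor_mz=prec
    )
    spectra = [
        SpectrumRecord("m1", 1, "MS1", 0.0, "negative", [[191.02, 100.0]]),
        mk("d1", 1.0, 191.02),
        mk("d2", 1.4, 191.02),
        mk("d3", 1.5, 250.00),
    ]
    return Run("s", spectra)


def test_select_dda_spectrum_nearest_apex_wins():
    run = _dda_run()
    scan = select_dda_spectrum(run, 191.02, (0.8, 1.4))
    assert scan.scan_id == "d1"  # rt 1.0 is nearer the window center 1.1
    assert select_dda_spectrum(run, 500.0, (0.0, 2.0)) is None


def test_select_dda_spectrum_respects_mz_tolerance():
    run = _dda_run()
    assert select_dda_spectrum(run, 191.10, (0.0, 2.0), tol_da=0.005) is None


# --- DIA pseudo-spectrum ----------------------------------------------------


def _dia_run(frag_shift_min=0.0, noise_frag=False):
    """Precursor at 191.02 eluting at 2.0; fragment 87.0 co-eluting (or
    shifted); an unrelated compound at 350.1/rt 3.0 contributes fragment
    120.0."""
    rts = np.arange(1.0, 4.0, 0.02)
    sigma = 0.05
    spectra = []
    for i, t in enumerate(rts):
        prec = 5000 * np.exp(-0.5 * ((t - 2.0) / sigma) ** 2)
        other = 5000 * np.exp(-0.5 * ((t - 3.0) / sigma) ** 2)
        low = []
        if prec > 1:
            low.append([191.02, prec])
        if other > 1:
            low.append([350.10, other])
        spectra.append(SpectrumRecord(f"l{i}", 1, DIA_LOW, t, "negative", sorted(low)))
        frag = 5000 * np.exp(-0.5 * ((t - 2.0 - frag_shift_min) / sigma) ** 2)
        high = []
        if frag > 1:
            high.append([87.0, 0.8 * frag])
        if other > 1:
            high.append([120.0, 0.8 * other])
        spectra.append(
            SpectrumRecord(f"h{i}", 1, DIA_HIGH, t + 0.01, "negative", sorted(high))
        )
    return Run("s", spectra)


def _precursor_feature(run):
    eic = extract_eic(run, 191.02, 0.005)
    (feat,) = detect_peaks(eic, sample_id="s")
    return eic, feat


def test_dia_pseudo_spectrum_includes_coeluting_fragment():
    run = _dia_run()
    eic, feat = _precursor_feature(run)
    spec = dia_pseudo_spectrum(run, eic, feat)
    mzs = [mz for mz, _ in spec]
    assert any(abs(mz - 87.0) < 0.01 for mz in mzs)
    assert not any(abs(mz - 120.0) < 0.01 for mz in mzs)  # 1 min away, excluded


def test_dia_pseudo_spectrum_excludes_shifted_fragment():
    run = _dia_run(frag_shift_min=1.0)
    eic, feat = _precursor_feature(run)
    spec = dia_pseudo_spectrum(run, eic, feat)
    assert not any(abs(mz - 87.0) < 0.01 for mz, _ in spec)


def test_dia_pseudo_spectrum_empty_high_scans():
    rts = np.arange(1.0, 3.0, 0.02)
    sigma = 0.05
    spectra = []
    for i, t in enumerate(rts):
        prec = 5000 * np.exp(-0.5 * ((t - 2.0) / sigma) ** 2)
        low = [[191.02, prec]] if prec > 1 else []
        spectra.append(SpectrumRecord(f"l{i}", 1, DIA_LOW, t, "negative", low))
        spectra.append(SpectrumRecord(f"h{i}", 1, DIA_HIGH, t + 0.01, "negative", []))
    run = Run("s", spectra)
    eic, feat = _precursor_feature(run)
    assert dia_pseudo_spectrum(run, eic, feat) == []


def test_dia_pseudo_spectrum_requires_high_scans():
    run = Run("s", [SpectrumRecord("m", 1, "MS1", 0.0, "negative", [[191.02, 10.0]])])
    eic = extract_eic(run, 191.02, 0.005)
    feat = Feature(suspect=None, sample_id="s", rt_apex=0.0, height=10.0, area=1.0,
                   rt_bounds=(0.0, 0.0))
    with pytest.raises(ValueError, match="high-energy"):
        dia_pseudo_spectrum(run, eic, feat)


# --- diagnostic ions --------------------------------------------------------


def test_diagnostic_ion_check():
    spectrum = [(300.9976, 100.0), (463.05, 20.0)]
    ok, matched = diagnostic_ion_check(spectrum, [300.9990], 0.01)
    assert ok and matched == [300.9990]
    ok, matched = diagnostic_ion_check(spectrum, [999.0], 0.01)
    assert not ok and matched == []
    ok, _ = diagnostic_ion_check([(300.9990, 1.0)], [300.9990], 0.0)
    assert ok
    with pytest.raises(ValueError, match="empty"):
        diagnostic_ion_check(spectrum, [], 0.01)
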
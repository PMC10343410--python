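"""Suspect-list CSV/MSP I/O and list algebra."""

import csv

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pomscreen.chem import adduct_mz, get_adduct, parse_formula
from pomscreen.suspects import (
    MspFormatError,
    MspRecord,
    SuspectEntry,
    dedupe_key,
    intersect_lists,
    merge_lists,
    read_msp,
    read_suspect_csv,
    write_msp,
    write_suspect_csv,
)
from pomscreen.simulate import make_bdsl_csv_rows


def _entry(name, formula, adduct="[M-H]-", sources=("BDSL",), **kw):
    f = parse_formula(formula)
    a = get_adduct(adduct)
    return SuspectEntry(
        name=name, formula=f, adduct=a, precursor_mz=adduct_mz(f, a), sources=tuple(sources), **kw
    )


# --- CSV --------------------------------------------------------------------


def test_csv_round_trip_preserves_canonical_fields(tmp_path):
    entries = [
        _entry("Citric acid", "C6H8O7", predicted_rt=1.1),
        _entry("Leucine", "C6H13NO2", "[M+H]+", sources=("BDSL", "LBL")),
        _entry("Ellagic acid glucoside", "C20H16O13", sources=("VMSL",),
               diagnostic_ions=(300.9990,)),
        _entry("Ethyl gallate", "C9H10O5", in_silico_fragments=(123.0086, 169.0146),
               reference_standard_available=False),
    ]
    path = tmp_path / "list.csv"
    write_suspect_csv(entries, path)
    back = read_suspect_csv(path)
    assert len(back) == len(entries)
    for orig, rt in zip(entries, back):
        assert rt.name == orig.name
        assert rt.formula == orig.formula
        assert rt.adduct.name == orig.adduct.name
        assert rt.sources == orig.sources
        assert rt.precursor_mz == pytest.approx(orig.precursor_mz, abs=1e-4)
        assert rt.diagnostic_ions == orig.diagnostic_ions
        assert rt.in_silico_fragments == orig.in_silico_fragments
    # second round trip is exactly stable (canonical form reached)
    path2 = tmp_path / "list2.csv"
    write_suspect_csv(back, path2)
    assert path.read_text() == path2.read_text()


def test_734_entry_antioxidant_list(tmp_path):
    rows = make_bdsl_csv_rows(734)
    path = tmp_path / "bdsl.csv"
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["name", "formula", "adduct", "source"])
        w.writeheader()
        w.writerows(rows)
    entries = read_suspect_csv(path)
    assert len(entries) == 734
    citric = next(e for e in entries if e.name == "Citric acid")
    # missing mass column: precursor recomputed from the formula
    assert citric.precursor_mz == pytest.approx(191.0197, abs=1e-4)


def test_empty_csv_with_header(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("name,formula\n")
    assert read_suspect_csv(path) == []


def test_csv_missing_required_column(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("name,mass\nX,123\n")
    with pytest.raises(ValueError, match="formula"):
        read_suspect_csv(path)


def test_csv_formula_error_reports_row(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("name,formula\nGood,H2O\nBad,Qq3\n")
    with pytest.raises(ValueError, match="row 3"):
        read_suspect_csv(path)


def test_neutral_exact_mass_column_is_adducted(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text("name,formula,exact_mass,adduct\nCitric acid,C6H8O7,192.0270,[M-H]-\n")
    (entry,) = read_suspect_csv(path)
    assert entry.precursor_mz == pytest.approx(191.0197, abs=1e-3)


# --- MSP --------------------------------------------------------------------


def _record(name="Kaempferol", formula="C15H10O6", peaks=((133.0297, 100.0),)):
    return MspRecord(
        name=name,
        formula=parse_formula(formula),
        precursor_mz=285.0405,
        precursor_type="[M-H]-",
        ion_mode="negative",
        retention_time=7.2,
        peaks=tuple(peaks),
        extra=(("COMMENT", "GNPS ID: VF-NPL-QEHF014174"),),
    )


def test_msp_round_trip_with_unknown_keys(tmp_path):
    rec = _record(peaks=((133.0297, 100.0), (151.0039, 80.0), (175.0388, 60.0), (285.0400, 40.0)))
    path = tmp_path / "lib.msp"
    write_msp([rec], path)
    text = path.read_text()
    assert "Num Peaks: 4" in text
    assert "COMMENT: GNPS ID: VF-NPL-QEHF014174" in text
    (back,) = read_msp(path)
    assert back.name == rec.name
    assert back.formula == rec.formula
    assert back.extra == rec.extra
    assert len(back.peaks) == 4
    assert [round(mz, 4) for mz, _ in back.peaks] == [133.0297, 151.0039, 175.0388, 285.04]


@given(
    st.lists(
        st.tuples(
            st.floats(min_value=50, max_value=999, allow_nan=False),
            st.floats(min_value=0.1, max_value=9999.0, allow_nan=False),
        ),
        min_size=1,
        max_size=8,
        unique_by=lambda p: round(p[0], 4),
    )
)
def test_msp_round_trip_random_records(tmp_path_factory, peaks):
    peaks = tuple(sorted((round(mz, 4), round(i, 1)) for mz, i in peaks))
    peaks = tuple((mz, i) for mz, i in peaks if i > 0)
    if not peaks:
        return
    rec = _record(peaks=peaks)
    path = tmp_path_factory.mktemp("msp") / "r.msp"
    write_msp([rec], path)
    (back,) = read_msp(path)
    assert [(round(a, 4), round(b, 1)) for a, b in back.peaks] == list(peaks)


def test_msp_truncated_file_errors(tmp_path):
    path = tmp_path / "bad.msp"
    path.write_text(
        "NAME: X\nFORMULA: H2O\nPRECURSORMZ: 17.0\nPRECURSORTYPE: [M-H]-\n"
        "IONMODE: negative\nNum Peaks: 3\n100.0\t1\n101.0\t2\n"
    )
    with pytest.raises(MspFormatError, match="peak count"):
        read_msp(path)


def test_msp_unsorted_peaks_rejected():
    with pytest.raises(ValueError, match="sorted"):
        _record(peaks=((200.0, 1.0), (100.0, 1.0)))


# --- list algebra -----------------------------------------------------------


def test_merge_unions_source_tags():
    a = _entry("Quercetin", "C15H10O7", sources=("BDSL",))
    b = _entry("Quercetin", "C15H10O7", sources=("LBL",))
    c = _entry("Rutin", "C27H30O16", sources=("LBL",))
    merged = merge_lists([[a], [b, c]])
    assert len(merged) == 2
    assert merged[0].sources == ("BDSL", "LBL")


def test_merge_keeps_name_collisions_with_different_formulas():
    a = _entry("Isomer", "C6H12O6")
    b = _entry("Isomer", "C7H12O6")
    assert len(merge_lists([[a], [b]])) == 2


def test_merge_is_order_insensitive_up_to_ordering():
    xs = [_entry("A", "C6H8O7"), _entry("B", "C7H6O5", sources=("LBL",))]
    ys = [_entry("B", "C7H6O5", sources=("VMSL",)), _entry("C", "C4H4O4")]
    one = {dedupe_key(e): e.sources for e in merge_lists([xs, ys])}
    two = {dedupe_key(e): e.sources for e in merge_lists([ys, xs])}
    assert one.keys() == two.keys()
    for k in one:
        assert set(one[k]) == set(two[k])


def test_intersect_idempotent_subset_and_empty():
    xs = [_entry("A", "C6H8O7"), _entry("B", "C7H6O5")]
    ys = [_entry("B", "C7H6O5", sources=("LBL",))]
    inter = intersect_lists(xs, ys)
    assert [e.name for e in inter] == ["B"]
    assert {dedupe_key(e) for e in inter} <= {dedupe_key(e) for e in xs}
    assert [e.name for e in intersect_lists(xs, xs)] == ["A", "B"]
    assert intersect_lists(xs, []) == []


def test_suspect_entry_precursor_consistency_enforced():
    with pytest.raises(ValueError, match="inconsistent"):
        SuspectEntry(
            name="Broken",
            formula=parse_formula("C6H8O7"),
            adduct=get_adduct("[M-H]-"),
            precursor_mz=200.0,
            sources=("BDSL",),
        )
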
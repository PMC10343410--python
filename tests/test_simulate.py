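"""Synthetic-run generator and study fixture ground truth."""

import numpy as np
import pytest

from pomscreen.model import DIA_HIGH, write_run_json
from pomscreen.screening import detect_peaks, extract_eic
from pomscreen.simulate import (
    BLANK_ID,
    COMMON_SIX,
    SAMPLES,
    QUANT_TABLE,
    CompoundSpec,
    RunRecipe,
    generate_run,
    quant_fixture,
    study_fixture,
)
from pomscreen.suspects import intersect_lists


def _one_compound_recipe(area=1e6, scan_interval=0.01, noise=0.0, seed=5, acquisition="DDA"):
    compound = CompoundSpec(
        name="Probe",
        formula="C6H8O7",
        adduct="[M-H]-",
        rt_apex=2.0,
        exp_mz=191.0213,
        fragments=(87.0092, 111.0094),
        area_by_sample={"s": area},
        peak_sigma=0.05,
    )
    return RunRecipe(
        sample_id="s",
        compounds=[compound],
        acquisition=acquisition,
        polarity="negative",
        gradient_length=4.0,
        scan_interval=scan_interval,
        noise_level=noise,
        seed=seed,
    )


def test_generated_eic_area_recovers_specified_area():
    run = generate_run(_one_compound_recipe())
    eic = extract_eic(run, 191.0213, 0.005)
    area = np.trapezoid(eic.intensity, eic.rt)
    assert area == pytest.approx(1e6, rel=0.02)


def test_eic_area_converges_with_finer_sampling():
    errors = []
    for interval in (0.02, 0.005):
        run = generate_run(_one_compound_recipe(scan_interval=interval))
        eic = extract_eic(run, 191.0213, 0.005)
        errors.append(abs(np.trapezoid(eic.intensity, eic.rt) - 1e6))
    assert errors[1] < errors[0]


def test_zero_noise_no_compounds_gives_empty_spectra():
    recipe = RunRecipe(
        sample_id="s", compounds=[], acquisition="DDA", polarity="negative",
        gradient_length=1.0, scan_interval=0.1, noise_level=0.0, seed=1,
    )
    run = generate_run(recipe)
    assert all(s.peaks.size == 0 for s in run.spectra)
    assert run.tic == 0.0


def test_same_seed_gives_byte_identical_runs(tmp_path):
    paths = []
    for i in range(2):
        run = generate_run(_one_compound_recipe(noise=20.0, seed=11))
        path = tmp_path / f"run{i}.json"
        write_run_json(run, path)
        paths.append(path.read_bytes())
    assert paths[0] == paths[1]
    other = generate_run(_one_compound_recipe(noise=20.0, seed=12))
    path3 = tmp_path / "run3.json"
    write_run_json(other, path3)
    assert path3.read_bytes() != paths[0]


def test_dda_and_dia_recipes_share_ms1_features():
    feats = {}
    for acq in ("DDA", "DIA"):
        run = generate_run(_one_compound_recipe(acquisition=acq))
        eic = extract_eic(run, 191.0213, 0.005)
        (feat,) = detect_peaks(eic, sample_id="s")
        feats[acq] = feat
    assert feats["DDA"].rt_apex == pytest.approx(feats["DIA"].rt_apex, abs=1e-9)
    assert feats["DDA"].area == pytest.approx(feats["DIA"].area, rel=1e-6)


def test_dia_run_contains_high_energy_fragments():
    run = generate_run(_one_compound_recipe(acquisition="DIA"))
    high = run.scans(DIA_HIGH)
    assert high and any(s.peaks.size for s in high)
    # fragments only appear in high-energy scans
    ms1_mzs = np.concatenate([s.peaks[:, 0] for s in run.scans("DIA_LOW") if s.peaks.size])
    assert not np.any(np.abs(ms1_mzs - 87.0092) < 0.005)


def test_overlapping_precursors_warn():
    c1 = CompoundSpec("A", "C6H8O7", "[M-H]-", 1.0, 191.0213, (), {"s": 1e5})
    c2 = CompoundSpec("B", "C7H12O6", "[M-H]-", 2.0, 191.0230, (), {"s": 1e5})
    recipe = RunRecipe("s", [c1, c2], "DDA", "negative", gradient_length=3.0,
                       scan_interval=0.05, noise_level=0.0, seed=0)
    with pytest.warns(UserWarning, match="overlap"):
        generate_run(recipe)


# --- study fixture ----------------------------------------------------------


def test_fixture_lists_and_intersection():
    fx = study_fixture(seed=0)
    assert len(fx.suspects) >= 29
    inter = intersect_lists(fx.suspect_lists["VMSL"], fx.suspect_lists["LBL"])
    assert sorted(e.name for e in inter) == sorted(COMMON_SIX)
    assert len(fx.suspect_lists["VMSL"]) == 7 * 3 * 2  # seven scaffolds, defaults


def test_fixture_citric_acid_ground_truth():
    fx = study_fixture(seed=0)
    citric = next(c for c in fx.compounds if c.name == "Citric acid")
    assert citric.rt_apex == 1.2
    assert citric.standard_rt == 1.2
    assert citric.fragments == (57.0353, 87.0092, 111.0094, 191.0198)
    assert citric.reference_standard_available


def test_fixture_blank_areas_exercise_both_sides_of_the_rule():
    fx = study_fixture(seed=0)
    for c in fx.compounds:
        blank = c.area_by_sample.get(BLANK_ID)
        sample_min = min(c.area_by_sample[s] for s in SAMPLES)
        if c.name.startswith("Contaminant probe"):
            assert blank == pytest.approx(sample_min / 3.0)
        elif blank is not None:
            assert sample_min / blank >= 10.0 - 1e-9


def test_fixture_area_patterns_follow_reported_trends():
    fx = study_fixture(seed=0)
    areas = {c.name: c.area_by_sample for c in fx.compounds}
    eg = areas["Ethyl gallate"]
    assert eg["80%"] < eg["90%"] < eg["100%"]
    q = areas["Quercetin"]
    assert q["80%"] > q["90%"] > q["100%"]
    f = areas["Fructose"]
    assert f["80%"] == f["90%"] == f["100%"]


def test_fixture_special_roles():
    fx = study_fixture(seed=0)
    by_name = {c.name: c for c in fx.compounds}
    assert by_name["Ethyl gallate"].in_silico_only
    assert by_name["Ellagic acid glucoside"].library_spectrum is None
    assert len(fx.msp_library) == 10  # one record per library-matched compound
    assert len(fx.standards) == 17  # reference standards at hand


# --- quantification fixture -------------------------------------------------


def test_quant_fixture_citric_calibration_response():
    fx = quant_fixture()
    series = dict(fx.calibration["Citric acid"])
    assert series[5.0] == pytest.approx(114212 * 5 - 27802)  # = 543,258


def test_quant_fixture_triplicates_encode_printed_mean_and_sd():
    fx = quant_fixture()
    reps = fx.responses[("Gallic acid", "80%")]
    concs = [(r - 57556) / 46623 for r in reps]
    assert np.mean(concs) == pytest.approx(5.72, abs=1e-9)
    assert np.std(concs, ddof=1) == pytest.approx(0.41, abs=1e-9)


def test_quant_fixture_noise_is_seeded():
    a = quant_fixture(noise_rel=0.02, seed=3).calibration["Quercetin"]
    b = quant_fixture(noise_rel=0.02, seed=3).calibration["Quercetin"]
    c = quant_fixture(noise_rel=0.02, seed=4).calibration["Quercetin"]
    assert a == b != c
    assert len(QUANT_TABLE) == 10
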
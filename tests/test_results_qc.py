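"""Dish compilation, QC flags, exports, normalization, and the 4PL fit."""

import numpy as np
import pandas as pd
import pytest

import coilcounter as cc
from coilcounter.peak_analysis import StcResult
from coilcounter.results_qc import (
    check_for_errors,
    compare_auto_vs_corrected,
    compile_dish,
    export_results,
    fit_concentration_response,
    normalize_to_control,
    read_results_csv,
)
from coilcounter.segmentation import LabelMap, Region
from coilcounter.synthetic_fixtures import four_pl_fraction
from coilcounter.tracking import EmbryoTrack, TrackEntry


def make_result(embryo_id, peak_indices, duration_s=60.0, n_trans=119):
    raw = np.zeros(n_trans)
    for p in peak_indices:
        raw[p] = 0.1
    return StcResult(
        embryo_id=embryo_id,
        peak_indices=np.asarray(peak_indices, dtype=int),
        peak_count=len(peak_indices),
        frequency_per_min=len(peak_indices) * 60.0 / duration_s,
        raw_trace=raw,
        smoothed_trace=raw.copy(),
    )


def static_tracks_and_maps(n_embryos, n_frames, drop=None):
    """Simple synthetic tracking state; ``drop`` = {(embryo, frame), ...}."""
    maps = []
    tracks = [EmbryoTrack(embryo_id=i) for i in range(n_embryos)]
    for t in range(n_frames):
        labels = np.zeros((50, 20 * n_embryos + 10), dtype=np.int32)
        regions = []
        lab = 0
        for i in range(n_embryos):
            if drop and (i, t) in drop:
                continue
            lab += 1
            c = (25.0, 20.0 * i + 15.0)
            labels[20:30, 20 * i + 10 : 20 * i + 20] = lab
            regions.append(Region(lab, 100, c))
            tracks[i].entries.append(TrackEntry(t, lab, c))
        maps.append(LabelMap(labels=labels, regions=regions))
    return tracks, maps


class TestCheckForErrors:
    def test_clean_dish_zero_flags(self):
        tracks, maps = static_tracks_and_maps(20, 40)
        assert check_for_errors(tracks, maps, expected_n=20) == []

    def test_coverage_flag_for_vanishing_embryo(self):
        drop = {(3, t) for t in range(10, 40)}  # embryo 3 lost for 30 frames
        tracks, maps = static_tracks_and_maps(5, 60, drop=drop)
        flags = check_for_errors(tracks, maps, expected_n=5)
        kinds = {f.kind for f in flags}
        assert "track_coverage" in kinds
        assert any("embryo 3" in f.message for f in flags)

    def test_count_flag(self):
        tracks, maps = static_tracks_and_maps(19, 10)
        flags = check_for_errors(tracks, maps, expected_n=20)
        assert any(f.kind == "track_count" for f in flags)
        assert any("adjust" in f.suggestion or "check" in f.suggestion for f in flags)


class TestExportResults:
    def test_workbook_and_csv_round_trip(self, tmp_path):
        dish = compile_dish("dishA", [make_result(0, [5, 20, 40]),
                                      make_result(1, [3, 9, 30, 60, 90])], 0.07)
        paths = export_results(dish, tmp_path)
        assert paths["xlsx"].name == "dishA.xlsx"

        sheets = pd.read_excel(paths["xlsx"], sheet_name=None, skiprows=1)
        assert set(sheets) == {"default", "Raw data"}
        assert sheets["default"]["n_embryos_analyzed"].iloc[0] == 2
        assert sheets["default"]["threshold"].iloc[0] == pytest.approx(0.07)
        assert sheets["Raw data"]["peak_count"].tolist() == [3, 5]

        back = read_results_csv(paths["results_csv"])
        np.testing.assert_array_equal(
            back["frequency_per_min"].to_numpy(), dish.frequencies()
        )
        assert back["peak_indices"].tolist() == ["5;20;40", "3;9;30;60;90"]

    def test_id_offset_note_present(self, tmp_path):
        import openpyxl

        dish = compile_dish("d2", [make_result(0, [10])], 0.05)
        paths = export_results(dish, tmp_path)
        wb = openpyxl.load_workbook(paths["xlsx"])
        note = wb["default"].cell(row=1, column=1).value
        assert "0-based" in note and "1-based" in note

    def test_mean_frequency_is_arithmetic_mean(self):
        dish = compile_dish("d", [make_result(0, [1, 5]), make_result(1, [7])], 0.1)
        assert dish.mean_frequency_per_min == pytest.approx((2 + 1) / 2)


class TestCompareAutoVsCorrected:
    def test_identical_vectors(self):
        out = compare_auto_vs_corrected([3, 4, 5], [3, 4, 5])
        assert np.all(out["differences"] == 0)
        assert out["p_value"] == 1.0

    def test_systematic_shift_detected(self):
        # oracle: exact signed-rank with 10 all-positive differences has
        # two-sided p = 2 / 2**10 < 0.05
        corrected = np.arange(10, dtype=float)
        out = compare_auto_vs_corrected(corrected + 1, corrected)
        assert out["n_auto_higher"] == 10
        assert out["p_value"] == pytest.approx(2 / 2**10)
        assert out["p_value"] < 0.05

    def test_single_pair_skipped(self):
        with pytest.warns(UserWarning, match="2 pairs"):
            out = compare_auto_vs_corrected([3.0], [4.0])
        assert np.isnan(out["p_value"])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            compare_auto_vs_corrected([1, 2], [1])


class TestNormalizeToControl:
    def test_examples(self):
        assert normalize_to_control([3.3], 3.3)[0] == pytest.approx(100.0)
        assert normalize_to_control([6.6], 3.3)[0] == pytest.approx(200.0)
        assert normalize_to_control([0.0], 3.3)[0] == 0.0

    def test_scale_invariance(self):
        vals = np.array([1.1, 2.2, 4.4])
        a = normalize_to_control(vals, 2.2)
        b = normalize_to_control(vals * 7.3, 2.2 * 7.3)
        np.testing.assert_allclose(a, b)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            normalize_to_control([1.0], 0.0)


class TestDoseResponseFit:
    concs = np.array([0.00625, 0.0125, 0.025, 0.05, 0.1, 0.2, 0.4])

    def test_noiseless_4pl_recovered_exactly(self):
        pct = 100.0 * four_pl_fraction(self.concs, ec50=0.05, slope=2.0)
        fit = fit_concentration_response(self.concs, pct)
        assert fit.direction == "hypoactivity"
        assert fit.ec50 == pytest.approx(0.05, rel=1e-6)
        assert fit.hill == pytest.approx(2.0, rel=1e-5)
        assert fit.anchor == pytest.approx(100.0, rel=1e-6)

    def test_hyperactivity_direction(self):
        pct = 100.0 * four_pl_fraction(self.concs, ec50=0.05, slope=2.0,
                                       max_effect_frac=2.5)
        fit = fit_concentration_response(self.concs, pct)
        assert fit.direction == "hyperactivity"
        assert fit.ec50 == pytest.approx(0.05, rel=1e-4)

    def test_ec10_crosses_90pct_of_anchor(self):
        pct = 100.0 * four_pl_fraction(self.concs, ec50=0.05, slope=2.0)
        fit = fit_concentration_response(self.concs, pct)
        assert fit.ec10 is not None
        assert fit.predict([fit.ec10])[0] == pytest.approx(0.9 * fit.anchor, rel=1e-6)
        assert fit.ec10 < fit.ec50  # the 10% effect occurs at a lower dose

    def test_flat_responses_flagged_no_effect(self):
        fit = fit_concentration_response(self.concs, np.full(7, 100.0))
        assert fit.direction == "no_effect"
        assert np.isnan(fit.ec50)

    def test_noisy_recovery_within_20pct(self):
        table, truth = cc.generate_dose_response_dataset(
            ec50=0.05, slope=2.0, concentrations=self.concs,
            n_embryos=20, n_replicates=2, seed=5,
        )
        control = table.loc[table.concentration == 0, "frequency_per_min"].mean()
        means = table[table.concentration > 0].groupby("concentration")[
            "frequency_per_min"].mean()
        pct = normalize_to_control(means.to_numpy(), control)
        fit = fit_concentration_response(means.index.to_numpy(), pct)
        assert abs(fit.ec50 - truth["ec50"]) / truth["ec50"] < 0.2

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError, match="concentrations"):
            fit_concentration_response([0.0, 0.1, 0.2], [100, 80, 60])


class TestStatWrappers:
    def test_wrappers_return_stat_and_p(self):
        rng = np.random.default_rng(0)
        g1, g2 = rng.normal(0, 1, 30), rng.normal(2, 1, 30)
        for stat, p in (
            cc.results_qc.shapiro_test(g1),
            cc.results_qc.bartlett_test(g1, g2),
            cc.results_qc.kruskal_test(g1, g2),
        ):
            assert np.isfinite(stat) and 0 <= p <= 1
        assert cc.results_qc.kruskal_test(g1, g2)[1] < 0.05
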
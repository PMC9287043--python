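import numpy as np
import pytest

from satcal import CalibrationSeries, IsotopeDistribution, characterize
from satcal.corrections import (
    SaturationError,
    apply_corrections,
    detect_saturation_isotope,
    detect_saturation_ms2,
    isotope_correct,
    ms2_correct,
)

from .conftest import make_series

DIST_2TO1 = IsotopeDistribution([2.0 / 3.0, 1.0 / 3.0], charge=2, monoisotopic_mz=500.0)


def series_with_ratios(i0_levels, ratio_per_level, ms2=None):
    """MS1 series whose per-level I1/I0 ratio is set explicitly."""
    levels = [10.0**i for i in range(1, len(i0_levels) + 1)]
    i1 = [a * r for a, r in zip(i0_levels, ratio_per_level)]
    return make_series(levels, {0: i0_levels, 1: i1}, ms2_areas=ms2), levels


class TestDetectSaturationIsotope:
    def test_exact_theoretical_ratios_unflagged(self):
        i0 = [1e2, 1e3, 1e4, 1e5]
        series, _ = series_with_ratios(i0, [0.5] * 4)
        flags = detect_saturation_isotope(series, DIST_2TO1, tol=0.2)
        assert not flags.any_flagged()

    def test_top_level_exceedance_flagged(self):
        i0 = [1e2, 1e3, 1e4, 1e5]
        series, levels = series_with_ratios(i0, [0.5, 0.5, 0.5, 0.65])
        flags = detect_saturation_isotope(series, DIST_2TO1, tol=0.2)
        np.testing.assert_array_equal(
            flags.channel_flags["0"], [False, False, False, True]
        )
        assert flags.kstar == [0, 0, 0, 1]

    def test_monotone_closure_in_concentration(self):
        i0 = [1e2, 1e3, 1e4, 1e5]
        series, _ = series_with_ratios(i0, [0.5, 0.5, 0.7, 0.5])
        flags = detect_saturation_isotope(series, DIST_2TO1, tol=0.2)
        np.testing.assert_array_equal(
            flags.channel_flags["0"], [False, False, True, True]
        )

    def test_single_channel_directs_to_ms2(self):
        series = make_series([1.0, 10.0, 100.0], {0: [1.0, 10.0, 100.0]})
        with pytest.raises(SaturationError, match="MS2"):
            detect_saturation_isotope(series, DIST_2TO1)

    def test_simulator_flags_match_transfer_function(self, mono_sat_experiment):
        """Flagged set equals the closed-form inversion of the simulator ceiling.

        Both isotope channels pass through the same ceiling, so the observed
        I1/I0 ratio is inflated by the ratio of their compression factors
        h(v) = (1 - exp(-v))/v at v1 = u/2 and v0 = u, with u the true
        monoisotopic intensity in units of Imax.  The tolerance-matched
        onset u* solves h(u/2)/h(u) = 1 + tol.
        """
        from scipy.optimize import brentq

        cfg, table, truth = mono_sat_experiment

        def h(v):
            return (1.0 - np.exp(-v)) / v

        tol = 0.1
        series = CalibrationSeries.from_records(table, "pep")
        flags = detect_saturation_isotope(series, DIST_2TO1, tol=tol)
        u_star = brentq(lambda u: h(u / 2.0) / h(u) - 1.0 - tol, 1e-6, 50.0)
        slope_mono = truth["analytes"]["pep"]["slope_mono"]
        expected = slope_mono * flags.levels > u_star * cfg.imax_ms1
        np.testing.assert_array_equal(flags.channel_flags["0"], expected)


class TestIsotopeCorrect:
    def test_ratio_arithmetic(self):
        dist = IsotopeDistribution([0.64, 0.32], monoisotopic_mz=400.0)
        series, _ = series_with_ratios([1e3, 1e4, 1e5, 2.0e5], [0.5, 0.5, 0.5, 1.0])
        flags = detect_saturation_isotope(series, dist, tol=0.2)
        corrected, records = isotope_correct(series, dist, flags)
        top = [r for r in records if r.concentration == 1.0e4][0]
        # I1exp = 2e5, scale I0th/I1th = 2 -> 4e5
        assert top.method == "isotope"
        assert top.corrected == pytest.approx(4.0e5)
        assert top.scale == pytest.approx(2.0)

    def test_unflagged_levels_identity(self):
        series, _ = series_with_ratios([7.3e4, 7.3e5, 7.3e6], [0.5] * 3)
        flags = detect_saturation_isotope(series, DIST_2TO1, tol=0.2)
        corrected, records = isotope_correct(series, DIST_2TO1, flags)
        assert all(r.method == "none" for r in records)
        assert all(r.corrected == r.original for r in records)
        x0, y0 = series.response_points()
        x1, y1 = corrected.response_points()
        np.testing.assert_array_equal(y0, y1)

    def test_missing_donor_is_uncorrectable(self):
        # top level flagged, but its first-isotope measurement is missing:
        # no corrected value may be invented and the record is dropped
        levels = [10.0, 100.0, 1000.0, 10000.0]
        series, _ = series_with_ratios([1e2, 1e3, 1e4, 1e5], [0.5, 0.5, 0.5, 0.8])
        flags = detect_saturation_isotope(series, DIST_2TO1, tol=0.2)
        assert flags.channel_flags["0"][-1]
        broken = series.data.copy()
        top_donor = (broken["channel"] == "1") & (
            broken["concentration"] == broken["concentration"].max()
        )
        broken.loc[top_donor, "area"] = np.nan
        from satcal import CalibrationSeries as CS

        series2 = CS(series.analyte, series.mode, broken, "MS1")
        corrected, records = isotope_correct(series2, DIST_2TO1, flags)
        top = [r for r in records if r.concentration == series.concentrations[-1]][0]
        assert top.method == "uncorrectable"
        assert np.isnan(top.corrected)
        # the top level's mono response is gone from the corrected series
        assert corrected.response_points()[0].max() == pytest.approx(1000.0)

    def test_restores_linearity_on_simulated_saturation(
        self, noiseless_mono_only_experiment
    ):
        cfg, table, truth = noiseless_mono_only_experiment
        series = CalibrationSeries.from_records(table, "pep")
        flags = detect_saturation_isotope(series, DIST_2TO1, tol=0.1)
        corrected, _ = isotope_correct(series, DIST_2TO1, flags)
        slope = truth["analytes"]["pep"]["slope_mono"]
        x, y = corrected.response_points()
        flagged = np.isin(x, flags.flagged_levels())
        # corrected (flagged) levels sit within 2% of the true linear response
        rel = np.abs(y[flagged] / (slope * x[flagged]) - 1.0)
        assert rel.max() < 0.02
        # uncorrected top level under-reports by far more than 20%
        x0, y0 = series.response_points()
        top = x0 == x0.max()
        assert np.all(np.abs(y0[top] / (slope * x0[top]) - 1.0) > 0.2)


class TestDetectSaturationMs2:
    def test_constant_ratio_unflagged(self):
        levels = [1.0, 10.0, 100.0, 1000.0]
        ms1 = {0: [10.0, 100.0, 1000.0, 10000.0]}
        ms2 = {"f1": [1.0, 10.0, 100.0, 1000.0]}
        series = make_series(levels, ms1, ms2)
        flags = detect_saturation_ms2(series, tol=0.2)
        assert not flags.any_flagged()
        assert flags.reference_ratio == pytest.approx(10.0)

    def test_ratio_drop_flags_top_level(self):
        levels = [1.0, 10.0, 100.0, 1000.0]
        ms1 = {0: [10.0, 100.0, 1000.0, 7000.0]}
        ms2 = {"f1": [1.0, 10.0, 100.0, 1000.0]}
        series = make_series(levels, ms1, ms2)
        flags = detect_saturation_ms2(series, tol=0.2)
        np.testing.assert_array_equal(
            flags.channel_flags["0"], [False, False, False, True]
        )

    def test_zero_ms2_levels_excluded_from_reference(self):
        levels = [1.0, 10.0, 100.0, 1000.0]
        ms1 = {0: [10.0, 100.0, 1000.0, 10000.0]}
        ms2 = {"f1": [0.0, 10.0, 100.0, 1000.0]}
        series = make_series(levels, ms1, ms2)
        flags = detect_saturation_ms2(series, tol=0.2)
        assert flags.reference_ratio == pytest.approx(10.0)

    def test_requires_ms2_channels(self):
        series = make_series([1.0, 10.0, 100.0], {0: [1.0, 10.0, 100.0]})
        with pytest.raises(SaturationError):
            detect_saturation_ms2(series)

    def test_simulator_ms1_only_saturation_flags(self, two_peak_analyte):
        from satcal.synthetic import SimulationConfig, simulate_experiment

        cfg = SimulationConfig(
            [two_peak_analyte],
            n_levels=13,
            fold_step=10.0**0.5,
            replicates=2,
            replicate_cv=0.0,
            noise_floor_median=5.0,
            imax_ms1=1e4,
            imax_ms2=None,
            n_isotope_channels=2,
            seed=21,
        )
        table, truth = simulate_experiment(cfg)
        series = CalibrationSeries.from_records(table, "pep")
        tol = 0.2
        flags = detect_saturation_ms2(series, tol=tol)
        # MS1 under-reporting factor is (1-exp(-v))/v at v = I_true/Imax
        slope = truth["analytes"]["pep"]["slope_mono"]
        v = slope * flags.levels / cfg.imax_ms1
        under = (1.0 - np.exp(-v)) / v
        expected = under < (1.0 - tol)
        got = flags.channel_flags["0"]
        # agreement except possibly at the threshold-straddling level
        assert (got != expected).sum() <= 1


class TestMs2Correct:
    def test_scale_arithmetic(self):
        levels = [1.0, 10.0, 100.0, 1000.0]
        ms1 = {0: [10.0, 100.0, 1000.0, 3500.0]}
        ms2 = {"f1": [0.6, 6.0, 60.0, 300.0], "f2": [0.4, 4.0, 40.0, 200.0]}
        series = make_series(levels, ms1, ms2)
        flags = detect_saturation_ms2(series, tol=0.2)
        assert flags.reference_ratio == pytest.approx(10.0)
        corrected, records = ms2_correct(series, flags)
        top = [r for r in records if r.concentration == 1000.0][0]
        assert top.method == "ms2"
        assert top.corrected == pytest.approx(10.0 * 500.0)

    def test_no_flags_identity(self):
        levels = [1.0, 10.0, 100.0, 1000.0]
        ms1 = {0: [10.0, 100.0, 1000.0, 10000.0]}
        ms2 = {"f1": [1.0, 10.0, 100.0, 1000.0]}
        series = make_series(levels, ms1, ms2)
        flags = detect_saturation_ms2(series, tol=0.2)
        corrected, records = ms2_correct(series, flags)
        np.testing.assert_array_equal(
            series.response_points()[1], corrected.response_points()[1]
        )

    def test_corrects_simulated_top_level(self, two_peak_analyte):
        from satcal.synthetic import SimulationConfig, simulate_experiment

        cfg = SimulationConfig(
            [two_peak_analyte],
            n_levels=13,
            fold_step=10.0**0.5,
            replicates=2,
            replicate_cv=0.0,
            noise_floor_median=0.5,
            imax_ms1=1e4,
            imax_ms2=None,
            n_isotope_channels=2,
            seed=33,
        )
        table, truth = simulate_experiment(cfg)
        series = CalibrationSeries.from_records(table, "pep")
        flags = detect_saturation_ms2(series, tol=0.1)
        corrected, _ = ms2_correct(series, flags)
        slope = truth["analytes"]["pep"]["slope_mono"]
        x, y = corrected.response_points()
        top = x == x.max()
        assert np.abs(y[top] / (slope * x.max()) - 1.0).max() < 0.02


class TestInvariants:
    def test_isotope_idempotent(self, mono_sat_experiment):
        cfg, table, _ = mono_sat_experiment
        series = CalibrationSeries.from_records(table, "pep")
        flags = detect_saturation_isotope(series, DIST_2TO1, tol=0.1)
        corrected, _ = isotope_correct(series, DIST_2TO1, flags)
        flags2 = detect_saturation_isotope(corrected, DIST_2TO1, tol=0.1)
        assert not flags2.any_flagged()
        twice, _ = isotope_correct(corrected, DIST_2TO1, flags2)
        np.testing.assert_allclose(
            corrected.response_points()[1], twice.response_points()[1]
        )

    def test_ms2_idempotent(self, mono_sat_experiment):
        cfg, table, _ = mono_sat_experiment
        series = CalibrationSeries.from_records(table, "pep")
        flags = detect_saturation_ms2(series, tol=0.1)
        corrected, _ = ms2_correct(series, flags)
        flags2 = detect_saturation_ms2(corrected, tol=0.1)
        assert not flags2.any_flagged()

    def test_order_preserved_zero_noise(self, noiseless_sat_experiment):
        cfg, table, _ = noiseless_sat_experiment
        series = CalibrationSeries.from_records(table, "pep")
        flags = detect_saturation_isotope(series, DIST_2TO1, tol=0.1)
        corrected, _ = isotope_correct(series, DIST_2TO1, flags)
        tab = corrected.response_table().groupby("concentration")["area"].mean()
        assert np.all(np.diff(tab.to_numpy()) > 0)

    def test_uloq_extension_approaches_theoretical_ratio(
        self, noiseless_sat_experiment
    ):
        cfg, table, _ = noiseless_sat_experiment
        series = CalibrationSeries.from_records(table, "pep")
        flags = detect_saturation_isotope(series, DIST_2TO1, tol=0.1)
        corrected, _ = isotope_correct(series, DIST_2TO1, flags)
        f0 = characterize(series, delta=0.2)
        f1 = characterize(corrected, delta=0.2)
        assert f1.uloq / f0.uloq == pytest.approx(2.0, rel=0.05)

    def test_apply_corrections_reports_both(self, mono_sat_experiment):
        cfg, table, _ = mono_sat_experiment
        series = CalibrationSeries.from_records(table, "pep")
        variants = apply_corrections(series, DIST_2TO1, tol=0.1)
        assert set(variants) == {"uncorrected", "isotope", "ms2"}
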
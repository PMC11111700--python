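import numpy as np
import pandas as pd
import pytest

import vigapfill as vg
from vigapfill.identification import LABEL_VALID, REASON_NONE, ValidityMask
from vigapfill.reconstruction import (
    GapFillError,
    assemble_growth_segment,
    assemble_withering_segment,
    evaluate_fit,
)
from conftest import make_cube
from oracle_impl import normal_equations_quartic


def all_valid_mask(cube):
    mm = vg.monthly_maxima(cube)
    return ValidityMask(times=cube.times,
                        labels=np.full(cube.values.shape, LABEL_VALID, np.uint8),
                        months=mm.months,
                        month_reason=np.full(mm.maxima.shape, REASON_NONE, np.uint8))


class TestPeakDay:
    def test_single_maximum(self):
        dates = pd.date_range("2001-01-01", periods=365, freq="D")
        vals = np.zeros(365)
        vals[209] = 0.9  # day-of-year 210
        assert vg.find_peak_day(dates, vals).dayofyear == 210

    def test_tie_broken_by_earliest_date(self):
        dates = pd.date_range("2001-01-01", periods=365, freq="D")
        vals = np.zeros(365)
        vals[[149, 209]] = 0.8
        assert vg.find_peak_day(dates, vals).dayofyear == 150

    def test_empty_year_signals_unfittable(self):
        dates = pd.date_range("2001-01-01", periods=10, freq="D")
        assert vg.find_peak_day(dates, np.full(10, np.nan)) is None


class TestSegmentAssembly:
    def test_growth_time_coordinates_count_from_october(self):
        dates = pd.DatetimeIndex(["2000-11-15", "2001-03-01"])
        vals = np.array([0.3, 0.4])
        t, v, epoch = assemble_growth_segment(dates, vals, 2001,
                                              pd.Timestamp("2001-07-01"))
        assert epoch == pd.Timestamp("2000-10-01")
        np.testing.assert_array_equal(t, [45.0, 151.0])  # non-leap Feb
        np.testing.assert_array_equal(v, vals)

    def test_withering_time_coordinates_count_from_peak(self):
        peak = pd.Timestamp("2001-07-19")  # DOY 200, non-leap
        dates = pd.DatetimeIndex(["2001-10-01", "2002-02-01"])
        t, v, epoch = assemble_withering_segment(dates, np.array([0.5, 0.2]),
                                                 2001, peak)
        assert epoch == peak
        np.testing.assert_array_equal(t, [74.0, 197.0])

    def test_first_year_growth_truncated_to_current_year(self):
        dates = pd.date_range("2001-01-01", periods=60, freq="D")
        vals = np.linspace(0.1, 0.3, 60)
        t, v, _ = assemble_growth_segment(dates, vals, 2001,
                                          pd.Timestamp("2001-02-15"))
        assert t.min() == 92.0  # Jan 1 relative to Oct 1 of 2000
        assert len(t) == 46

    def test_empty_window_returns_no_points(self):
        dates = pd.date_range("2001-06-01", periods=5, freq="D")
        t, v, _ = assemble_growth_segment(dates, np.full(5, np.nan), 2001,
                                          pd.Timestamp("2001-07-01"))
        assert len(t) == 0


class TestQuarticFit:
    def test_reproduces_known_quartic_and_matches_normal_equations(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 200, 20))
        coeffs = rng.uniform(-1, 1, 5)
        v = np.polynomial.polynomial.polyval((t - 100) / 100, coeffs)
        fit = vg.fit_quartic(t, v, 2001, "growth", pd.Timestamp("2000-10-01"))
        assert fit.fitted
        x = (t - fit.t_mid) / fit.t_half
        pred = np.polynomial.polynomial.polyval(x, fit.coefficients)
        np.testing.assert_allclose(pred, v, atol=1e-8)
        np.testing.assert_allclose(pred, normal_equations_quartic(t, v), atol=1e-8)

    def test_constant_points_give_constant_polynomial(self):
        t = np.arange(20, dtype=float)
        fit = vg.fit_quartic(t, np.full(20, 0.3), 2001, "growth",
                             pd.Timestamp("2000-10-01"))
        x = np.linspace(-1, 1, 7)
        np.testing.assert_allclose(
            np.polynomial.polynomial.polyval(x, fit.coefficients), 0.3, atol=1e-12)

    def test_too_few_points_fall_back(self):
        fit = vg.fit_quartic(np.arange(4.0), np.ones(4), 2001, "growth",
                             pd.Timestamp("2000-10-01"))
        assert fit.status == "fallback"

    def test_degenerate_single_date_falls_back(self):
        fit = vg.fit_quartic(np.full(12, 5.0), np.ones(12), 2001, "growth",
                             pd.Timestamp("2000-10-01"))
        assert fit.status == "fallback"

    def test_matches_normal_equations_on_random_segments(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(10, 200)
            t = np.sort(rng.uniform(0, 400, n))
            while len(np.unique(t)) < 5:
                t = np.sort(rng.uniform(0, 400, n))
            v = rng.uniform(0, 1, n)
            fit = vg.fit_quartic(t, v, 2001, "growth", pd.Timestamp("2000-10-01"))
            x = (t - fit.t_mid) / fit.t_half
            pred = np.polynomial.polynomial.polyval(x, fit.coefficients)
            expected = normal_equations_quartic(t, v)
            np.testing.assert_allclose(pred, expected, rtol=1e-8, atol=1e-10)


class TestPixelYear:
    def test_fitted_values_clamped_to_physical_range(self):
        # a steep quartic that exceeds 1 within the year is clipped at 1
        t = np.linspace(0, 364, 30)
        v = np.linspace(-0.5, 0.5, 30)
        fit = vg.fit_quartic(t, v, 2001, "growth", pd.Timestamp("2001-01-01"))
        fit.coefficients = np.array([1.2, 0.0, 0.0, 0.0, 0.5])  # max 1.7
        days, series = vg.reconstruct_pixel_year(fit, fit, 2001,
                                                 pd.Timestamp("2001-12-31"))
        assert series.max() == pytest.approx(1.0)

    def test_fallback_growth_leaves_early_days_missing(self):
        t = np.linspace(0, 200, 30)
        wither = vg.fit_quartic(t, np.full(30, 0.4), 2001, "withering",
                                pd.Timestamp("2001-06-30"))
        growth = vg.fit_quartic(np.arange(3.0), np.ones(3), 2001, "growth",
                                pd.Timestamp("2000-10-01"))
        days, series = vg.reconstruct_pixel_year(growth, wither, 2001,
                                                 pd.Timestamp("2001-06-30"))
        peak_pos = (pd.Timestamp("2001-06-30") - pd.Timestamp("2001-01-01")).days
        assert np.isnan(series[: peak_pos + 1]).all()
        np.testing.assert_allclose(series[peak_pos + 1:], 0.4, atol=1e-9)


class TestResidualFill:
    def _cube_with_hole(self, neighbor_values):
        times = pd.date_range("2001-01-01", "2005-12-31", freq="D")
        vals = np.full((len(times), 1, 1), np.nan)
        target = pd.Timestamp("2003-06-15")
        for year, v in zip((2001, 2002, 2004, 2005), neighbor_values):
            k = (pd.Timestamp(year, 6, 15) - times[0]).days
            vals[k] = v
        vals[np.isnan(vals)] = 0.5
        vals[(target - times[0]).days] = np.nan
        return vg.DailyVICube(vg.GridSpec.toy(1, 1), times, vals), target, times

    def test_mean_of_four_neighbor_years(self):
        cube, target, times = self._cube_with_hole([0.2, 0.3, 0.4, 0.5])
        filled = vg.fill_residual_gaps(cube)
        assert filled.values[(target - times[0]).days, 0, 0] == pytest.approx(0.35)

    def test_single_available_neighbor(self):
        times = pd.date_range("2002-01-01", "2003-12-31", freq="D")
        vals = np.full((len(times), 1, 1), 0.5)
        hole = (pd.Timestamp("2002-06-15") - times[0]).days
        nb = (pd.Timestamp("2003-06-15") - times[0]).days
        vals[hole] = np.nan
        vals[nb] = 0.4
        cube = vg.DailyVICube(vg.GridSpec.toy(1, 1), times, vals)
        filled = vg.fill_residual_gaps(cube)
        assert filled.values[hole, 0, 0] == pytest.approx(0.4)

    def test_no_neighbor_is_a_hard_error(self):
        times = pd.date_range("2001-01-01", periods=365, freq="D")
        vals = np.full((len(times), 1, 1), 0.5)
        vals[100] = np.nan
        cube = vg.DailyVICube(vg.GridSpec.toy(1, 1), times, vals)
        with pytest.raises(GapFillError, match="pixel"):
            vg.fill_residual_gaps(cube)

    def test_leap_day_uses_feb_28_of_non_leap_neighbors(self):
        times = pd.date_range("2003-01-01", "2005-12-31", freq="D")
        vals = np.full((len(times), 1, 1), 0.5)
        feb29 = (pd.Timestamp("2004-02-29") - times[0]).days
        vals[feb29] = np.nan
        for year, v in ((2003, 0.2), (2005, 0.6)):
            vals[(pd.Timestamp(year, 2, 28) - times[0]).days] = v
        cube = vg.DailyVICube(vg.GridSpec.toy(1, 1), times, vals)
        filled = vg.fill_residual_gaps(cube)
        assert filled.values[feb29, 0, 0] == pytest.approx(0.4)


class TestReconstructCube:
    def test_exact_recovery_of_quartic_truth(self):
        truth = vg.simulate_quartic_truth(vg.GridSpec.toy(3, 3),
                                          range(2001, 2004), seed=5)
        recon, report = vg.reconstruct_cube(truth, all_valid_mask(truth))
        assert recon.n_missing == 0
        np.testing.assert_allclose(recon.values, truth.values, atol=1e-6)

    def test_fully_missing_middle_year_filled_from_neighbors(self):
        truth = vg.simulate_quartic_truth(vg.GridSpec.toy(1, 1),
                                          range(2001, 2004), seed=3)
        obs = truth.copy()
        year2 = obs.times.year == 2002
        obs.values[year2, 0, 0] = np.nan
        mask = all_valid_mask(obs)
        mask.labels[year2] = 0  # missing
        recon, report = vg.reconstruct_cube(obs, mask)
        assert recon.n_missing == 0
        # filled days equal the mean of the two adjacent reconstructed years
        k = (pd.Timestamp("2002-06-15") - obs.times[0]).days
        k1 = (pd.Timestamp("2001-06-15") - obs.times[0]).days
        k3 = (pd.Timestamp("2003-06-15") - obs.times[0]).days
        expected = (recon.values[k1, 0, 0] + recon.values[k3, 0, 0]) / 2
        assert recon.values[k, 0, 0] == pytest.approx(expected, abs=1e-9)

    def test_gap_free_and_deterministic_on_contaminated_scene(self, standard_pipeline):
        scene, mask, recon, report = standard_pipeline
        assert recon.n_missing == 0
        assert np.isfinite(recon.values).all()
        assert abs(recon.values).max() <= 1.0
        recon2, _ = vg.reconstruct_cube(scene.observed, mask)
        np.testing.assert_array_equal(recon.values, recon2.values)

    def test_mismatched_mask_rejected(self, standard_scene):
        mask = vg.identify_valid(standard_scene.observed)
        short = make_cube(np.full((40, 1, 1), 0.3))
        with pytest.raises(ValueError):
            vg.reconstruct_cube(short, mask)
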
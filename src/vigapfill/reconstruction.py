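"""Gap-free daily reconstruction by segmented quartic fitting.

Vegetation greenness rises and falls asymmetrically over a year, so each
pixel-year is split at the date of its maximum valid value and the two
sides are fitted separately with degree-4 polynomials:

* growth stage: valid observations from the last three months of the
  previous year (Oct-Dec) through the peak date,
* withering stage: valid observations from the day after the peak through
  the first three months of the following year (Jan-Mar).

The fitted curves replace the daily series everywhere (including
originally valid days). Segments with too few valid points, and years
with no valid data at all, are left missing and filled afterwards with
the mean reconstructed value on the same calendar day in the adjacent
four years (y-2, y-1, y+1, y+2).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .identification import LABEL_VALID, ValidityMask
from .io_grid import DailyVICube

__all__ = [
    "ReconstructionConfig",
    "SegmentFit",
    "GapFillError",
    "find_peak_day",
    "assemble_growth_segment",
    "assemble_withering_segment",
    "fit_quartic",
    "evaluate_fit",
    "reconstruct_pixel_year",
    "fill_residual_gaps",
    "reconstruct_cube",
]

log = logging.getLogger(__name__)

POLY_DEGREE = 4


class GapFillError(RuntimeError):
    """Raised when residual gaps cannot be filled from adjacent years."""


@dataclasses.dataclass(frozen=True)
class ReconstructionConfig:
    """Knobs of the reconstruction stage.

    min_points: minimum valid observations for a segment fit (a quartic
    needs 5; the default 10 guards against wild extrapolation).
    clamp_range: physical bounds applied to fitted values.
    keep_observations: if True, originally valid observations are kept and
    only invalid/missing days take fitted values (off by default: the
    fitted curve replaces everything).
    """

    min_points: int = 10
    clamp_range: tuple[float, float] = (-1.0, 1.0)
    neighbor_years: int = 4
    keep_observations: bool = False

    def __post_init__(self) -> None:
        if self.min_points < POLY_DEGREE + 1:
            raise ValueError("min_points must be at least 5 for a quartic fit")


@dataclasses.dataclass
class SegmentFit:
    """One pixel-year-stage quartic fit on an affinely rescaled time axis.

    The model is sum(coefficients[k] * x**k) with
    x = ((date - epoch).days - t_mid) / t_half, so evaluation at any
    calendar date is exact given (epoch, t_mid, t_half).
    """

    year: int
    stage: str  # "growth" | "withering"
    coefficients: np.ndarray
    epoch: pd.Timestamp
    t_mid: float
    t_half: float
    support_n: int
    status: str  # "fitted" | "fallback"

    @property
    def fitted(self) -> bool:
        return self.status == "fitted"


def find_peak_day(dates: pd.DatetimeIndex, values: np.ndarray) -> pd.Timestamp | None:
    """Date of the maximum valid value in a pixel-year; ties -> earliest date.

    Returns None when the year holds no valid data (the unfittable-year
    signal, handled by the adjacent-year fill).
    """
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if not ok.any():
        return None
    vmax = values[ok].max()
    idx = np.nonzero(ok & (values == vmax))[0][0]
    return pd.Timestamp(dates[idx])


def _segment_points(dates: pd.DatetimeIndex, values: np.ndarray,
                    start: pd.Timestamp, end: pd.Timestamp,
                    epoch: pd.Timestamp) -> tuple[np.ndarray, np.ndarray]:
    ok = np.isfinite(values) & (dates >= start) & (dates <= end)
    t = (dates[ok] - epoch).days.to_numpy(dtype=float)
    return t, np.asarray(values)[ok]


def assemble_growth_segment(dates: pd.DatetimeIndex, values: np.ndarray,
                            year: int, peak: pd.Timestamp
                            ) -> tuple[np.ndarray, np.ndarray, pd.Timestamp]:
    """Valid points from Oct 1 of year-1 through the peak.

    Returns (t, v, epoch) with t in days since Oct 1 of year-1.
    """
    epoch = pd.Timestamp(year - 1, 10, 1)
    return (*_segment_points(dates, values, epoch, peak, epoch), epoch)


def assemble_withering_segment(dates: pd.DatetimeIndex, values: np.ndarray,
                               year: int, peak: pd.Timestamp
                               ) -> tuple[np.ndarray, np.ndarray, pd.Timestamp]:
    """Valid points from the day after the peak through Mar 31 of year+1.

    Returns (t, v, epoch) with t in days since the peak date.
    """
    end = pd.Timestamp(year + 1, 3, 31)
    t, v = _segment_points(dates, values, peak + pd.Timedelta(days=1), end, peak)
    return t, v, peak


def fit_quartic(t: np.ndarray, v: np.ndarray, year: int, stage: str,
                epoch: pd.Timestamp,
                config: ReconstructionConfig | None = None) -> SegmentFit:
    """Least-squares degree-4 polynomial on a time axis rescaled to [-1, 1].

    Falls back (status="fallback") when fewer than ``min_points`` valid
    observations support the segment or the design is degenerate (fewer
    than 5 distinct dates).
    """
    config = config or ReconstructionConfig()
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    n = len(t)
    if n < config.min_points or len(np.unique(t)) < POLY_DEGREE + 1:
        return SegmentFit(year, stage, np.zeros(POLY_DEGREE + 1), epoch,
                          0.0, 1.0, n, "fallback")
    t_mid = (t.min() + t.max()) / 2.0
    t_half = (t.max() - t.min()) / 2.0
    x = (t - t_mid) / t_half
    coeffs = np.polynomial.polynomial.polyfit(x, v, POLY_DEGREE)
    if not np.all(np.isfinite(coeffs)):
        return SegmentFit(year, stage, np.zeros(POLY_DEGREE + 1), epoch,
                          0.0, 1.0, n, "fallback")
    return SegmentFit(year, stage, coeffs, epoch, t_mid, t_half, n, "fitted")


def evaluate_fit(fit: SegmentFit, dates: pd.DatetimeIndex) -> np.ndarray:
    """Evaluate a fitted segment at calendar dates (no clamping here)."""
    t = (dates - fit.epoch).days.to_numpy(dtype=float)
    x = (t - fit.t_mid) / fit.t_half
    return np.polynomial.polynomial.polyval(x, fit.coefficients)


def reconstruct_pixel_year(growth: SegmentFit, withering: SegmentFit,
                           year: int, peak: pd.Timestamp,
                           config: ReconstructionConfig | None = None
                           ) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """Daily values for one calendar year from the two segment fits.

    Days up to and including the peak come from the growth polynomial,
    later days from the withering polynomial; values are clamped to the
    physical range. Days under a fallback segment are NaN, pending the
    adjacent-year fill.
    """
    config = config or ReconstructionConfig()
    days = pd.date_range(pd.Timestamp(year, 1, 1), pd.Timestamp(year, 12, 31), freq="D")
    out = np.full(len(days), np.nan)
    before = days <= peak
    if growth.fitted and before.any():
        out[before] = evaluate_fit(growth, days[before])
    after = ~before
    if withering.fitted and after.any():
        out[after] = evaluate_fit(withering, days[after])
    lo, hi = config.clamp_range
    return days, np.clip(out, lo, hi)


def fill_residual_gaps(cube: DailyVICube, neighbor_span: int = 2) -> DailyVICube:
    """Replace each missing value by the mean same-calendar-day value of
    the adjacent four years (y-2, y-1, y+1, y+2).

    Feb 29 draws on Feb 28 in non-leap neighbor years. Only the pre-fill
    state is consulted, so the result does not depend on fill order.
    Raises :class:`GapFillError` (listing offending pixel-dates) if a gap
    has no neighbor-year value.
    """
    t0 = cube.times[0]
    span_days = (cube.times[-1] - t0).days + 1
    if len(cube.times) != span_days:
        raise ValueError("fill_residual_gaps expects a contiguous daily time axis")
    src = cube.values  # pre-fill snapshot (read-only)
    out = cube.values.copy()
    missing_t, missing_i, missing_j = np.nonzero(np.isnan(src))
    failures: list[str] = []
    for ti, ii, jj in zip(missing_t, missing_i, missing_j):
        d = cube.times[ti]
        acc, cnt = 0.0, 0
        for dy in (-2, -1, 1, 2):
            ny = d.year + dy
            month, day = d.month, d.day
            if month == 2 and day == 29 and not pd.Timestamp(ny, 1, 1).is_leap_year:
                day = 28
            nd = pd.Timestamp(ny, month, day)
            k = (nd - t0).days
            if 0 <= k < span_days:
                val = src[k, ii, jj]
                if np.isfinite(val):
                    acc += val
                    cnt += 1
        if cnt:
            out[ti, ii, jj] = acc / cnt
        else:
            failures.append(f"pixel({ii},{jj})@{d.date()}")
    if failures:
        head = ", ".join(failures[:10])
        raise GapFillError(
            f"{len(failures)} gaps have no reconstructed neighbor-year value: {head}"
            + ("..." if len(failures) > 10 else "")
        )
    return DailyVICube(cube.grid, cube.times, out, name=cube.name, validate=False)


def reconstruct_cube(cube: DailyVICube, mask: ValidityMask,
                     config: ReconstructionConfig | None = None
                     ) -> tuple[DailyVICube, dict]:
    """Full per-pixel, per-year reconstruction of a cube.

    Returns the gap-free cube (contiguous daily axis over the input's
    date range) and a report dict with fit/fallback counts, the number of
    gap-filled values and peak-discontinuity statistics.
    """
    config = config or ReconstructionConfig()
    if len(mask.times) != len(cube.times) or (mask.times != cube.times).any():
        raise ValueError("mask time axis does not match the cube")

    t0, t1 = cube.times[0], cube.times[-1]
    full_times = pd.date_range(t0, t1, freq="D")
    nlat, nlon = cube.grid.lat_count, cube.grid.lon_count
    out = np.full((len(full_times), nlat, nlon), np.nan)
    day_index = (cube.times - t0).days.to_numpy()  # position of each input date
    out_pos = {d: k for k, d in enumerate(full_times)}

    years = range(t0.year, t1.year + 1)
    n_fitted = n_fallback = 0
    discontinuities: list[float] = []

    valid3d = (mask.labels == LABEL_VALID) & np.isfinite(cube.values)
    for ii in range(nlat):
        for jj in range(nlon):
            vals = np.where(valid3d[:, ii, jj], cube.values[:, ii, jj], np.nan)
            year_arr = cube.times.year
            for year in years:
                in_year = year_arr == year
                peak = find_peak_day(cube.times[in_year], vals[in_year])
                if peak is None:
                    n_fallback += 2
                    continue
                tg, vg, eg = assemble_growth_segment(cube.times, vals, year, peak)
                tw, vw, ew = assemble_withering_segment(cube.times, vals, year, peak)
                fg = fit_quartic(tg, vg, year, "growth", eg, config)
                fw = fit_quartic(tw, vw, year, "withering", ew, config)
                n_fitted += fg.fitted + fw.fitted
                n_fallback += (not fg.fitted) + (not fw.fitted)
                if fg.fitted and fw.fitted:
                    gap = float(abs(evaluate_fit(fg, pd.DatetimeIndex([peak]))[0]
                                    - evaluate_fit(fw, pd.DatetimeIndex([peak]))[0]))
                    discontinuities.append(gap)
                days, series = reconstruct_pixel_year(fg, fw, year, peak, config)
                keep = (days >= t0) & (days <= t1)
                pos = np.array([out_pos[d] for d in days[keep]])
                out[pos, ii, jj] = series[keep]
            if config.keep_observations:
                obs_ok = valid3d[:, ii, jj]
                out[day_index[obs_ok], ii, jj] = cube.values[obs_ok, ii, jj]

    partial = DailyVICube(cube.grid, full_times, out, name=cube.name, validate=False)
    n_gaps = partial.n_missing
    filled = fill_residual_gaps(partial)
    report = {
        "n_segments_fitted": int(n_fitted),
        "n_segments_fallback": int(n_fallback),
        "n_gap_filled_values": int(n_gaps),
        "peak_discontinuity_mean": float(np.mean(discontinuities)) if discontinuities else 0.0,
        "peak_discontinuity_max": float(np.max(discontinuities)) if discontinuities else 0.0,
    }
    log.info("reconstruction: %s", report)
    return filled, report
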
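"""Valid-data identification for daily VI cubes.

Two screening stages, applied per pixel:

Stage 1 (day level). A three-month sliding window (the fundamental
processing unit, FPU) is centered on each target month. From the monthly
maxima of the previous, target and next months, a reference set ``V_max``
of up to five numbers is formed: the three maxima plus the means of
(previous, target) and (target, next). A day is *valid* when its percent
bias against at least one reference is within the threshold ``T1``
(default 20%); otherwise it is *invalid*.

Stage 2 (month level). A target month is invalidated wholesale when it
contains no data at all, or when the percent bias between its monthly
maximum and the mean monthly maximum of the same calendar month in the
adjacent four years (y-2, y-1, y+1, y+2) exceeds ``T2`` (default 39%).

The thresholds were originally calibrated from a long monthly-maximum
reference record: T1 as the average |PB| between adjacent months (~20%),
T2 as the average per-pixel maximum of those |PB| values (~39%).
``calibrate_thresholds`` reproduces that procedure on any monthly-maximum
series.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .io_grid import DailyVICube

__all__ = [
    "IdentificationConfig",
    "MonthlyMaxSeries",
    "ValidityMask",
    "LABEL_MISSING",
    "LABEL_VALID",
    "LABEL_INVALID",
    "REASON_NONE",
    "REASON_NO_DATA",
    "REASON_INTERANNUAL",
    "monthly_maxima",
    "build_fpu_references",
    "day_validity",
    "month_validity",
    "identify_valid",
    "calibrate_thresholds",
]

log = logging.getLogger(__name__)

LABEL_MISSING = np.uint8(0)
LABEL_VALID = np.uint8(1)
LABEL_INVALID = np.uint8(2)

REASON_NONE = np.uint8(0)
REASON_NO_DATA = np.uint8(1)
REASON_INTERANNUAL = np.uint8(2)


@dataclasses.dataclass(frozen=True)
class IdentificationConfig:
    """Thresholds and window sizes of the two screening stages.

    t1, t2 are percent-bias thresholds (percent units). ``fpu_months`` is
    fixed at 3 and ``neighbor_years`` at 4 (two before, two after); they
    are recorded for provenance. ``require_all_refs`` switches stage 1
    from the default "at least one reference within T1" reading to the
    stricter "all references within T1".
    """

    t1: float = 20.0
    t2: float = 39.0
    fpu_months: int = 3
    neighbor_years: int = 4
    require_all_refs: bool = False

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("thresholds must be positive percentages")
        if self.fpu_months != 3:
            raise ValueError("the sliding window is fixed at three months")


@dataclasses.dataclass
class MonthlyMaxSeries:
    """Per-pixel monthly maxima: (n_months, lat, lon), NaN where a month has no data."""

    months: pd.PeriodIndex  # consecutive calendar months
    maxima: np.ndarray

    def __post_init__(self) -> None:
        if self.maxima.shape[0] != len(self.months):
            raise ValueError("maxima first axis must match months")


@dataclasses.dataclass
class ValidityMask:
    """Day labels (0=missing, 1=valid, 2=invalid) plus month-level flags."""

    times: pd.DatetimeIndex
    labels: np.ndarray  # (time, lat, lon) uint8
    months: pd.PeriodIndex
    month_reason: np.ndarray  # (n_months, lat, lon) uint8

    def month_invalid(self) -> np.ndarray:
        return self.month_reason != REASON_NONE

    @property
    def valid_fraction(self) -> float:
        observed = self.labels != LABEL_MISSING
        n = int(observed.sum())
        return float((self.labels == LABEL_VALID).sum() / n) if n else 0.0

    def to_dataset(self, grid) -> "object":
        """Serialize as byte variables on the cube grid (0=missing, 1=valid, 2=invalid)."""
        import xarray as xr

        return xr.Dataset(
            {
                "label": (("time", "lat", "lon"), self.labels),
                "month_reason": (("month", "lat", "lon"), self.month_reason),
            },
            coords={"time": self.times,
                    "month": self.months.to_timestamp(),
                    "lat": grid.lat_centers(), "lon": grid.lon_centers()},
        )


def write_mask(mask: ValidityMask, grid, path) -> None:
    from .io_grid import _preferred_engine

    mask.to_dataset(grid).to_netcdf(path, engine=_preferred_engine())


def read_mask(path) -> ValidityMask:
    import xarray as xr

    from .io_grid import _preferred_engine

    with xr.open_dataset(path, engine=_preferred_engine()) as ds:
        ds = ds.load()
    return ValidityMask(
        times=pd.DatetimeIndex(ds["time"].values),
        labels=ds["label"].values.astype(np.uint8),
        months=pd.DatetimeIndex(ds["month"].values).to_period("M"),
        month_reason=ds["month_reason"].values.astype(np.uint8),
    )


def monthly_maxima(cube: DailyVICube) -> MonthlyMaxSeries:
    """Maximum over non-missing daily values per pixel and calendar month.

    The month axis runs consecutively from the first to the last month in
    the cube's span; months with no data (including months absent from a
    gappy input time axis) carry NaN.
    """
    periods = cube.times.to_period("M")
    months = pd.period_range(periods[0], periods[-1], freq="M")
    shape = (len(months), cube.grid.lat_count, cube.grid.lon_count)
    out = np.full(shape, np.nan)
    codes = months.get_indexer(periods)
    neg_inf = np.float64(-np.inf)
    for m in range(len(months)):
        sel = codes == m
        if sel.any():
            block = np.where(np.isfinite(cube.values[sel]), cube.values[sel], neg_inf)
            mx = block.max(axis=0)
            out[m] = np.where(np.isfinite(mx), mx, np.nan)
    return MonthlyMaxSeries(months=months, maxima=out)


def build_fpu_references(prev_max: float | None, target_max: float | None,
                         next_max: float | None) -> list[float]:
    """Reference set V_max for one target month.

    Full windows give five numbers: the three monthly maxima and the means
    of (previous, target) and (target, next). Members whose inputs are
    absent (record edges, empty neighbor months) are omitted.
    """
    def ok(x):
        return x is not None and np.isfinite(x)

    if not (ok(prev_max) or ok(target_max) or ok(next_max)):
        raise ValueError("cannot build references: all three monthly maxima absent")
    refs: list[float] = []
    if ok(prev_max):
        refs.append(float(prev_max))
    if ok(target_max):
        refs.append(float(target_max))
    if ok(next_max):
        refs.append(float(next_max))
    if ok(prev_max) and ok(target_max):
        refs.append((float(prev_max) + float(target_max)) / 2.0)
    if ok(target_max) and ok(next_max):
        refs.append((float(target_max) + float(next_max)) / 2.0)
    return refs


def day_validity(value: float, refs: list[float], t1: float = 20.0,
                 require_all: bool = False) -> bool:
    """Stage-1 screen for a single daily value against its V_max references.

    Zero-valued references make the percent bias undefined and are
    skipped; if every reference is zero the day is invalid (logged).
    """
    usable = [r for r in refs if r != 0.0]
    if not usable:
        log.warning("all V_max references are zero; day classified invalid")
        return False
    pb = [abs((value - r) / r) * 100.0 for r in usable]
    return max(pb) <= t1 if require_all else min(pb) <= t1


def month_validity(target_max: float | None,
                   neighbor_year_maxima: list[float],
                   t2: float = 39.0) -> tuple[bool, int]:
    """Stage-2 screen for one pixel-month.

    Returns ``(invalid, reason)`` with reason in {REASON_NONE,
    REASON_NO_DATA, REASON_INTERANNUAL}. The interannual test compares the
    target month's maximum with the mean of the same calendar month's
    maxima over the adjacent four years; with no neighbors it is skipped.
    """
    if target_max is None or not np.isfinite(target_max):
        return True, int(REASON_NO_DATA)
    neigh = [x for x in neighbor_year_maxima if x is not None and np.isfinite(x)]
    if not neigh:
        return False, int(REASON_NONE)
    ref = float(np.mean(neigh))
    if ref == 0.0:
        return False, int(REASON_NONE)
    pb = abs((target_max - ref) / ref) * 100.0
    if pb > t2:
        return True, int(REASON_INTERANNUAL)
    return False, int(REASON_NONE)


def _stack_references(mm: MonthlyMaxSeries) -> np.ndarray:
    """V_max as a (5, n_months, lat, lon) array; NaN marks absent members."""
    m = mm.maxima
    prev = np.full_like(m, np.nan)
    nxt = np.full_like(m, np.nan)
    prev[1:] = m[:-1]
    nxt[:-1] = m[1:]
    with np.errstate(invalid="ignore"):
        mean_pt = (prev + m) / 2.0  # NaN if either absent
        mean_tn = (m + nxt) / 2.0
    return np.stack([prev, m, nxt, mean_pt, mean_tn])


def _month_flags(mm: MonthlyMaxSeries, t2: float) -> np.ndarray:
    """Stage-2 reason codes per (month, pixel)."""
    months = mm.months
    m = mm.maxima
    reason = np.zeros(m.shape, dtype=np.uint8)
    reason[np.isnan(m)] = REASON_NO_DATA

    years = np.array([p.year for p in months])
    cal_month = np.array([p.month for p in months])
    for i, p in enumerate(months):
        neigh_idx = []
        for dy in (-2, -1, 1, 2):
            j = np.nonzero((years == p.year + dy) & (cal_month == p.month))[0]
            neigh_idx.extend(j.tolist())
        if not neigh_idx:
            continue
        neigh = m[neigh_idx]  # (k, lat, lon)
        finite = np.isfinite(neigh)
        cnt = finite.sum(axis=0)
        with np.errstate(all="ignore"):
            ref = np.where(finite, neigh, 0.0).sum(axis=0) / cnt
            pb = np.abs((m[i] - ref) / ref) * 100.0
        exceed = np.isfinite(pb) & (ref != 0) & (pb > t2) & (reason[i] == REASON_NONE)
        reason[i][exceed] = REASON_INTERANNUAL
    return reason


def identify_valid(cube: DailyVICube,
                   config: IdentificationConfig | None = None) -> ValidityMask:
    """Run both screening stages over a cube.

    Stage 1 labels each non-missing day valid/invalid against its month's
    V_max references; stage 2 month flags then override every non-missing
    day of a flagged month to invalid. Missing days stay labeled missing.

    Stage-2 maxima are the raw monthly maxima. This is equivalent to
    using stage-1 survivors: a month's maximum day always survives stage
    1, since its percent bias against the target-month-max reference
    (itself) is zero.
    """
    config = config or IdentificationConfig()
    mm = monthly_maxima(cube)
    refs = _stack_references(mm)  # (5, n_months, lat, lon)

    month_of_day = mm.months.get_indexer(cube.times.to_period("M"))
    labels = np.full(cube.values.shape, LABEL_MISSING, dtype=np.uint8)
    observed = np.isfinite(cube.values)

    day_refs = refs[:, month_of_day]            # (5, time, lat, lon)
    with np.errstate(all="ignore"):
        pb = np.abs((cube.values[None] - day_refs) / day_refs) * 100.0
    pb[day_refs == 0] = np.nan                  # zero references skipped
    usable = np.isfinite(pb)
    if config.require_all_refs:
        crit = np.max(np.where(usable, pb, -np.inf), axis=0)
    else:
        crit = np.min(np.where(usable, pb, np.inf), axis=0)
    ok = usable.any(axis=0) & (crit <= config.t1)

    labels[observed] = np.where(ok[observed], LABEL_VALID, LABEL_INVALID)

    reason = _month_flags(mm, config.t2)
    month_bad = (reason != REASON_NONE)[month_of_day]  # (time, lat, lon)
    labels[observed & month_bad] = LABEL_INVALID

    n_barren = int((observed & ~usable.any(axis=0)).sum())
    if n_barren:
        log.warning("%d observed days had only zero-valued references; "
                    "classified invalid", n_barren)
    return ValidityMask(times=cube.times, labels=labels,
                        months=mm.months, month_reason=reason)


def calibrate_thresholds(reference: MonthlyMaxSeries) -> tuple[float, float]:
    """Estimate (T1, T2) from a multi-year monthly-maximum reference record.

    T1 = mean over pixels and consecutive-month pairs of the |PB| between
    adjacent monthly maxima; T2 = mean over pixels of each pixel's maximum
    pairwise |PB|. Pairs with a zero or absent earlier month are skipped.
    """
    m = reference.maxima
    if m.shape[0] < 2:
        raise ValueError("need at least two consecutive months")
    with np.errstate(all="ignore"):
        pb = np.abs((m[1:] - m[:-1]) / m[:-1]) * 100.0
    pb[~np.isfinite(pb)] = np.nan
    if not np.isfinite(pb).any():
        raise ValueError("no usable adjacent-month pairs (all absent or zero)")
    with np.errstate(all="ignore"):
        t1 = float(np.nanmean(pb))
        per_pixel_max = np.nanmax(pb, axis=0)
        t2 = float(np.nanmean(per_pixel_max))
    return t1, t2
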
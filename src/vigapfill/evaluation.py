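"""Validation metrics and dataset inter-comparison utilities.

Five criteria evaluate a reconstruction against a comparison series:
Pearson correlation r, coefficient of determination
R^2 = 1 - SSres/SStot (asymmetric: the observation series defines SStot),
mean absolute error, root-mean-square error, and percent bias
PB = mean((rec - ref)/ref) * 100.

Two quality rules classify per-pixel metric maps:
* "self"  (reconstruction vs original valid data): |PB| < 1% and
  RMSE < 0.08 and R^2 > 0.5,
* "modis" (vs an independent daily gap-filled product): r > 0.5 and
  |PB| < 50% and RMSE < 0.2.

Monthly maximum-value compositing (MVC) and nearest-neighbour regridding
support comparisons against coarser or differently gridded products.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .identification import LABEL_VALID, ValidityMask, monthly_maxima
from .io_grid import DailyVICube, GridSpec

__all__ = [
    "MetricSet",
    "QualityRule",
    "RULES",
    "percent_bias",
    "pearson_r",
    "r_squared",
    "mae",
    "rmse",
    "pixelwise_metrics",
    "quality_classification",
    "latitudinal_profile",
    "mvc_monthly_composite",
    "regrid_nearest",
]


@dataclasses.dataclass
class MetricSet:
    r: float
    r2: float
    mae: float
    rmse: float
    pb: float
    n: int


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    return a[ok], b[ok]


def percent_bias(rec, ref) -> float:
    """Mean of (rec-ref)/ref over pairs, as a percentage.

    Pairs with a zero reference have undefined relative bias and are
    skipped; an empty result after skipping is an error.
    """
    rec, ref = _pair(rec, ref)
    nz = ref != 0
    if not nz.any():
        raise ValueError("no usable pairs: every reference value is zero or missing")
    return float(np.mean((rec[nz] - ref[nz]) / ref[nz]) * 100.0)


def pearson_r(a, b) -> float:
    a, b = _pair(a, b)
    if len(a) < 2:
        raise ValueError("need at least two pairs for a correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(np.corrcoef(a, b)[0, 1])


def r_squared(rec, obs) -> float:
    """1 - SSres/SStot with SStot about the observed mean (asymmetric)."""
    rec, obs = _pair(rec, obs)
    if len(obs) < 2:
        raise ValueError("need at least two pairs")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for a constant observation series")
    ss_res = float(np.sum((obs - rec) ** 2))
    return 1.0 - ss_res / ss_tot


def mae(a, b) -> float:
    a, b = _pair(a, b)
    return float(np.mean(np.abs(a - b)))


def rmse(a, b) -> float:
    a, b = _pair(a, b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclasses.dataclass(frozen=True)
class QualityRule:
    """Pure predicate on a per-pixel MetricSet."""

    name: str
    max_abs_pb: float | None = None
    max_rmse: float | None = None
    min_r2: float | None = None
    min_r: float | None = None

    def __call__(self, m: MetricSet) -> bool:
        ok = True
        if self.max_abs_pb is not None:
            ok &= abs(m.pb) < self.max_abs_pb
        if self.max_rmse is not None:
            ok &= m.rmse < self.max_rmse
        if self.min_r2 is not None:
            ok &= m.r2 > self.min_r2
        if self.min_r is not None:
            ok &= m.r > self.min_r
        return bool(ok)


RULES: dict[str, QualityRule] = {
    "self": QualityRule("self", max_abs_pb=1.0, max_rmse=0.08, min_r2=0.5),
    "modis": QualityRule("modis", min_r=0.5, max_abs_pb=50.0, max_rmse=0.2),
}


def pixelwise_metrics(recon: DailyVICube, reference: DailyVICube,
                      mask: ValidityMask | None = None,
                      min_n: int = 2) -> dict[str, np.ndarray]:
    """Per-pixel MetricSet maps between two aligned cubes.

    With a validity mask (self-validation mode) only days labeled valid
    enter the comparison; without one, all co-observed days do. Returns
    2-D arrays "r", "r2", "mae", "rmse", "pb", "n" plus a boolean
    "insufficient" flag for pixels with fewer than ``min_n`` usable pairs
    (their metric cells are NaN).
    """
    if recon.values.shape != reference.values.shape:
        raise ValueError("cube shapes differ; align grids and date ranges first")
    if (recon.times != reference.times).any():
        raise ValueError("cube time axes differ")
    a = recon.values
    b = reference.values
    ok = np.isfinite(a) & np.isfinite(b)
    if mask is not None:
        ok &= mask.labels == LABEL_VALID
    a = np.where(ok, a, np.nan)
    b = np.where(ok, b, np.nan)

    n = ok.sum(axis=0).astype(float)
    shape = n.shape
    with np.errstate(all="ignore"):
        am = np.nansum(a, axis=0) / n
        bm = np.nansum(b, axis=0) / n
        da = a - am
        db = b - bm
        cov = np.nansum(da * db, axis=0)
        va = np.nansum(da * da, axis=0)
        vb = np.nansum(db * db, axis=0)
        r = cov / np.sqrt(va * vb)
        r2 = 1.0 - np.nansum((b - a) ** 2, axis=0) / vb
        mae_map = np.nansum(np.abs(a - b), axis=0) / n
        rmse_map = np.sqrt(np.nansum((a - b) ** 2, axis=0) / n)
        ratio = np.where(b != 0, (a - b) / b, np.nan)
        n_pb = np.isfinite(ratio).sum(axis=0).astype(float)
        pb = np.nansum(ratio, axis=0) / n_pb * 100.0

    insufficient = n < min_n
    for arr in (r, r2, mae_map, rmse_map, pb):
        arr[insufficient] = np.nan
    return {"r": r, "r2": r2, "mae": mae_map, "rmse": rmse_map, "pb": pb,
            "n": n.astype(int).reshape(shape), "insufficient": insufficient}


def quality_classification(metrics: dict[str, np.ndarray],
                           rule: QualityRule | str = "self"
                           ) -> tuple[np.ndarray, float]:
    """Apply a quality rule per pixel; proportion is over non-flagged pixels.

    Area proportions are pixel counts on the regular grid (no latitude
    weighting).
    """
    if isinstance(rule, str):
        rule = RULES[rule]
    ok = np.ones(metrics["rmse"].shape, dtype=bool)
    if rule.max_abs_pb is not None:
        ok &= np.abs(metrics["pb"]) < rule.max_abs_pb
    if rule.max_rmse is not None:
        ok &= metrics["rmse"] < rule.max_rmse
    if rule.min_r2 is not None:
        ok &= metrics["r2"] > rule.min_r2
    if rule.min_r is not None:
        ok &= metrics["r"] > rule.min_r
    usable = ~metrics["insufficient"]
    ok &= usable
    prop = float(ok.sum() / usable.sum()) if usable.any() else float("nan")
    return ok, prop


def latitudinal_profile(field: np.ndarray, grid: GridSpec) -> pd.DataFrame:
    """Row-wise mean and standard deviation of a per-pixel map.

    Latitude bands are the grid rows themselves. NaN cells (flagged
    pixels) are excluded per band.
    """
    field = np.asarray(field, dtype=float)
    ok = np.isfinite(field)
    n = ok.sum(axis=1)
    with np.errstate(all="ignore"):
        means = np.where(ok, field, 0.0).sum(axis=1) / n
        var = np.where(ok, (field - means[:, None]) ** 2, 0.0).sum(axis=1) / n
        stds = np.sqrt(var)
    return pd.DataFrame({"lat": grid.lat_centers(), "mean": means, "std": stds})


def mvc_monthly_composite(cube: DailyVICube):
    """Monthly maximum-value composite of a daily cube.

    Returns an xarray.DataArray with a monthly (period start) time axis;
    months with no data carry NaN.
    """
    import xarray as xr

    mm = monthly_maxima(cube)
    return xr.DataArray(
        mm.maxima,
        dims=("month", "lat", "lon"),
        coords={"month": mm.months.to_timestamp(),
                "lat": cube.grid.lat_centers(),
                "lon": cube.grid.lon_centers()},
        name=cube.name,
    )


def _nearest_indices(src_centers: np.ndarray, tgt_centers: np.ndarray) -> np.ndarray:
    """Index of the nearest source center per target center; ties -> smaller index."""
    pos = np.searchsorted(src_centers, tgt_centers)
    pos = np.clip(pos, 1, len(src_centers) - 1) if len(src_centers) > 1 else np.zeros_like(pos)
    if len(src_centers) == 1:
        return np.zeros(len(tgt_centers), dtype=int)
    left = src_centers[pos - 1]
    right = src_centers[pos]
    choose_right = (tgt_centers - left) > (right - tgt_centers)  # tie -> left (smaller index)
    return pos - 1 + choose_right.astype(int)


def regrid_nearest(cube: DailyVICube, target: GridSpec) -> DailyVICube:
    """Nearest-neighbour assignment of a cube onto a target grid.

    Each target cell takes the value of the source cell whose center is
    nearest its own center (separable per axis on regular grids); exact
    ties go to the smaller index.
    """
    if (target.lat_min >= cube.grid.lat_max or target.lat_max <= cube.grid.lat_min or
            target.lon_min >= cube.grid.lon_max or target.lon_max <= cube.grid.lon_min):
        raise ValueError("target grid does not overlap the source grid")
    li = _nearest_indices(cube.grid.lat_centers(), target.lat_centers())
    lj = _nearest_indices(cube.grid.lon_centers(), target.lon_centers())
    values = cube.values[:, li][:, :, lj]
    return DailyVICube(target, cube.times, values, name=cube.name, validate=False)
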
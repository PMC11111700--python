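"""Grid definition and NetCDF I/O for daily vegetation-index cubes.

The central object is :class:`DailyVICube`: daily NDVI-like values on a
regular latitude/longitude grid, carried in memory as unpacked floats in
[-1, 1] with NaN for missing, and stored on disk as 16-bit packed integers
with a 0.001 scale factor (the CDR convention).

Conventions
-----------
* latitude is stored south -> north ascending; files with descending
  latitude are flipped on read,
* cell-center registration; published extents are outer cell edges,
* time is a true calendar axis (CF "days since" on disk), so leap days
  are real samples.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "GridSpec",
    "DailyVICube",
    "product_filename",
    "read_daily_cube",
    "write_daily_cube",
    "write_yearly_cubes",
    "CubeFormatError",
    "CubeValidationError",
]

SCALE_FACTOR = 0.001
FILL_SENTINEL = -32768
PRODUCT_TEMPLATE = "Daily_Gap-filled_NDVI_{year:04d}.nc4"

#: published study extent (outer cell edges), 0.05 degree cells
CHINA_EXTENT = (18.16, 53.56, 73.44, 135.09)


class CubeFormatError(ValueError):
    """File does not follow the expected (time, lat, lon) layout."""


class CubeValidationError(ValueError):
    """Cube contents violate an invariant (range, time ordering, ...)."""


def _preferred_engine() -> str:
    try:  # a true NetCDF-4 writer when available
        import netCDF4  # noqa: F401

        return "netcdf4"
    except ImportError:
        return "scipy"


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid, cell-center registered.

    ``lat_min``/``lat_max``/``lon_min``/``lon_max`` are outer cell edges;
    the first center sits half a cell inside the edge.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    cell_size: float = 0.05
    lat_count: int = dataclasses.field(default=0)
    lon_count: int = dataclasses.field(default=0)

    def __post_init__(self) -> None:
        if self.lat_count == 0:
            object.__setattr__(
                self, "lat_count", int(round((self.lat_max - self.lat_min) / self.cell_size))
            )
        if self.lon_count == 0:
            object.__setattr__(
                self, "lon_count", int(round((self.lon_max - self.lon_min) / self.cell_size))
            )
        tol = 0.5 * self.cell_size
        if abs(self.lat_count * self.cell_size - (self.lat_max - self.lat_min)) > tol:
            raise CubeValidationError("lat_count inconsistent with extent/cell_size")
        if abs(self.lon_count * self.cell_size - (self.lon_max - self.lon_min)) > tol:
            raise CubeValidationError("lon_count inconsistent with extent/cell_size")
        if self.lat_count <= 0 or self.lon_count <= 0:
            raise CubeValidationError("grid must contain at least one cell")

    @classmethod
    def china(cls, cell_size: float = 0.05) -> "GridSpec":
        """The published national grid: 18.16-53.56N, 73.44-135.09E at 0.05 deg."""
        lat_min, lat_max, lon_min, lon_max = CHINA_EXTENT
        return cls(lat_min, lat_max, lon_min, lon_max, cell_size)

    @classmethod
    def toy(cls, lat_count: int = 4, lon_count: int = 4, cell_size: float = 0.05,
            lat_min: float = 30.0, lon_min: float = 100.0) -> "GridSpec":
        return cls(lat_min, lat_min + lat_count * cell_size,
                   lon_min, lon_min + lon_count * cell_size, cell_size)

    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, south -> north ascending."""
        return self.lat_min + self.cell_size * (np.arange(self.lat_count) + 0.5)

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + self.cell_size * (np.arange(self.lon_count) + 0.5)

    @classmethod
    def from_centers(cls, lat: np.ndarray, lon: np.ndarray) -> "GridSpec":
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        if lat.size > 1:
            cell = float(np.median(np.diff(lat)))
        elif lon.size > 1:
            cell = float(np.median(np.diff(lon)))
        else:
            cell = 0.05
        cell = abs(cell)
        return cls(float(lat.min()) - cell / 2, float(lat.max()) + cell / 2,
                   float(lon.min()) - cell / 2, float(lon.max()) + cell / 2, cell)


class DailyVICube:
    """Daily VI values on a grid: shape (time, lat, lon), NaN = missing."""

    def __init__(self, grid: GridSpec, times: pd.DatetimeIndex, values: np.ndarray,
                 name: str = "NDVI", validate: bool = True):
        times = pd.DatetimeIndex(times)
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (len(times), grid.lat_count, grid.lon_count):
            raise CubeValidationError(
                f"values shape {values.shape} does not match "
                f"({len(times)}, {grid.lat_count}, {grid.lon_count})"
            )
        self.grid = grid
        self.times = times
        self.values = values
        self.name = name
        if validate:
            self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if len(self.times) == 0:
            raise CubeValidationError("empty time axis")
        diffs = np.diff(self.times.values)
        if len(diffs) and not (diffs > np.timedelta64(0, "ns")).all():
            raise CubeValidationError("time axis must be strictly increasing with no duplicates")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1.0 - 1e-9 or finite.max() > 1.0 + 1e-9):
            raise CubeValidationError("values outside the physical range [-1, 1]")

    # -- convenience -----------------------------------------------------
    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def copy(self) -> "DailyVICube":
        return DailyVICube(self.grid, self.times, self.values.copy(),
                           name=self.name, validate=False)

    def sel_year(self, year: int) -> "DailyVICube":
        keep = self.times.year == year
        return DailyVICube(self.grid, self.times[keep], self.values[keep],
                           name=self.name, validate=False)

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {self.name: (("time", "lat", "lon"), self.values)},
            coords={
                "time": self.times,
                "lat": self.grid.lat_centers(),
                "lon": self.grid.lon_centers(),
            },
        )

    @classmethod
    def from_dataarray(cls, da: xr.DataArray, name: str = "NDVI") -> "DailyVICube":
        da = da.transpose("time", "lat", "lon")
        lat = da["lat"].values
        if lat.size > 1 and lat[0] > lat[-1]:  # normalize to ascending
            da = da.isel(lat=slice(None, None, -1))
            lat = da["lat"].values
        grid = GridSpec.from_centers(lat, da["lon"].values)
        times = pd.DatetimeIndex(da["time"].values)
        return cls(grid, times, da.values.astype(np.float64), name=name)


def product_filename(year: int) -> str:
    """Render the published per-year file name, e.g. Daily_Gap-filled_NDVI_2000.nc4."""
    name = PRODUCT_TEMPLATE.format(year=int(year))
    if not re.fullmatch(r"Daily_Gap-filled_NDVI_\d{4}\.nc4", name):
        raise ValueError(f"year {year} does not render a 4-digit file name")
    return name


def read_daily_cube(path: str | Path, variable: str = "NDVI") -> DailyVICube:
    """Read a daily cube, unpacking scale/offset and mapping sentinels to NaN."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with xr.open_dataset(path, engine=_preferred_engine(), mask_and_scale=True) as ds:
        if variable not in ds:
            raise CubeFormatError(f"variable {variable!r} not found in {path.name}; "
                                  f"available: {list(ds.data_vars)}")
        da = ds[variable].load()
    missing = {"time", "lat", "lon"} - set(da.dims)
    if missing:
        raise CubeFormatError(f"variable {variable!r} lacks dims {sorted(missing)}")
    times = pd.DatetimeIndex(da["time"].values)
    if times.has_duplicates or not times.is_monotonic_increasing:
        raise CubeValidationError(f"non-monotonic or duplicated time axis in {path.name}")
    return DailyVICube.from_dataarray(da, name=variable)


def write_daily_cube(cube: DailyVICube, path: str | Path, packed: bool = True) -> Path:
    """Write a cube to NetCDF; packed=True stores int16 * 0.001 with a -32768 sentinel."""
    cube.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds = cube.to_dataset()
    ds[cube.name].attrs["units"] = "1"
    encoding: dict = {"time": {"units": f"days since {cube.times[0].date()}",
                               "dtype": "int32"}}
    if packed:
        encoding[cube.name] = {
            "dtype": "int16",
            "scale_factor": SCALE_FACTOR,
            "_FillValue": FILL_SENTINEL,
        }
    else:
        encoding[cube.name] = {"dtype": "float32", "_FillValue": np.float32(np.nan)}
    ds.to_netcdf(path, engine=_preferred_engine(), encoding=encoding)
    return path


def write_yearly_cubes(cube: DailyVICube, out_dir: str | Path, packed: bool = True) -> list[Path]:
    """Split a cube by calendar year and write one product-named file per year."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for year in sorted(set(cube.times.year)):
        sub = cube.sel_year(int(year))
        paths.append(write_daily_cube(sub, out_dir / product_filename(int(year)), packed=packed))
    return paths
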
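"""Survey and environmental-field ingestion.

Reads larval tow records and gridded environmental covariates, computes
larval densities C = N / V (individuals per (10 m)^3 of filtered water),
bins stations to 0.25-degree grid cells, composites environmental fields
month by month, and pairs each occupied cell with its SST / SSS / Chl-a
values so downstream modules can fit suitability curves.

Conventions
-----------
* Grid cells are half-open boxes indexed ``(i, j)`` with ``i`` along
  longitude and ``j`` along latitude, lower-left origin, 0-based.
* 2-D arrays are stored ``(n_lat, n_lon)`` (row = latitude), the usual
  NetCDF layout, and indexed ``values[j, i]``.
* ``mask`` arrays are boolean with ``True`` = valid observation.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .errors import (
    GridMismatchError,
    InputError,
    InvalidCountError,
    InvalidVolumeError,
    MissingFieldError,
    OutOfDomainError,
)

#: Environmental covariates handled by the pipeline, in canonical order.
VARIABLES: tuple[str, str, str] = ("sst", "sss", "chla")

#: CF-style units for each covariate (salinity is practical, dimensionless).
UNITS: Mapping[str, str] = {"sst": "degC", "sss": "1", "chla": "mg m-3"}

#: Calendar months surveyed in the source study (April and June-September).
SURVEY_MONTHS: tuple[int, ...] = (4, 6, 7, 8, 9)

#: Values at or below this are treated as fill/sentinel values in satellite
#: products (common conventions use -9999 or large negative fills).
SENTINEL_MIN: float = -9000.0

SURVEY_CSV_COLUMNS = ("station_id", "lon", "lat", "year", "month", "count", "volume")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid of half-open square cells.

    Cell ``(i, j)`` covers ``[lon_origin + i*cs, lon_origin + (i+1)*cs) x
    [lat_origin + j*cs, lat_origin + (j+1)*cs)``.
    """

    lon_origin: float
    lat_origin: float
    cell_size: float = 0.25
    n_lon: int = 8
    n_lat: int = 8

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_lon < 1 or self.n_lat < 1:
            raise ValueError("grid must have at least one cell per axis")

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(n_lat, n_lon)`` for fields on this grid."""
        return (self.n_lat, self.n_lon)

    @property
    def lon_max(self) -> float:
        return self.lon_origin + self.n_lon * self.cell_size

    @property
    def lat_max(self) -> float:
        return self.lat_origin + self.n_lat * self.cell_size

    def lon_centers(self) -> np.ndarray:
        return self.lon_origin + (np.arange(self.n_lon) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        return self.lat_origin + (np.arange(self.n_lat) + 0.5) * self.cell_size

    def contains(self, lon: float, lat: float) -> bool:
        return (
            self.lon_origin <= lon < self.lon_max
            and self.lat_origin <= lat < self.lat_max
        )

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Index of the unique half-open cell containing ``(lon, lat)``."""
        if not self.contains(lon, lat):
            raise OutOfDomainError(
                f"point ({lon}, {lat}) outside grid "
                f"[{self.lon_origin}, {self.lon_max}) x "
                f"[{self.lat_origin}, {self.lat_max})"
            )
        i = int(math.floor((lon - self.lon_origin) / self.cell_size))
        j = int(math.floor((lat - self.lat_origin) / self.cell_size))
        # guard against float round-off at the upper edges
        return (min(i, self.n_lon - 1), min(j, self.n_lat - 1))

    def cell_bounds(self, i: int, j: int) -> tuple[float, float, float, float]:
        """(lon_lo, lon_hi, lat_lo, lat_hi) of cell (i, j)."""
        cs = self.cell_size
        return (
            self.lon_origin + i * cs,
            self.lon_origin + (i + 1) * cs,
            self.lat_origin + j * cs,
            self.lat_origin + (j + 1) * cs,
        )


@dataclass
class SurveyRecord:
    """One net tow: where, when, how many larvae, how much water filtered."""

    station_id: str
    lon: float
    lat: float
    year: int
    month: int
    count: int
    volume: float
    density: float = field(init=False)

    def __post_init__(self) -> None:
        if not 1 <= int(self.month) <= 12:
            raise ValueError(f"month {self.month} not in 1..12")
        self.density = compute_density(self.count, self.volume)


@dataclass
class EnvField:
    """One environmental variable on a regular grid for one month."""

    variable: str
    units: str
    grid: GridSpec
    month: int
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")
        if self.values.shape != self.grid.shape or self.mask.shape != self.grid.shape:
            raise GridMismatchError(
                f"{self.variable} field shape {self.values.shape} does not match "
                f"grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values under a valid mask")

    def value_at(self, i: int, j: int) -> float | None:
        """Value at cell (i, j), or None where masked invalid."""
        if not self.mask[j, i]:
            return None
        return float(self.values[j, i])


@dataclass
class CellDensity:
    """Mean larval density of one grid cell in one calendar month."""

    cell: tuple[int, int]
    month: int
    mean_density: float
    n_stations: int
    env: dict[str, float | None] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        """True when all three covariates were attached and valid."""
        return all(self.env.get(v) is not None for v in VARIABLES)


# ---------------------------------------------------------------------------
# Densities and gridding
# ---------------------------------------------------------------------------


def compute_density(count: int, volume: float) -> float:
    """Larval density C = N / V in ind (10 m)^-3.

    ``count`` is the number of larvae in the tow, ``volume`` the filtered
    water volume in units of (10 m)^3.
    """
    if count < 0:
        raise InvalidCountError(f"count must be >= 0, got {count}")
    if volume <= 0:
        raise InvalidVolumeError(f"volume must be > 0, got {volume}")
    return count / volume


def assign_cell(lon: float, lat: float, grid: GridSpec) -> tuple[int, int]:
    """Grid-cell index of a station position (half-open cell convention)."""
    return grid.cell_of(lon, lat)


def aggregate_cells(
    records: Sequence[SurveyRecord],
    grid: GridSpec,
    years: Iterable[int] | None = None,
) -> list[CellDensity]:
    """Bin station records to grid cells, one :class:`CellDensity` per
    occupied (cell, month).

    Records from different years but the same calendar month pool into the
    same cell; ``years`` optionally restricts which survey years enter.
    The cell statistic is the arithmetic mean of member station densities.
    """
    if years is not None:
        years = set(int(y) for y in years)
    groups: dict[tuple[tuple[int, int], int], list[float]] = defaultdict(list)
    for rec in records:
        if years is not None and rec.year not in years:
            continue
        groups[(assign_cell(rec.lon, rec.lat, grid), rec.month)].append(rec.density)
    out = [
        CellDensity(cell=cell, month=month,
                    mean_density=float(np.mean(dens)), n_stations=len(dens))
        for (cell, month), dens in groups.items()
    ]
    out.sort(key=lambda c: (c.month, c.cell))
    return out


# ---------------------------------------------------------------------------
# Environmental compositing
# ---------------------------------------------------------------------------


def mask_invalid(values: np.ndarray, variable: str,
                 sentinel_min: float = SENTINEL_MIN) -> np.ndarray:
    """Validity mask for a raw satellite array.

    Non-finite entries and sentinel fills (<= ``sentinel_min``) are invalid;
    Chl-a additionally rejects negative concentrations.
    """
    values = np.asarray(values, dtype=float)
    mask = np.isfinite(values) & (values > sentinel_min)
    if variable == "chla":
        mask &= values >= 0
    return mask


def monthly_composite(fields: Sequence[EnvField]) -> EnvField:
    """Average several same-month snapshots of one variable cell by cell.

    Only valid observations enter each cell's mean; a cell valid in no
    input stays masked. With a single input the composite is that field.
    """
    if not fields:
        raise InputError("monthly_composite needs at least one field")
    first = fields[0]
    for f in fields[1:]:
        if f.grid != first.grid:
            raise GridMismatchError("composite inputs on different grids")
        if f.variable != first.variable or f.month != first.month:
            raise InputError("composite inputs mix variables or months")
    stack = np.stack([f.values for f in fields])
    masks = np.stack([f.mask for f in fields])
    n_valid = masks.sum(axis=0)
    total = np.where(masks, stack, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_valid > 0, total / np.maximum(n_valid, 1), np.nan)
    return EnvField(
        variable=first.variable,
        units=first.units,
        grid=first.grid,
        month=first.month,
        values=mean,
        mask=n_valid > 0,
    )


def regrid_nearest(fld: EnvField, grid: GridSpec) -> EnvField:
    """Nearest-cell regrid of a field onto the analysis grid.

    Each target cell takes the source cell whose center is nearest to its
    own center; no interpolation across masked cells. Target cells whose
    nearest source center lies outside the source domain are masked.
    """
    if fld.grid == grid:
        return fld
    src = fld.grid
    lonc = grid.lon_centers()
    latc = grid.lat_centers()
    ii = np.round((lonc - src.lon_origin) / src.cell_size - 0.5).astype(int)
    jj = np.round((latc - src.lat_origin) / src.cell_size - 0.5).astype(int)
    ok_i = (ii >= 0) & (ii < src.n_lon)
    ok_j = (jj >= 0) & (jj < src.n_lat)
    ii_c = np.clip(ii, 0, src.n_lon - 1)
    jj_c = np.clip(jj, 0, src.n_lat - 1)
    values = fld.values[np.ix_(jj_c, ii_c)]
    mask = fld.mask[np.ix_(jj_c, ii_c)] & np.outer(ok_j, ok_i)
    values = np.where(mask, values, np.nan)
    return EnvField(fld.variable, fld.units, grid, fld.month, values, mask)


def attach_env(cells: Sequence[CellDensity],
               fields: Sequence[EnvField]) -> list[CellDensity]:
    """Attach SST/SSS/Chl-a values to each cell from its month's fields.

    Fields are regridded (nearest cell) to each cell's implied grid
    beforehand by the caller if needed; here grids must match across the
    provided fields. Masked covariates become ``None`` entries — such cells
    survive but are flagged incomplete and excluded from curve fitting.
    """
    by_key: dict[tuple[int, str], EnvField] = {}
    for f in fields:
        by_key[(f.month, f.variable)] = f
    out: list[CellDensity] = []
    for cell in cells:
        env: dict[str, float | None] = {}
        i, j = cell.cell
        for var in VARIABLES:
            try:
                fld = by_key[(cell.month, var)]
            except KeyError:
                raise MissingFieldError(
                    f"no {var} field for month {cell.month}"
                ) from None
            env[var] = fld.value_at(i, j)
        out.append(CellDensity(cell=cell.cell, month=cell.month,
                               mean_density=cell.mean_density,
                               n_stations=cell.n_stations, env=env))
    return out


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_survey_csv(path: str | Path, grid: GridSpec | None = None) -> list[SurveyRecord]:
    """Read tow records from CSV (columns station_id, lon, lat, year, month,
    count, volume). Density is always recomputed, never read."""
    df = pd.read_csv(path)
    missing = set(SURVEY_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"survey CSV missing columns: {sorted(missing)}")
    records = [
        SurveyRecord(
            station_id=str(row.station_id),
            lon=float(row.lon), lat=float(row.lat),
            year=int(row.year), month=int(row.month),
            count=int(row.count), volume=float(row.volume),
        )
        for row in df.itertuples(index=False)
    ]
    if grid is not None:
        for rec in records:
            assign_cell(rec.lon, rec.lat, grid)
    return records


def write_survey_csv(records: Sequence[SurveyRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {c: getattr(r, c) for c in SURVEY_CSV_COLUMNS}
            for r in records
        ]
    )
    df.to_csv(path, index=False)


def cells_to_dataframe(cells: Sequence[CellDensity]) -> pd.DataFrame:
    rows = []
    for c in cells:
        row = {"i": c.cell[0], "j": c.cell[1], "month": c.month,
               "mean_density": c.mean_density, "n_stations": c.n_stations}
        for var in VARIABLES:
            row[var] = c.env.get(var)
        rows.append(row)
    return pd.DataFrame(rows, columns=["i", "j", "month", "mean_density",
                                       "n_stations", *VARIABLES])


def write_cells_csv(cells: Sequence[CellDensity], path: str | Path) -> None:
    cells_to_dataframe(cells).to_csv(path, index=False)


def read_cells_csv(path: str | Path) -> list[CellDensity]:
    df = pd.read_csv(path)
    cells = []
    for row in df.itertuples(index=False):
        env = {v: (None if pd.isna(getattr(row, v)) else float(getattr(row, v)))
               for v in VARIABLES}
        cells.append(CellDensity(cell=(int(row.i), int(row.j)), month=int(row.month),
                                 mean_density=float(row.mean_density),
                                 n_stations=int(row.n_stations), env=env))
    return cells


def env_fields_to_dataset(fields: Sequence[EnvField]) -> xr.Dataset:
    """Bundle one month's fields (shared grid) into an xarray Dataset."""
    if not fields:
        raise InputError("no fields to bundle")
    grid, month = fields[0].grid, fields[0].month
    for f in fields:
        if f.grid != grid:
            raise GridMismatchError("fields on different grids")
        if f.month != month:
            raise InputError("fields from different months")
    data = {}
    for f in fields:
        arr = np.where(f.mask, f.values, np.nan)
        data[f.variable] = xr.DataArray(
            arr, dims=("lat", "lon"),
            coords={"lat": grid.lat_centers(), "lon": grid.lon_centers()},
            attrs={"units": f.units},
        )
    ds = xr.Dataset(data)
    ds.attrs.update(month=month, cell_size=grid.cell_size,
                    lon_origin=grid.lon_origin, lat_origin=grid.lat_origin)
    return ds


def write_env_netcdf(fields: Sequence[EnvField], path: str | Path) -> None:
    """Write one month's fields as classic NetCDF (scipy backend)."""
    env_fields_to_dataset(fields).to_netcdf(path, engine="scipy")


def read_env_netcdf(path: str | Path) -> list[EnvField]:
    """Read a per-month NetCDF file back into :class:`EnvField` objects.

    The grid is reconstructed from the lat/lon coordinate vectors (assumed
    regular and cell-centered); NaNs become masked cells.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    lon = np.asarray(ds["lon"].values, dtype=float)
    lat = np.asarray(ds["lat"].values, dtype=float)
    cs = float(ds.attrs.get("cell_size", lon[1] - lon[0] if lon.size > 1 else 0.25))
    grid = GridSpec(
        lon_origin=float(ds.attrs.get("lon_origin", lon[0] - cs / 2)),
        lat_origin=float(ds.attrs.get("lat_origin", lat[0] - cs / 2)),
        cell_size=cs, n_lon=lon.size, n_lat=lat.size,
    )
    month = int(ds.attrs["month"])
    fields = []
    for var in VARIABLES:
        if var not in ds:
            continue
        raw = np.asarray(ds[var].values, dtype=float)
        mask = mask_invalid(raw, var)
        fields.append(EnvField(var, str(ds[var].attrs.get("units", UNITS[var])),
                               grid, month, np.where(mask, raw, np.nan), mask))
    return fields


def read_env_grid_csv(path: str | Path, variable: str, month: int,
                      grid: GridSpec) -> EnvField:
    """CSV fallback for environmental input: columns lon, lat, value.

    Points are binned to ``grid`` cells; multiple points per cell average.
    """
    df = pd.read_csv(path)
    for col in ("lon", "lat", "value"):
        if col not in df.columns:
            raise InputError(f"environmental CSV missing column {col!r}")
    total = np.zeros(grid.shape)
    n = np.zeros(grid.shape, dtype=int)
    for row in df.itertuples(index=False):
        raw = float(row.value)
        if not mask_invalid(np.array([raw]), variable)[0]:
            continue
        try:
            i, j = grid.cell_of(float(row.lon), float(row.lat))
        except OutOfDomainError:
            continue
        total[j, i] += raw
        n[j, i] += 1
    mask = n > 0
    values = np.where(mask, total / np.maximum(n, 1), np.nan)
    return EnvField(variable, UNITS[variable], grid, month, values, mask)
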
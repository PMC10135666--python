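"""Combining single-factor SI values into a Habitat Suitability Index.

Four classical combiners map the (SI_SST, SI_SSS, SI_Chl-a) triple to one
HSI in [0, 1]:

* MAXM — maximum of the three (optimistic),
* MINM — minimum (conservative, Liebig-style limiting factor),
* AMM  — arithmetic mean,
* GMM  — geometric mean.

The published formulation divides the 3-term AMM sum by 4 and takes the
4th root of the 3-term GMM product (apparent vestiges of a four-factor
model); both that ``as_printed`` form and the standard 3-term
``renormalized`` form are provided. Under ``as_printed`` the AMM can never
exceed 0.75. MAXM and MINM are identical in the two variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .errors import ConfigurationError, GridMismatchError, InputError
from .si_fit import SICurve, evaluate_si
from .survey_ingest import EnvField, GridSpec, VARIABLES

METHODS = ("AMM", "GMM", "MAXM", "MINM")
VARIANTS = ("as_printed", "renormalized")


@dataclass(frozen=True)
class CombinerSpec:
    """Which combiner to use and which normalization variant."""

    method: str
    variant: str = "as_printed"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown method {self.method!r}")
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")

    @property
    def label(self) -> str:
        return f"{self.method}/{self.variant}"


@dataclass
class HSISurface:
    """Gridded HSI values for one month under one combiner."""

    month: int
    combiner: CombinerSpec
    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError("surface shape does not match grid")
        valid = self.values[self.mask]
        if valid.size and (valid.min() < -1e-12 or valid.max() > 1 + 1e-12):
            raise ValueError("HSI values outside [0, 1]")


def combine(si_sst, si_sss, si_chla, spec: CombinerSpec):
    """Combine three SI values (scalars or broadcastable arrays) into HSI."""
    arrs = [np.asarray(a, dtype=float) for a in (si_sst, si_sss, si_chla)]
    for a in arrs:
        if np.any((a < 0) | (a > 1)):
            raise InputError("SI inputs must lie in [0, 1]")
    s1, s2, s3 = arrs
    if spec.method == "MAXM":
        out = np.maximum(np.maximum(s1, s2), s3)
    elif spec.method == "MINM":
        out = np.minimum(np.minimum(s1, s2), s3)
    elif spec.method == "AMM":
        denom = 4.0 if spec.variant == "as_printed" else 3.0
        out = (s1 + s2 + s3) / denom
    else:  # GMM
        root = 4.0 if spec.variant == "as_printed" else 3.0
        out = (s1 * s2 * s3) ** (1.0 / root)
    return float(out) if out.ndim == 0 else out


def predict_hsi_surface(
    curves: Mapping[str, SICurve] | Sequence[SICurve],
    fields: Sequence[EnvField],
    spec: CombinerSpec,
) -> HSISurface:
    """Predict the HSI surface for one month from fitted curves and fields.

    Each unmasked grid cell gets ``combine`` of the three single-factor
    SI values evaluated at the cell's environmental values; a cell masked
    in any input field is masked in the output.
    """
    if not isinstance(curves, Mapping):
        curves = {c.variable: c for c in curves}
    fields_by_var = {f.variable: f for f in fields}
    if set(VARIABLES) - set(curves):
        raise ConfigurationError(f"missing curves for {sorted(set(VARIABLES) - set(curves))}")
    if set(VARIABLES) - set(fields_by_var):
        raise ConfigurationError(f"missing fields for {sorted(set(VARIABLES) - set(fields_by_var))}")
    months = {f.month for f in fields} | {curves[v].month for v in VARIABLES}
    if len(months) != 1:
        raise ConfigurationError(f"curves/fields mix months: {sorted(months)}")
    grid = fields_by_var["sst"].grid
    for f in fields:
        if f.grid != grid:
            raise ConfigurationError("fields on different grids")

    mask = np.logical_and.reduce([fields_by_var[v].mask for v in VARIABLES])
    si = {}
    for v in VARIABLES:
        vals = np.where(fields_by_var[v].mask, fields_by_var[v].values, curves[v].B)
        si[v] = evaluate_si(curves[v], vals)
    hsi = combine(si["sst"], si["sss"], si["chla"], spec)
    hsi = np.where(mask, hsi, np.nan)
    return HSISurface(month=months.pop(), combiner=spec, grid=grid,
                      values=hsi, mask=mask)


def classify_zones(surface: HSISurface, high: float = 0.8,
                   low: float = 0.2) -> np.ndarray:
    """Zone map: 'high' where HSI > high, 'low' where HSI < low, 'mid'
    otherwise (thresholds strict, so HSI == high is 'mid'); masked cells
    are None."""
    if not 0 <= low < high <= 1:
        raise ConfigurationError(f"need 0 <= low < high <= 1, got {low}, {high}")
    zones = np.full(surface.values.shape, None, dtype=object)
    v, m = surface.values, surface.mask
    zones[m & (v > high)] = "high"
    zones[m & (v < low)] = "low"
    zones[m & (v >= low) & (v <= high)] = "mid"
    return zones


def surfaces_to_dataframe(surfaces: Sequence[HSISurface]) -> pd.DataFrame:
    """Long-format table (i, j, month, method, variant, hsi) of unmasked cells."""
    rows = []
    for s in surfaces:
        jj, ii = np.nonzero(s.mask)
        for i, j in zip(ii, jj):
            rows.append({"i": int(i), "j": int(j), "month": s.month,
                         "method": s.combiner.method,
                         "variant": s.combiner.variant,
                         "hsi": float(s.values[j, i])})
    return pd.DataFrame(rows, columns=["i", "j", "month", "method", "variant", "hsi"])


def surface_to_dataset(surface: HSISurface) -> xr.Dataset:
    """NetCDF-ready dataset with an ``hsi`` variable on lon/lat dims."""
    grid = surface.grid
    arr = np.where(surface.mask, surface.values, np.nan)
    da = xr.DataArray(arr, dims=("lat", "lon"),
                      coords={"lat": grid.lat_centers(), "lon": grid.lon_centers()})
    ds = xr.Dataset({"hsi": da})
    ds.attrs.update(month=surface.month, method=surface.combiner.method,
                    variant=surface.combiner.variant,
                    cell_size=grid.cell_size,
                    lon_origin=grid.lon_origin, lat_origin=grid.lat_origin)
    return ds
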
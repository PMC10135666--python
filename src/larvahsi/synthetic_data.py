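"""Synthetic surveys and environmental fields with known ground truth.

The generator emulates the statistical structure the analysis assumes for
a subtropical estuary like the Pearl River Estuary: monthly SST / SSS /
Chl-a fields with realistic ranges (April SST 22-25 degC, summer SST
28-30 degC, SSS 22-34, Chl-a 0-10 mg/m3), and tow surveys whose expected
larval density follows a known HSI surface built from known Gaussian SI
curves (peak densities ~100 ind (10 m)^-3 in April and ~700 in summer).

All three covariates of a month derive from one latent habitat-quality
coordinate ``w`` — a smooth random surface with a plume-like trend
(increasing eastward/offshore). Each covariate is an *affine* function
of ``w``, centered on its true optimum B at the bump center ``w0 = 1/2``
(a symmetric design, so noise in the normalizing maximum cannot shift
fitted centers), with the largest slope that keeps the covariate inside
its realistic range and the sign chosen so SSS increases and Chl-a
decreases offshore. Along such a transect every single-factor relation
is exactly ``SI = exp(A (x - B)^2)`` up to a per-variable curvature
rescaling that leaves the center untouched, so all fifteen optima are
simultaneously identifiable from one survey; real covariates are not
functionally linked like this, so real fits face confounding the
synthetic study deliberately avoids (see the methods note). Counts are
drawn as Poisson(expected density x filtered volume) on top of
multiplicative log-normal density noise — the minimal error structure
that yields the zeros and overdispersion of real tow data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, InputError
from .hsi_combine import CombinerSpec, HSISurface, combine, predict_hsi_surface
from .si_fit import SICurve, reference_curves
from .survey_ingest import (
    EnvField,
    GridSpec,
    SURVEY_MONTHS,
    SurveyRecord,
    UNITS,
    VARIABLES,
    write_env_netcdf,
    write_survey_csv,
)

#: Study-area grid: 113-115 E, 21-23 N at 0.25 degrees.
DEFAULT_GRID = GridSpec(lon_origin=113.0, lat_origin=21.0, cell_size=0.25,
                        n_lon=8, n_lat=8)

#: Peak larval density per month, ind (10 m)^-3 (April lower, summer high).
DEFAULT_D_MAX: dict[int, float] = {4: 100.0, 6: 700.0, 7: 700.0, 8: 700.0, 9: 700.0}

#: Environmental ranges (lo, hi) per variable; SST is month-dependent.
SST_RANGE_BY_MONTH: dict[int, tuple[float, float]] = {
    4: (22.0, 25.0), 6: (28.0, 30.0), 7: (28.0, 30.0),
    8: (28.0, 30.0), 9: (28.0, 30.0),
}
SSS_RANGE = (22.0, 34.0)
CHLA_RANGE = (0.0, 10.0)

#: Weight of the plume-like directional trend vs. the smooth random
#: component in the latent habitat coordinate.
TREND_WEIGHT = 0.35

#: Flank orientation of each covariate along the latent coordinate
#: (offshore/east positive): SST and SSS increase with w, Chl-a decreases.
FLANK_SIGN = {"sst": +1.0, "sss": +1.0, "chla": -1.0}

_YEARS = (2014, 2015, 2016, 2017)


@dataclass
class SyntheticConfig:
    """Everything needed to generate one reproducible synthetic study."""

    grid: GridSpec = DEFAULT_GRID
    months: tuple[int, ...] = SURVEY_MONTHS
    true_curves: Mapping[tuple[int, str], SICurve] | None = None
    true_combiner: CombinerSpec = CombinerSpec("GMM", "renormalized")
    d_max: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_D_MAX))
    n_stations: int = 300
    volume_range: tuple[float, float] = (0.1, 0.5)
    noise_sd: float = 0.1
    cloud_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cloud_fraction < 1.0:
            raise ConfigurationError("cloud_fraction must be in [0, 1)")
        if self.volume_range[0] <= 0 or self.volume_range[1] < self.volume_range[0]:
            raise ConfigurationError("volume_range must be positive and ordered")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for m in self.months:
            if self.d_max.get(m, 0.0) <= 0:
                raise ConfigurationError(f"d_max missing or nonpositive for month {m}")
        if self.true_curves is None:
            self.true_curves = reference_curves()
        missing = [
            (m, v) for m in self.months for v in VARIABLES
            if (m, v) not in self.true_curves
        ]
        if missing:
            raise ConfigurationError(f"true_curves missing {missing}")


def sst_range(month: int) -> tuple[float, float]:
    """Month-appropriate SST range (April cooler than June-September)."""
    return SST_RANGE_BY_MONTH.get(month, (28.0, 30.0) if month >= 6 else (22.0, 25.0))


def variable_range(variable: str, month: int) -> tuple[float, float]:
    if variable == "sst":
        return sst_range(month)
    return SSS_RANGE if variable == "sss" else CHLA_RANGE


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  n_modes: int = 6) -> np.ndarray:
    """Smooth random surface in [0, 1] from a few random Fourier modes."""
    n_lat, n_lon = shape
    v, u = np.meshgrid(np.linspace(0, 1, n_lat), np.linspace(0, 1, n_lon),
                       indexing="ij")
    z = np.zeros(shape)
    for _ in range(n_modes):
        amp = rng.uniform(0.3, 1.0)
        fu, fv = rng.uniform(0.5, 2.5, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        z += amp * np.sin(2 * np.pi * (fu * u + fv * v) + phase)
    lo, hi = z.min(), z.max()
    return (z - lo) / (hi - lo) if hi > lo else np.full(shape, 0.5)


def _plume_trend(shape: tuple[int, int]) -> np.ndarray:
    """Plume-distance coordinate in [0, 1], increasing eastward/offshore
    (offshore = southward in the study area)."""
    n_lat, n_lon = shape
    v, u = np.meshgrid(np.linspace(0, 1, n_lat), np.linspace(0, 1, n_lon),
                       indexing="ij")
    return (u + (1.0 - v)) / 2.0


def month_geometry(config: SyntheticConfig,
                   month: int) -> tuple[float, float, dict[str, float]]:
    """Latent-transect geometry for one month.

    Returns the bump center ``w0`` (1/2: a symmetric design about every
    optimum), the curvature ``lam_bar`` of the latent suitability bump
    ``exp(-lam_bar (w - w0)^2)`` implied by the geometric-mean combiner,
    and the per-variable slopes ``c_v`` of the affine covariate transects
    ``x_v = B_v + sign_v * c_v * (w - w0)``. Each slope is the largest
    that keeps the covariate inside its realistic range over w in [0, 1];
    this requires every true optimum B to lie strictly inside its range.
    """
    w0 = 0.5
    slopes: dict[str, float] = {}
    lams: list[float] = []
    for var in VARIABLES:
        curve = config.true_curves[(month, var)]
        lo, hi = variable_range(var, month)
        up, dn = hi - curve.B, curve.B - lo
        if up <= 0 or dn <= 0:
            raise ConfigurationError(
                f"true optimum {curve.B} for {var}/month {month} must lie "
                f"strictly inside the realistic range ({lo}, {hi})")
        if FLANK_SIGN[var] > 0:
            c_v = min(up / (1 - w0), dn / w0)
        else:
            c_v = min(dn / (1 - w0), up / w0)
        slopes[var] = float(c_v)
        lams.append(abs(curve.A) * c_v * c_v)
    return w0, float(np.mean(lams)), slopes


def generate_env_fields(config: SyntheticConfig) -> list[EnvField]:
    """Deterministic monthly SST/SSS/Chl-a fields with cloud gaps.

    Per month, a smooth latent coordinate w (plume trend + random smooth
    component) drives all three covariates affinely (see module
    docstring), so values fall inside each variable's realistic range and
    the true suitability at a cell is the same for every factor. A
    ``cloud_fraction`` share of cells is masked invalid per variable and
    month (emulating cloud cover in satellite composites). The same seed
    reproduces the fields bit for bit.
    """
    rng = np.random.default_rng([int(config.seed), 101])
    fields: list[EnvField] = []
    for month in config.months:
        z = _smooth_noise(rng, config.grid.shape)
        w = TREND_WEIGHT * _plume_trend(config.grid.shape) + (1 - TREND_WEIGHT) * z
        lo_w, hi_w = w.min(), w.max()
        w = (w - lo_w) / (hi_w - lo_w) if hi_w > lo_w else np.full_like(w, 0.5)
        w0, _lam, slopes = month_geometry(config, month)
        for var in VARIABLES:
            curve = config.true_curves[(month, var)]
            lo, hi = variable_range(var, month)
            values = curve.B + FLANK_SIGN[var] * slopes[var] * (w - w0)
            values = np.clip(values, lo, hi)  # float round-off guard only
            mask = rng.random(config.grid.shape) >= config.cloud_fraction
            fields.append(EnvField(var, UNITS[var], config.grid, month,
                                   np.where(mask, values, np.nan), mask))
    return fields


def true_si_triple(config: SyntheticConfig, month: int,
                   sst: float, sss: float, chla: float) -> tuple[float, float, float]:
    """Ground-truth single-factor SI values at one environmental triple."""
    c = config.true_curves
    return (c[(month, "sst")](sst), c[(month, "sss")](sss), c[(month, "chla")](chla))


def simulate_survey(config: SyntheticConfig,
                    fields: Sequence[EnvField]) -> list[SurveyRecord]:
    """Draw tow records whose expected density follows the true HSI.

    Stations fall uniformly over cells valid in all three covariates; at a
    station the expected density is ``d_max(month) x HSI_true`` times
    log-normal noise (sd ``noise_sd`` on the log scale), the filtered
    volume is uniform over ``volume_range`` and the count is Poisson with
    mean density x volume.
    """
    rng = np.random.default_rng([int(config.seed), 202])
    by_month: dict[int, dict[str, EnvField]] = {}
    for f in fields:
        by_month.setdefault(f.month, {})[f.variable] = f
    records: list[SurveyRecord] = []
    for month in config.months:
        month_fields = by_month.get(month, {})
        if set(month_fields) != set(VARIABLES):
            raise InputError(f"fields for month {month} incomplete")
        mask = np.logical_and.reduce([month_fields[v].mask for v in VARIABLES])
        jj, ii = np.nonzero(mask)
        if jj.size == 0:
            raise InputError(f"month {month}: no cell valid in all covariates")
        grid = config.grid
        pick = rng.integers(0, jj.size, size=config.n_stations)
        for k, idx in enumerate(pick):
            i, j = int(ii[idx]), int(jj[idx])
            lon_lo, lon_hi, lat_lo, lat_hi = grid.cell_bounds(i, j)
            lon = rng.uniform(lon_lo, lon_hi)
            lat = rng.uniform(lat_lo, lat_hi)
            si = true_si_triple(config, month,
                                month_fields["sst"].values[j, i],
                                month_fields["sss"].values[j, i],
                                month_fields["chla"].values[j, i])
            hsi = combine(*si, config.true_combiner)
            mean_density = config.d_max[month] * hsi
            if config.noise_sd > 0:
                mean_density *= np.exp(rng.normal(0.0, config.noise_sd))
            volume = rng.uniform(*config.volume_range)
            count = int(rng.poisson(mean_density * volume))
            records.append(SurveyRecord(
                station_id=f"SYN-{month:02d}-{k:04d}",
                lon=float(lon), lat=float(lat),
                year=_YEARS[k % len(_YEARS)], month=month,
                count=count, volume=float(volume),
            ))
    return records


@dataclass
class GroundTruth:
    """The objects the pipeline should recover from a synthetic run."""

    curves: dict[tuple[int, str], SICurve]
    optima: dict[tuple[int, str], float]
    hsi_surfaces: dict[int, HSISurface]


def ground_truth_bundle(config: SyntheticConfig) -> GroundTruth:
    """True curves, optima and HSI surfaces for recovery assertions.

    Pure in the config: two calls with equal configs return identical
    objects (the environmental fields are regenerated from the seed).
    """
    fields = generate_env_fields(config)
    by_month: dict[int, list[EnvField]] = {}
    for f in fields:
        by_month.setdefault(f.month, []).append(f)
    surfaces = {
        month: predict_hsi_surface(
            {v: config.true_curves[(month, v)] for v in VARIABLES},
            month_fields, config.true_combiner)
        for month, month_fields in by_month.items()
    }
    curves = dict(config.true_curves)
    optima = {key: c.B for key, c in curves.items() if key[0] in config.months}
    return GroundTruth(curves=curves, optima=optima, hsi_surfaces=surfaces)


def write_synthetic_dataset(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Emit the survey CSV and per-month environmental NetCDF files in the
    exact formats the ingestion module consumes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fields = generate_env_fields(config)
    records = simulate_survey(config, fields)
    survey_path = out_dir / "survey.csv"
    write_survey_csv(records, survey_path)
    paths = {"survey": survey_path}
    by_month: dict[int, list[EnvField]] = {}
    for f in fields:
        by_month.setdefault(f.month, []).append(f)
    for month, month_fields in sorted(by_month.items()):
        p = out_dir / f"env_{month:02d}.nc"
        write_env_netcdf(month_fields, p)
        paths[f"env_{month:02d}"] = p
    return paths
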
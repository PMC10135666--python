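"""Configuration-driven orchestration of the full analysis.

Stages (each file-based, so they can be re-run independently):

1. ``simulate``  — optional: write a synthetic survey + environmental files
2. ``ingest``    — densities, gridding, monthly composites, env attachment
3. ``fit``       — train/test split and per month x variable SI curves
4. ``predict``   — HSI surfaces per month x combiner
5. ``validate``  — hold-out accuracy with the |error| < threshold rule
6. ``report``    — formatted analogs of the curve, optimum and accuracy tables

All randomness flows from one top-level seed, split into per-stage
streams, so a rerun with the same config reproduces every artifact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, MissingArtifactError
from .hsi_combine import (
    CombinerSpec,
    HSISurface,
    METHODS,
    VARIANTS,
    predict_hsi_surface,
    surface_to_dataset,
    surfaces_to_dataframe,
)
from .si_fit import MONTH_NAMES, SICurve, fit_si_curve, format_si_formula, optimum
from .survey_ingest import (
    CellDensity,
    EnvField,
    GridSpec,
    SURVEY_MONTHS,
    VARIABLES,
    aggregate_cells,
    attach_env,
    monthly_composite,
    read_cells_csv,
    read_env_netcdf,
    read_survey_csv,
    regrid_nearest,
    write_cells_csv,
)
from .synthetic_data import SyntheticConfig, write_synthetic_dataset
from .validation import (
    SplitSpec,
    ValidationReport,
    train_month_maxima,
    validation_report,
    split_train_test,
)

logger = logging.getLogger(__name__)

_DEFAULT_COMBINERS = tuple(
    CombinerSpec(method, variant) for method in METHODS for variant in VARIANTS
)


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from YAML."""

    output_dir: Path
    survey_csv: Path | None = None
    env_dir: Path | None = None
    grid: GridSpec | None = None  # defaults to the synthetic grid or the study-area grid
    months: tuple[int, ...] = SURVEY_MONTHS
    seed: int = 0
    train_fraction: float = 0.8
    stratify_by_month: bool = True
    combiners: tuple[CombinerSpec, ...] = _DEFAULT_COMBINERS
    threshold: float = 0.4
    fit_granularity: str = "cell"
    init_threshold: float = 0.05
    years: tuple[int, ...] | None = None
    synthetic: SyntheticConfig | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if self.survey_csv is not None:
            self.survey_csv = Path(self.survey_csv)
        if self.env_dir is not None:
            self.env_dir = Path(self.env_dir)
        if self.grid is None:
            self.grid = (self.synthetic.grid if self.synthetic is not None
                         else GridSpec(113.0, 21.0, 0.25, 8, 8))
        if not 0.0 < self.threshold <= 1.0:
            raise ConfigurationError("threshold must be in (0, 1]")
        if self.fit_granularity not in ("cell", "station"):
            raise ConfigurationError("fit_granularity must be 'cell' or 'station'")

    # -- seeds -------------------------------------------------------------
    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the top-level seed."""
        order = {"simulate": 0, "split": 1}
        child = np.random.SeedSequence(self.seed).spawn(2)[order[stage]]
        return int(child.generate_state(1)[0] & 0x7FFFFFFF)

    # -- YAML --------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        kw: dict[str, Any] = {}
        paths = raw.get("paths", {})
        kw["output_dir"] = paths.get("output_dir", raw.get("output_dir", "runs/out"))
        if paths.get("survey_csv") or raw.get("survey_csv"):
            kw["survey_csv"] = paths.get("survey_csv", raw.get("survey_csv"))
        if paths.get("env_dir") or raw.get("env_dir"):
            kw["env_dir"] = paths.get("env_dir", raw.get("env_dir"))
        if "grid" in raw:
            kw["grid"] = GridSpec(**raw["grid"])
        for key in ("months", "seed", "threshold", "fit_granularity",
                    "init_threshold", "log_level"):
            if key in raw:
                kw[key] = tuple(raw[key]) if key == "months" else raw[key]
        split = raw.get("split", {})
        if "train_fraction" in split:
            kw["train_fraction"] = float(split["train_fraction"])
        if "stratify_by_month" in split:
            kw["stratify_by_month"] = bool(split["stratify_by_month"])
        if "combiners" in raw:
            kw["combiners"] = tuple(
                CombinerSpec(c["method"], c.get("variant", "as_printed"))
                for c in raw["combiners"]
            )
        if "years" in raw and raw["years"]:
            kw["years"] = tuple(int(y) for y in raw["years"])
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            if "grid" in syn:
                syn["grid"] = GridSpec(**syn["grid"])
            elif "grid" in raw:
                syn["grid"] = GridSpec(**raw["grid"])
            if "months" in raw and "months" not in syn:
                syn["months"] = tuple(raw["months"])
            if "d_max" in syn:
                syn["d_max"] = {int(k): float(v) for k, v in syn["d_max"].items()}
            if "volume_range" in syn:
                syn["volume_range"] = tuple(syn["volume_range"])
            if "true_combiner" in syn:
                tc = syn["true_combiner"]
                syn["true_combiner"] = CombinerSpec(tc["method"],
                                                    tc.get("variant", "renormalized"))
            syn.setdefault("seed", raw.get("seed", 0))
            kw["synthetic"] = SyntheticConfig(**syn)
        return cls(**kw)


@dataclass
class RunArtifacts:
    """In-memory handles plus file paths produced by a run."""

    config: PipelineConfig
    cells: list[CellDensity]
    train_cells: list[CellDensity]
    test_cells: list[CellDensity]
    curves: dict[tuple[int, str], SICurve]
    surfaces: list[HSISurface]
    report: ValidationReport
    paths: dict[str, Path]


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _atomic_write_df(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, index=False)
    os.replace(tmp, path)


def _curves_to_dataframe(curves: Mapping[tuple[int, str], SICurve]) -> pd.DataFrame:
    rows = []
    for (month, var), c in sorted(curves.items()):
        rows.append({"month": month, "variable": var, "A": c.A, "B": c.B,
                     "n": c.n, "p_value": c.p_value, "B_se": c.B_se,
                     "formula": format_si_formula(c)})
    return pd.DataFrame(rows, columns=["month", "variable", "A", "B", "n",
                                       "p_value", "B_se", "formula"])


def _curves_from_dataframe(df: pd.DataFrame) -> dict[tuple[int, str], SICurve]:
    curves = {}
    for row in df.itertuples(index=False):
        curves[(int(row.month), str(row.variable))] = SICurve(
            variable=str(row.variable), month=int(row.month),
            A=float(row.A), B=float(row.B), n=int(row.n),
            p_value=float(row.p_value), B_se=float(row.B_se))
    return curves


def _configure_logging(config: PipelineConfig) -> None:
    config.output_dir.mkdir(parents=True, exist_ok=True)
    root = logging.getLogger("larvahsi")
    root.setLevel(config.log_level.upper())
    for handler in [h for h in root.handlers if isinstance(h, logging.FileHandler)]:
        root.removeHandler(handler)
        handler.close()
    fh = logging.FileHandler(config.output_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root.addHandler(fh)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Generate the synthetic survey + environmental inputs (if configured)."""
    if config.synthetic is None:
        raise ConfigurationError("no synthetic section in the configuration")
    syn = dataclasses.replace(config.synthetic, seed=config.stage_seed("simulate"))
    data_dir = config.output_dir / "synthetic"
    paths = write_synthetic_dataset(syn, data_dir)
    logger.info("simulate: wrote %d files to %s", len(paths), data_dir)
    config.survey_csv = paths["survey"]
    config.env_dir = data_dir
    return paths


def load_env_fields(config: PipelineConfig) -> list[EnvField]:
    """Read, composite and regrid each month's environmental files.

    Files named ``env_MM*.nc`` in ``env_dir``; several files for one month
    are composited (invalid values eliminated, cellwise average).
    """
    if config.env_dir is None:
        raise ConfigurationError("env_dir not set")
    fields: list[EnvField] = []
    for month in config.months:
        paths = sorted(Path(config.env_dir).glob(f"env_{month:02d}*.nc"))
        if not paths:
            raise MissingArtifactError(
                f"no environmental file env_{month:02d}*.nc in {config.env_dir}")
        per_var: dict[str, list[EnvField]] = {}
        for p in paths:
            for f in read_env_netcdf(p):
                per_var.setdefault(f.variable, []).append(f)
        for var in VARIABLES:
            if var not in per_var:
                raise MissingArtifactError(
                    f"variable {var} missing for month {month} in {config.env_dir}")
            composite = monthly_composite(per_var[var])
            fields.append(regrid_nearest(composite, config.grid))
    return fields


def stage_ingest(config: PipelineConfig) -> list[CellDensity]:
    """Survey CSV + env files -> attached cell table (cells.csv)."""
    if config.survey_csv is None:
        raise ConfigurationError("survey_csv not set")
    records = read_survey_csv(config.survey_csv, grid=config.grid)
    fields = load_env_fields(config)
    cells = aggregate_cells(records, config.grid, years=config.years)
    cells = [c for c in cells if c.month in set(config.months)]
    cells = attach_env(cells, fields)
    config.output_dir.mkdir(parents=True, exist_ok=True)
    write_cells_csv(cells, config.output_dir / "cells.csv")
    if config.fit_granularity == "station":
        rows = []
        by_key = {(f.month, f.variable): f for f in fields}
        for rec in records:
            if rec.month not in set(config.months):
                continue
            i, j = config.grid.cell_of(rec.lon, rec.lat)
            row = {"station_id": rec.station_id, "month": rec.month,
                   "i": i, "j": j, "density": rec.density}
            for var in VARIABLES:
                row[var] = by_key[(rec.month, var)].value_at(i, j)
            rows.append(row)
        _atomic_write_df(pd.DataFrame(rows), config.output_dir / "stations.csv")
    logger.info("ingest: %d records -> %d cells", len(records), len(cells))
    return cells


def fit_curves(
    train_cells: Sequence[CellDensity],
    months: Sequence[int],
    init_threshold: float = 0.05,
    station_samples: pd.DataFrame | None = None,
) -> dict[tuple[int, str], SICurve]:
    """Fit the per month x variable Gaussian SI curves on training data.

    Cell granularity: one (env value, SI) pair per complete cell, SI
    normalized by the month's maximum training cell density. Station
    granularity: pairs per station (``station_samples`` rows restricted to
    training cells), normalized by the month's maximum station density.
    """
    maxima = train_month_maxima(train_cells)
    curves: dict[tuple[int, str], SICurve] = {}
    for month in months:
        if station_samples is not None:
            train_keys = {(c.cell[0], c.cell[1]) for c in train_cells
                          if c.month == month}
            sub = station_samples[station_samples["month"] == month]
            sub = sub[[(int(r.i), int(r.j)) in train_keys
                       for r in sub.itertuples(index=False)]]
            y_max = float(sub["density"].max()) if len(sub) else 0.0
            if y_max <= 0:
                logger.warning("month %d: no positive station density; skipped", month)
                continue
            si = np.clip(sub["density"].to_numpy() / y_max, 0.0, 1.0)
            for var in VARIABLES:
                x = sub[var].to_numpy(dtype=float)
                keep = np.isfinite(x)
                curves[(month, var)] = fit_si_curve(
                    x=x[keep], si=si[keep], variable=var, month=month,
                    init_threshold=init_threshold)
        else:
            month_cells = [c for c in train_cells if c.month == month and c.complete]
            y_max = float(maxima.get(month, 0.0))
            if y_max <= 0 or not month_cells:
                logger.warning("month %d: no usable training cells; skipped", month)
                continue
            si = np.clip([c.mean_density / y_max for c in month_cells], 0.0, 1.0)
            for var in VARIABLES:
                x = np.array([c.env[var] for c in month_cells], dtype=float)
                curves[(month, var)] = fit_si_curve(
                    x=x, si=si, variable=var, month=month,
                    init_threshold=init_threshold)
    for (month, var), c in sorted(curves.items()):
        logger.info("fit: month %d %s  A=%.4g B=%.4g n=%d p=%.3g",
                    month, var, c.A, c.B, c.n, c.p_value)
    return curves


def stage_fit(config: PipelineConfig,
              cells: Sequence[CellDensity] | None = None) -> dict[tuple[int, str], SICurve]:
    """Split cells, fit training curves, write curve/split artifacts."""
    if cells is None:
        cells_path = config.output_dir / "cells.csv"
        if not cells_path.exists():
            raise MissingArtifactError(f"{cells_path} missing; run ingest first")
        cells = read_cells_csv(cells_path)
    split = SplitSpec(train_fraction=config.train_fraction,
                      seed=config.stage_seed("split"),
                      stratify_by_month=config.stratify_by_month)
    train, test = split_train_test(list(cells), split)
    station_samples = None
    if config.fit_granularity == "station":
        st_path = config.output_dir / "stations.csv"
        if not st_path.exists():
            raise MissingArtifactError(f"{st_path} missing; run ingest first")
        station_samples = pd.read_csv(st_path)
    curves = fit_curves(train, config.months, config.init_threshold,
                        station_samples)
    write_cells_csv(train, config.output_dir / "train_cells.csv")
    write_cells_csv(test, config.output_dir / "test_cells.csv")
    _atomic_write_df(_curves_to_dataframe(curves), config.output_dir / "curves.csv")
    maxima = train_month_maxima(train)
    with open(config.output_dir / "train_maxima.json", "w") as fh:
        json.dump({str(k): v for k, v in maxima.items()}, fh, indent=1)
    return curves


def stage_predict(config: PipelineConfig,
                  curves: Mapping[tuple[int, str], SICurve] | None = None
                  ) -> list[HSISurface]:
    """Predict HSI surfaces for every month x combiner; write NetCDF + CSV."""
    if curves is None:
        path = config.output_dir / "curves.csv"
        if not path.exists():
            raise MissingArtifactError(f"{path} missing; run fit first")
        curves = _curves_from_dataframe(pd.read_csv(path))
    fields = load_env_fields(config)
    by_month: dict[int, list[EnvField]] = {}
    for f in fields:
        by_month.setdefault(f.month, []).append(f)
    hsi_dir = config.output_dir / "hsi"
    hsi_dir.mkdir(parents=True, exist_ok=True)
    surfaces: list[HSISurface] = []
    for month in config.months:
        month_curves = {v: curves[(month, v)] for v in VARIABLES
                        if (month, v) in curves}
        if len(month_curves) < len(VARIABLES):
            logger.warning("predict: month %d skipped (missing curves)", month)
            continue
        for spec in config.combiners:
            surface = predict_hsi_surface(month_curves, by_month[month], spec)
            surfaces.append(surface)
            out = hsi_dir / f"hsi_m{month:02d}_{spec.method}_{spec.variant}.nc"
            surface_to_dataset(surface).to_netcdf(out, engine="scipy")
    _atomic_write_df(surfaces_to_dataframe(surfaces), config.output_dir / "hsi.csv")
    return surfaces


def stage_validate(config: PipelineConfig,
                   curves: Mapping[tuple[int, str], SICurve] | None = None,
                   test_cells: Sequence[CellDensity] | None = None,
                   train_maxima: Mapping[int, float] | None = None
                   ) -> ValidationReport:
    """Score test-cell predictions; write validation.csv and pairs.csv."""
    if curves is None:
        path = config.output_dir / "curves.csv"
        if not path.exists():
            raise MissingArtifactError(f"{path} missing; run fit first")
        curves = _curves_from_dataframe(pd.read_csv(path))
    if test_cells is None:
        path = config.output_dir / "test_cells.csv"
        if not path.exists():
            raise MissingArtifactError(f"{path} missing; run fit first")
        test_cells = read_cells_csv(path)
    if train_maxima is None:
        path = config.output_dir / "train_maxima.json"
        if not path.exists():
            raise MissingArtifactError(f"{path} missing; run fit first")
        with open(path) as fh:
            train_maxima = {int(k): float(v) for k, v in json.load(fh).items()}
    report = validation_report(list(test_cells), curves, list(config.combiners),
                               train_maxima, config.threshold)
    _atomic_write_df(report.to_dataframe(), config.output_dir / "validation.csv")
    _atomic_write_df(report.pairs, config.output_dir / "pairs.csv")
    for e in report.entries:
        logger.info("validate: month %d %s/%s accuracy %.2f (%d/%d)",
                    e.month, e.method, e.variant, e.accuracy,
                    e.n_accurate, e.n_test)
    return report


def make_table_analogs(
    curves: Mapping[tuple[int, str], SICurve] | None = None,
    report: ValidationReport | None = None,
    output_dir: str | Path | None = None,
    variant: str = "as_printed",
) -> dict[str, pd.DataFrame]:
    """Formatted analogs of the three result tables.

    * ``si_models`` — one row per month x variable with the fitted curve in
      printed notation, its sample size and p-value;
    * ``optima``    — months x factors, each entry ``B ± SE`` at one decimal;
    * ``accuracy``  — months x combiner methods, hold-out accuracy fractions.
    """
    if curves is None or report is None:
        if output_dir is None:
            raise MissingArtifactError("need curves+report or an output_dir")
        output_dir = Path(output_dir)
        cpath, vpath = output_dir / "curves.csv", output_dir / "validation.csv"
        if not cpath.exists() or not vpath.exists():
            raise MissingArtifactError("run fit and validate before report")
        curves = _curves_from_dataframe(pd.read_csv(cpath))
        vdf = pd.read_csv(vpath)
    else:
        vdf = report.to_dataframe()

    rows = []
    for (month, var), c in sorted(curves.items()):
        rows.append({"month": MONTH_NAMES.get(month, str(month)),
                     "variable": {"sst": "SST", "sss": "SSS", "chla": "Chl-a"}[var],
                     "si_model": format_si_formula(c),
                     "n": c.n, "p_value": c.p_value})
    si_models = pd.DataFrame(rows, columns=["month", "variable", "si_model",
                                            "n", "p_value"])

    months = sorted({m for m, _ in curves})
    opt_rows = []
    for month in months:
        row: dict[str, Any] = {"month": MONTH_NAMES.get(month, str(month))}
        for var, col in (("sst", "SST (degC)"), ("sss", "SSS"),
                         ("chla", "Chl-a (mg/m3)")):
            if (month, var) in curves:
                x_opt, se = optimum(curves[(month, var)])
                row[col] = (f"{x_opt:.1f} ± {se:.1f}" if np.isfinite(se)
                            else f"{x_opt:.1f}")
            else:
                row[col] = ""
        opt_rows.append(row)
    optima_df = pd.DataFrame(opt_rows,
                             columns=["month", "SST (degC)", "SSS", "Chl-a (mg/m3)"])

    acc = vdf[vdf["variant"] == variant]
    accuracy = acc.pivot(index="month", columns="method", values="accuracy")
    accuracy = accuracy.reindex(columns=[m for m in METHODS if m in accuracy.columns])
    accuracy.index = [MONTH_NAMES.get(m, str(m)) for m in accuracy.index]

    tables = {"si_models": si_models, "optima": optima_df, "accuracy": accuracy}
    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        si_models.to_csv(output_dir / "table_si_models.csv", index=False)
        optima_df.to_csv(output_dir / "table_optima.csv", index=False)
        accuracy.to_csv(output_dir / "table_accuracy.csv")
    return tables


def run_pipeline(config: PipelineConfig) -> RunArtifacts:
    """Run every stage in order and return all artifacts."""
    _configure_logging(config)
    paths: dict[str, Path] = {}
    if config.synthetic is not None and config.survey_csv is None:
        paths.update(stage_simulate(config))
    cells = stage_ingest(config)
    curves = stage_fit(config, cells)
    surfaces = stage_predict(config, curves)
    train = read_cells_csv(config.output_dir / "train_cells.csv")
    test = read_cells_csv(config.output_dir / "test_cells.csv")
    report = stage_validate(config, curves, test, train_month_maxima(train))
    make_table_analogs(curves, report, config.output_dir)
    for name in ("cells.csv", "train_cells.csv", "test_cells.csv", "curves.csv",
                 "hsi.csv", "validation.csv", "pairs.csv", "table_si_models.csv",
                 "table_optima.csv", "table_accuracy.csv", "run.log"):
        paths[name] = config.output_dir / name
    return RunArtifacts(config=config, cells=cells, train_cells=train,
                        test_cells=test, curves=curves, surfaces=surfaces,
                        report=report, paths=paths)
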
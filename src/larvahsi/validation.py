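"""Hold-out validation of HSI predictions.

The survey cells are split 80/20 (stratified by month so every monthly
model keeps training and test data), curves are fitted on the training
portion only, and each test cell's predicted HSI is compared with its
observed SI — density normalized by the *training* month maximum, clipped
to [0, 1]. A prediction counts as accurate when the absolute error is
strictly below the threshold (default 0.4), and accuracy is the accurate
fraction per month x combiner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, InsufficientDataError
from .hsi_combine import CombinerSpec, combine
from .si_fit import SICurve, evaluate_si
from .survey_ingest import CellDensity, VARIABLES

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.4


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition parameters."""

    train_fraction: float = 0.8
    seed: int = 0
    stratify_by_month: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class ValidationEntry:
    month: int
    method: str
    variant: str
    n_test: int
    n_accurate: int

    @property
    def accuracy(self) -> float:
        return self.n_accurate / self.n_test


@dataclass
class ValidationReport:
    """Per month x combiner accuracy entries plus per-pair diagnostics."""

    entries: list[ValidationEntry] = field(default_factory=list)
    pairs: pd.DataFrame | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"month": e.month, "method": e.method, "variant": e.variant,
                 "n_test": e.n_test, "n_accurate": e.n_accurate,
                 "accuracy": e.accuracy}
                for e in self.entries
            ],
            columns=["month", "method", "variant", "n_test", "n_accurate", "accuracy"],
        )

    def pivot(self, variant: str = "as_printed") -> pd.DataFrame:
        """Months-by-methods accuracy table for one variant."""
        df = self.to_dataframe()
        df = df[df["variant"] == variant]
        return df.pivot(index="month", columns="method", values="accuracy")


def split_train_test(
    cells: Sequence[CellDensity], spec: SplitSpec
) -> tuple[list[CellDensity], list[CellDensity]]:
    """Random, reproducible train/test partition of survey cells.

    With ``stratify_by_month`` each month is split separately so the
    per-month models always retain both partitions; the train size per
    stratum is round(train_fraction * n). Identical seeds give identical
    partitions.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.stratify_by_month:
        strata: dict[int | None, list[int]] = {}
        for idx, c in enumerate(cells):
            strata.setdefault(c.month, []).append(idx)
    else:
        strata = {None: list(range(len(cells)))}

    train_idx: list[int] = []
    test_idx: list[int] = []
    for key in sorted(strata, key=lambda k: (k is None, k)):
        idx = np.array(strata[key])
        if idx.size < 5:
            raise InsufficientDataError(
                f"stratum {key!r} has only {idx.size} cells (< 5)"
            )
        n_train = int(np.floor(spec.train_fraction * idx.size + 0.5))
        n_train = min(max(n_train, 1), idx.size - 1)
        perm = rng.permutation(idx.size)
        train_idx.extend(idx[perm[:n_train]].tolist())
        test_idx.extend(idx[perm[n_train:]].tolist())
    return ([cells[i] for i in sorted(train_idx)],
            [cells[i] for i in sorted(test_idx)])


def forecast_accuracy(
    predicted_hsi: Sequence[float],
    actual_si: Sequence[float],
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[int, float]:
    """Count of accurate forecasts and their fraction.

    A (predicted, actual) pair is accurate iff |predicted − actual| is
    strictly less than ``threshold``.
    """
    pred = np.asarray(predicted_hsi, dtype=float)
    act = np.asarray(actual_si, dtype=float)
    if pred.shape != act.shape:
        raise InputError("predicted and actual must have equal length")
    if pred.size == 0:
        raise InputError("empty validation set")
    n_acc = int(np.count_nonzero(np.abs(pred - act) < threshold))
    return n_acc, n_acc / pred.size


def train_month_maxima(train_cells: Sequence[CellDensity]) -> dict[int, float]:
    """Maximum observed cell density per month in the training partition."""
    maxima: dict[int, float] = {}
    for c in train_cells:
        maxima[c.month] = max(maxima.get(c.month, 0.0), c.mean_density)
    return maxima


def validation_report(
    test_cells: Sequence[CellDensity],
    curves: Mapping[tuple[int, str], SICurve],
    combiners: Sequence[CombinerSpec],
    train_maxima: Mapping[int, float],
    threshold: float = DEFAULT_THRESHOLD,
) -> ValidationReport:
    """Score HSI predictions on the test cells, one entry per month x
    combiner.

    A test cell's actual SI is its density divided by the training
    maximum of its month (clipped to 1 — hold-out densities can exceed
    the training maximum); its predicted HSI combines the fitted curves
    evaluated at the cell's attached environmental values. Cells missing
    any covariate are skipped; months missing a fitted curve or a
    positive training maximum are skipped with a logged warning.
    """
    months = sorted({c.month for c in test_cells})
    report = ValidationReport()
    pair_rows = []
    for month in months:
        needed = [(month, v) for v in VARIABLES]
        if any(k not in curves for k in needed):
            logger.warning("month %d skipped: missing fitted curve(s)", month)
            continue
        y_max = float(train_maxima.get(month, 0.0))
        if y_max <= 0:
            logger.warning("month %d skipped: no positive training density", month)
            continue
        usable = [c for c in test_cells if c.month == month and c.complete]
        if not usable:
            logger.warning("month %d skipped: no complete test cells", month)
            continue
        actual = np.clip([c.mean_density / y_max for c in usable], 0.0, 1.0)
        si_by_var = {
            v: np.array([evaluate_si(curves[(month, v)], c.env[v]) for c in usable])
            for v in VARIABLES
        }
        for spec in combiners:
            pred = combine(si_by_var["sst"], si_by_var["sss"], si_by_var["chla"], spec)
            pred = np.atleast_1d(pred)
            n_acc, _ = forecast_accuracy(pred, actual, threshold)
            report.entries.append(
                ValidationEntry(month=month, method=spec.method,
                                variant=spec.variant, n_test=len(usable),
                                n_accurate=n_acc)
            )
            for c, p, a in zip(usable, pred, actual):
                pair_rows.append({"month": month, "i": c.cell[0], "j": c.cell[1],
                                  "method": spec.method, "variant": spec.variant,
                                  "predicted_hsi": float(p), "actual_si": float(a),
                                  "abs_error": float(abs(p - a)),
                                  "accurate": bool(abs(p - a) < threshold)})
    report.pairs = pd.DataFrame(
        pair_rows, columns=["month", "i", "j", "method", "variant",
                            "predicted_hsi", "actual_si", "abs_error", "accurate"])
    return report
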
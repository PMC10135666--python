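"""Single-factor Suitability Index (SI) curves.

The SI for month *i* is the larval density normalized by that month's
maximum, ``SI = Y / Y_max`` (so SI lies in [0, 1] and the densest site
scores 1). Each environmental factor X (SST, SSS, Chl-a) gets its own
Gaussian response curve

    SI(x) = exp(A * (x - B)**2),   A < 0,

so the curve peaks at exactly 1 at ``x = B``: B is the factor's optimum
for larvae and A sets how sharply suitability decays away from it
(half-width at SI = 0.5 is sqrt(ln 2 / -A)).

The module fits these curves by nonlinear least squares, tests each fit
against an intercept-only null, extracts optima (dSI/dx = 0 at x = B),
and can parse/format curves in the conventional printed notation
``SI = e^(−a×(X−b)^2)``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    DegenerateMonthError,
    FitFailureError,
    InsufficientDataError,
    InvalidCurveError,
    UnderdeterminedFitError,
)
from .survey_ingest import VARIABLES

MONTH_NAMES = {4: "April", 6: "June", 7: "July", 8: "August", 9: "September"}

#: Published single-factor SI models for fish larvae in the Pearl River
#: Estuary, keyed (month, variable), in the conventional printed notation.
#: These strings are *input data* (a reference coefficient table), used as
#: ground truth by the synthetic generator and as parser fixtures.
REFERENCE_SI_FORMULAS: dict[tuple[int, str], str] = {
    (4, "sst"): "SI = e^(−1.353×(SST−23.197)^2)",
    (4, "sss"): "SI = e^(−0.1238×(SSS−29.0204)^2)",
    (4, "chla"): "SI = e^(−0.3079×(Chla−2.9346)^2)",
    (6, "sst"): "SI = e^(−16.20×(SST−29.64)^2)",
    (6, "sss"): "SI = e^(−0.09026×(SSS−30.24479)^2)",
    (6, "chla"): "SI = e^(−0.154×(Chla−1.878)^2)",
    (7, "sst"): "SI = e^(−18.63×(SST−28.96)^2)",
    (7, "sss"): "SI = e^(−0.06309×(SSS−27.90948)^2)",
    (7, "chla"): "SI = e^(−0.07337×(Chla−4.09307)^2)",
    (8, "sst"): "SI = e^(−11.63×(SST−29.20)^2)",
    (8, "sss"): "SI = e^(−0.04606×(SSS−29.60043)^2)",
    (8, "chla"): "SI = e^(−0.121×(Chla−3.673)^2)",
    (9, "sst"): "SI = e^(−13.02×(SST−28.68)^2)",
    (9, "sss"): "SI = e^(−0.08401×(SSS−24.42966)^2)",
    (9, "chla"): "SI = e^(−0.2262×(Chla−2.3911)^2)",
}


@dataclass
class SISample:
    """One (environmental value, SI) observation for a month/variable."""

    x: float
    si: float
    month: int
    variable: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.si <= 1.0:
            raise ValueError(f"si must lie in [0, 1], got {self.si}")


@dataclass
class SICurve:
    """Fitted Gaussian suitability curve SI(x) = exp(A (x - B)^2), A < 0."""

    variable: str
    month: int
    A: float
    B: float
    n: int = 0
    p_value: float = float("nan")
    B_se: float = float("nan")

    def __post_init__(self) -> None:
        if self.A >= 0:
            raise InvalidCurveError(f"curvature A must be < 0, got {self.A}")
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")

    def __call__(self, x):
        return evaluate_si(self, x)


# ---------------------------------------------------------------------------
# SI computation and curve evaluation
# ---------------------------------------------------------------------------


def compute_si(densities: Sequence[float]) -> np.ndarray:
    """Normalize densities of one month by their maximum: SI = Y / Y_max."""
    dens = np.asarray(densities, dtype=float)
    if dens.size == 0:
        raise DegenerateMonthError("no densities supplied")
    if np.any(dens < 0):
        raise ValueError("densities must be nonnegative")
    y_max = dens.max()
    if y_max <= 0:
        raise DegenerateMonthError("all densities are zero; SI undefined")
    return dens / y_max


def evaluate_si(curve: SICurve, x):
    """SI(x) = exp(A (x - B)^2); vectorized over x, always in (0, 1]."""
    x = np.asarray(x, dtype=float)
    out = np.exp(curve.A * (x - curve.B) ** 2)
    return float(out) if out.ndim == 0 else out


def optimum(curve: SICurve) -> tuple[float, float]:
    """Environmental optimum: the stationary point of the SI curve.

    dSI/dx = 2A (x - B) SI(x) vanishes only at x = B (A < 0 makes it the
    unique maximum), so the optimum is B with standard error B_se.
    """
    if curve.A >= 0:  # defensive; the dataclass enforces this
        raise InvalidCurveError("optimum requires curvature A < 0")
    return curve.B, curve.B_se


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _gauss(x, a, b):
    return np.exp(a * (x - b) ** 2)


def _initial_guess(x: np.ndarray, si: np.ndarray, init_threshold: float) -> tuple[float, float]:
    """Start values from a quadratic regression of ln(si) on x.

    Only points with si above ``init_threshold`` enter (ln of near-zero SI
    is unstable and those points carry little shape information). Falls
    back to a moment-based guess when the parabola is not concave.
    """
    keep = si > init_threshold
    if keep.sum() >= 3 and np.unique(x[keep]).size >= 3:
        c2, c1, _ = np.polyfit(x[keep], np.log(si[keep]), 2)
        if c2 < 0:
            return float(c2), float(-c1 / (2 * c2))
    span = float(np.ptp(x)) or 1.0
    return -1.0 / span**2, float(x[np.argmax(si)])


def fit_si_curve(
    samples: Sequence[SISample] | None = None,
    *,
    x: Sequence[float] | None = None,
    si: Sequence[float] | None = None,
    variable: str | None = None,
    month: int | None = None,
    init_threshold: float = 0.05,
) -> SICurve:
    """Least-squares fit of the Gaussian SI curve to (x, SI) samples.

    Accepts either a sequence of :class:`SISample` or raw ``x``/``si``
    arrays plus ``variable``/``month``. The fit is performed on the SI
    scale (zero-SI points are legitimate observations there), with the
    curvature constrained negative; starting values come from a quadratic
    regression of ln(si) on x.
    """
    if samples is not None:
        if not samples:
            raise UnderdeterminedFitError("no samples")
        x = np.array([s.x for s in samples], dtype=float)
        si = np.array([s.si for s in samples], dtype=float)
        variable = samples[0].variable
        month = samples[0].month
    else:
        if x is None or si is None or variable is None or month is None:
            raise ValueError("provide samples, or x/si/variable/month")
        x = np.asarray(x, dtype=float)
        si = np.asarray(si, dtype=float)
        if x.shape != si.shape:
            raise ValueError("x and si must have the same length")

    n = x.size
    if n < 4:
        raise UnderdeterminedFitError(f"need >= 4 samples, got {n}")
    if np.unique(x).size < 3:
        raise UnderdeterminedFitError("need >= 3 distinct environmental values")
    if not np.any(si > 0):
        raise DegenerateMonthError("all SI values are zero")

    span = float(np.ptp(x)) or 1.0
    b_lo, b_hi = float(x.min()) - span, float(x.max()) + span
    starts = [_initial_guess(x, si, init_threshold)]
    # narrow start: half-width at half maximum around the best observation
    peak_x = float(x[np.argmax(si)])
    high = x[si >= 0.5 * si.max()]
    half_width = max(float(np.ptp(high)) / 2 if high.size > 1 else span / 20,
                     span / 200)
    starts.append((-math.log(2) / half_width**2, peak_x))
    # broad start: SI-weighted moments
    starts.append((-1.0 / span**2, float(np.sum(si * x) / np.sum(si))))

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    last_err: Exception | None = None
    for a0, b0 in starts:
        a0 = min(a0, -1e-8)
        b0 = min(max(b0, b_lo), b_hi)
        try:
            popt, pcov = optimize.curve_fit(
                _gauss, x, si, p0=(a0, b0),
                bounds=((-np.inf, b_lo), (-1e-12, b_hi)),
                maxfev=20000,
            )
        except (RuntimeError, optimize.OptimizeWarning) as exc:
            last_err = exc
            continue
        sse = float(np.sum((si - _gauss(x, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        raise FitFailureError(f"SI fit did not converge: {last_err}")
    _, popt, pcov = best
    a_hat, b_hat = float(popt[0]), float(popt[1])
    b_se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")

    curve = SICurve(variable=variable, month=month, A=a_hat, B=b_hat,
                    n=int(n), B_se=b_se)
    curve.p_value = significance_test(curve, x=x, si=si)
    return curve


def significance_test(
    curve: SICurve,
    samples: Sequence[SISample] | None = None,
    *,
    x: Sequence[float] | None = None,
    si: Sequence[float] | None = None,
) -> float:
    """p-value of the curve's regression against the intercept-only null.

    The residual-sum-of-squares ratio F-test with 2 model degrees of
    freedom, F(2, n-3). The model residual is the better of two
    single-peaked descriptions: the fitted Gaussian curve itself and its
    linearization, the quadratic regression ``si ~ 1 + x + x^2`` (which
    adds exactly two terms to the intercept-only null). The quadratic
    branch keeps the test F-calibrated under the null — the Gaussian
    family contains no free intercept, so its RSS alone can exceed the
    null's and would pin p at 1 — while the Gaussian branch makes a
    perfect nonlinear fit register as such (RSS 0, p 0).
    """
    if samples is not None:
        x = np.array([s.x for s in samples], dtype=float)
        si = np.array([s.si for s in samples], dtype=float)
    x = np.asarray(x, dtype=float)
    si = np.asarray(si, dtype=float)
    n = x.size
    if n <= 3:
        raise InsufficientDataError(f"significance test needs n > 3, got {n}")
    design = np.column_stack([np.ones(n), x, x * x])
    coef, _, _, _ = np.linalg.lstsq(design, si, rcond=None)
    ss_quad = float(np.sum((si - design @ coef) ** 2))
    ss_gauss = float(np.sum((si - _gauss(x, curve.A, curve.B)) ** 2))
    ss_res = min(ss_quad, ss_gauss)
    ss_null = float(np.sum((si - si.mean()) ** 2))
    if ss_null <= 0:  # constant response: nothing to explain
        return 1.0
    if ss_res <= 0:
        return 0.0
    f_stat = ((ss_null - ss_res) / 2) / (ss_res / (n - 3))
    if f_stat <= 0:
        return 1.0
    return float(stats.f.sf(f_stat, 2, n - 3))


# ---------------------------------------------------------------------------
# Printed-notation round trip
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(
    r"""SI\s*=\s*e\s*\^?\s*\(?\s*
        (?P<a>[−\-+]?\s*\d+(?:\.\d+)?)\s*[×x\*]\s*
        \(\s*(?P<lhs>[A-Za-z][A-Za-z\-]*|[−\-+]?\d+(?:\.\d+)?)\s*
        (?P<op>[−\-+])\s*
        (?P<rhs>[A-Za-z][A-Za-z\-]*|\d+(?:\.\d+)?)\s*\)\s*
        \^?\s*2\s*\)?\s*$""",
    re.VERBOSE,
)

_VAR_ALIASES = {"sst": "sst", "sss": "sss", "chla": "chla", "chl-a": "chla",
                "x": None}


def _to_float(token: str) -> float:
    return float(token.replace("−", "-").replace(" ", ""))


def parse_si_formula(text: str, month: int | None = None,
                     variable: str | None = None) -> SICurve:
    """Parse a printed SI model like ``SI = e^(−1.353×(SST−23.197)^2)``.

    Handles unicode minus/multiplication signs and either operand order
    inside the parenthesis: ``(X − b)`` gives B = b, ``(b + X)`` gives
    B = −b (the exponent depends only on (x − B)^2). The variable name in
    the formula fills ``variable`` when not given explicitly.
    """
    m = _FORMULA_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse SI formula: {text!r}")
    a = _to_float(m.group("a"))
    lhs, op, rhs = m.group("lhs"), m.group("op"), m.group("rhs")

    def classify(tok: str):
        try:
            return ("num", _to_float(tok))
        except ValueError:
            return ("var", tok.lower())

    lk, lv = classify(lhs)
    rk, rv = classify(rhs)
    minus = op in ("−", "-")
    if lk == "var" and rk == "num":
        # (X − b)^2 -> B = b ; (X + b)^2 = (X − (−b))^2 -> B = −b
        var_tok, b = lv, rv if minus else -rv
    elif lk == "num" and rk == "var":
        # (b + X)^2 -> B = −b ; (b − X)^2 = (X − b)^2 -> B = b
        var_tok, b = rv, lv if minus else -lv
    else:
        raise ValueError(f"formula needs one variable and one number: {text!r}")
    if a >= 0:
        raise InvalidCurveError(f"parsed curvature must be < 0: {text!r}")
    var = _VAR_ALIASES.get(var_tok, None) if var_tok in _VAR_ALIASES else None
    if variable is None:
        variable = var
    if variable is None:
        raise ValueError(f"cannot infer variable from {text!r}")
    return SICurve(variable=variable, month=month if month is not None else 0,
                   A=a, B=float(b))


def format_si_formula(curve: SICurve, var_label: str | None = None) -> str:
    """Render a curve in the conventional printed notation."""
    label = var_label or {"sst": "SST", "sss": "SSS", "chla": "Chla"}[curve.variable]
    if curve.B >= 0:
        return f"SI = e^(−{abs(curve.A):.10g}×({label}−{curve.B:.10g})^2)"
    return f"SI = e^(−{abs(curve.A):.10g}×({label}+{abs(curve.B):.10g})^2)"


def reference_curves() -> dict[tuple[int, str], SICurve]:
    """The published coefficient table parsed into :class:`SICurve` objects."""
    return {
        (month, var): parse_si_formula(text, month=month, variable=var)
        for (month, var), text in REFERENCE_SI_FORMULAS.items()
    }
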
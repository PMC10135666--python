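"""Suitability-index normalization, Gaussian curve fitting and optima."""

import math

import numpy as np
import pytest

from larvahsi import (
    SICurve,
    compute_si,
    evaluate_si,
    fit_si_curve,
    format_si_formula,
    optimum,
    parse_si_formula,
    significance_test,
)
from larvahsi.errors import (
    DegenerateMonthError,
    InsufficientDataError,
    UnderdeterminedFitError,
)
from larvahsi.si_fit import REFERENCE_SI_FORMULAS


def test_compute_si_normalizes_by_month_maximum():
    np.testing.assert_allclose(compute_si([0, 50, 100]), [0.0, 0.5, 1.0])
    np.testing.assert_allclose(compute_si([7, 7, 7]), [1.0, 1.0, 1.0])
    with pytest.raises(DegenerateMonthError):
        compute_si([0, 0])


def test_evaluate_si_peak_and_one_unit_offset():
    curve = SICurve("sst", 4, A=-1.353, B=23.197)
    assert evaluate_si(curve, 23.197) == 1.0
    # one unit from the optimum the Gaussian drops to exp(A)
    assert evaluate_si(curve, 24.197) == pytest.approx(0.25846370527942, abs=1e-12)
    assert evaluate_si(curve, 24.197) == pytest.approx(math.exp(-1.353))


def test_evaluate_si_unimodal_and_vanishing_tails(published_curves):
    for curve in published_curves.values():
        x_left = curve.B - np.linspace(10, 0, 50)
        x_right = curve.B + np.linspace(0, 10, 50)
        assert np.all(np.diff(evaluate_si(curve, x_left)) >= 0)
        assert np.all(np.diff(evaluate_si(curve, x_right)) <= 0)
        assert evaluate_si(curve, curve.B + 1e3) < 1e-200 or curve.A > -1e-3


@pytest.mark.parametrize("key, printed", [
    ((4, "sst"), 23.2),   # optimum SST for April larvae
    ((6, "sst"), 29.6),
    ((9, "sss"), 24.4),   # optimum SSS for September larvae
])
def test_optimum_is_curve_center(published_curves, key, printed):
    x_opt, _se = optimum(published_curves[key])
    assert round(x_opt, 1) == printed


def test_optimum_invariant_to_curvature():
    assert optimum(SICurve("sst", 4, A=-0.1, B=5.0))[0] == 5.0
    assert optimum(SICurve("sst", 4, A=-2.0, B=5.0))[0] == 5.0


def test_noiseless_fit_recovers_exactly():
    x = np.linspace(24, 34, 20)
    si = np.exp(-0.1 * (x - 29.0) ** 2)
    fit = fit_si_curve(x=x, si=si, variable="sss", month=4)
    assert fit.A == pytest.approx(-0.1, abs=1e-6)
    assert fit.B == pytest.approx(29.0, abs=1e-6)
    assert evaluate_si(fit, fit.B) == 1.0


def test_underdetermined_fits_raise():
    with pytest.raises(UnderdeterminedFitError):
        fit_si_curve(x=[1.0, 1.0, 1.0], si=[0.1, 0.2, 0.3],
                     variable="sst", month=4)
    with pytest.raises(UnderdeterminedFitError):
        fit_si_curve(x=[1.0, 1.0, 1.0, 1.0], si=[0.1, 0.2, 0.3, 0.4],
                     variable="sst", month=4)


def _grid_search_oracle(x, si, a_grid, b_grid):
    """Brute-force least squares over an (A, B) grid."""
    best = (np.inf, None, None)
    for a in a_grid:
        for b in b_grid:
            sse = float(np.sum((si - np.exp(a * (x - b) ** 2)) ** 2))
            if sse < best[0]:
                best = (sse, a, b)
    return best[1], best[2]


def test_noisy_fit_matches_grid_search_oracle():
    """Monte-Carlo check of the April SSS curve against a brute-force
    (A, B) grid search: fitted center within 0.3 of truth and within one
    grid step of the oracle's minimizer."""
    rng = np.random.default_rng(42)
    a_true, b_true = -0.124, 29.02
    x = rng.uniform(22, 34, 200)
    si = np.clip(np.exp(a_true * (x - b_true) ** 2)
                 + rng.normal(0, 0.05, x.size), 0.0, 1.0)
    fit = fit_si_curve(x=x, si=si, variable="sss", month=4)
    assert abs(fit.B - b_true) < 0.3
    a_grid = np.arange(-0.3, -0.02, 0.005)
    b_grid = np.arange(27.0, 31.0, 0.05)
    a_star, b_star = _grid_search_oracle(x, si, a_grid, b_grid)
    assert abs(fit.B - b_star) <= 0.05 + 1e-9
    assert abs(fit.A - a_star) <= 0.005 + 1e-9


def test_mean_center_recovery_over_replicates(published_curves):
    """Over seeded replicates at SI noise 0.05 and n = 200, the mean fitted
    center stays within 0.1 of the true center for all 15 curves."""
    for (month, var), truth in published_curves.items():
        if var == "sst":
            lo, hi = (22, 25) if month == 4 else (28, 30)
        elif var == "sss":
            lo, hi = 22, 34
        else:
            lo, hi = 0, 10
        rng = np.random.default_rng(1000 + 10 * month)
        b_hats = []
        for _ in range(100):
            x = rng.uniform(lo, hi, 200)
            si = np.clip(np.exp(truth.A * (x - truth.B) ** 2)
                         + rng.normal(0, 0.05, 200), 0.0, 1.0)
            b_hats.append(fit_si_curve(x=x, si=si, variable=var, month=month).B)
        assert abs(np.mean(b_hats) - truth.B) < 0.1, (month, var)


def test_significance_perfect_fit_is_decisive():
    x = np.linspace(22, 34, 20)
    si = np.exp(-0.1238 * (x - 29.0204) ** 2)
    fit = fit_si_curve(x=x, si=si, variable="sss", month=4)
    assert fit.p_value < 1e-10


def test_significance_null_is_calibrated():
    """With SI values shuffled against x the p-values are roughly uniform:
    the median over 200 seeded shuffles lies in [0.3, 0.7] (permutation
    oracle for the null distribution)."""
    rng = np.random.default_rng(12345)
    curve = SICurve("sss", 4, A=-0.1238, B=29.0204)
    p_values = []
    for _ in range(200):
        x = rng.uniform(22, 34, 100)
        si = np.clip(np.exp(curve.A * (x - curve.B) ** 2)
                     + rng.normal(0, 0.05, 100), 0.0, 1.0)
        shuffled = rng.permutation(si)
        fit = fit_si_curve(x=x, si=shuffled, variable="sss", month=4)
        p_values.append(fit.p_value)
    assert 0.3 <= float(np.median(p_values)) <= 0.7


def test_significance_requires_enough_samples():
    curve = SICurve("sss", 4, A=-0.1, B=29.0)
    with pytest.raises(InsufficientDataError):
        significance_test(curve, x=[1.0, 2.0, 3.0], si=[0.1, 0.5, 0.2])


def test_all_published_formulas_parse(published_curves):
    assert len(REFERENCE_SI_FORMULAS) == 15
    for (month, var), text in REFERENCE_SI_FORMULAS.items():
        curve = parse_si_formula(text, month=month, variable=var)
        assert curve.A < 0
        assert curve.A == published_curves[(month, var)].A
        assert curve.B == published_curves[(month, var)].B


@pytest.mark.parametrize("text, a, b", [
    ("SI = e^(−0.5×(SST−23.5)^2)", -0.5, 23.5),
    ("SI = e^-0.5*(SST-23.5)^2", -0.5, 23.5),
    ("SI = e^(−0.5×(SST+2.0)^2)", -0.5, -2.0),   # (X + b) centers at -b
    ("SI = e^(−0.5×(23.5−SST)^2)", -0.5, 23.5),  # (b − X) is symmetric
])
def test_parse_handles_notation_variants(text, a, b):
    curve = parse_si_formula(text, month=4, variable="sst")
    assert curve.A == pytest.approx(a) and curve.B == pytest.approx(b)


def test_format_parse_roundtrip():
    for a, b in [(-1.353, 23.197), (-0.04606, 29.60043), (-0.5, -2.25)]:
        curve = SICurve("sss", 7, A=a, B=b)
        back = parse_si_formula(format_si_formula(curve), month=7, variable="sss")
        assert back.A == pytest.approx(a, rel=1e-9)
        assert back.B == pytest.approx(b, rel=1e-9)
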
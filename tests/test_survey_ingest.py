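"""Densities, gridding, compositing and environmental attachment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from larvahsi import (
    CellDensity,
    EnvField,
    GridSpec,
    SurveyRecord,
    aggregate_cells,
    assign_cell,
    attach_env,
    compute_density,
    monthly_composite,
)
from larvahsi.errors import (
    GridMismatchError,
    InvalidCountError,
    InvalidVolumeError,
    MissingFieldError,
    OutOfDomainError,
)
from larvahsi.survey_ingest import (
    mask_invalid,
    read_env_netcdf,
    read_survey_csv,
    regrid_nearest,
    write_env_netcdf,
    write_survey_csv,
)


@pytest.mark.parametrize("count, volume, expected", [
    (50, 0.5, 100.0),
    (0, 1.0, 0.0),
    (7, 2.0, 3.5),
])
def test_density_is_count_over_volume(count, volume, expected):
    assert compute_density(count, volume) == expected


def test_density_rejects_bad_inputs():
    with pytest.raises(InvalidVolumeError):
        compute_density(5, 0.0)
    with pytest.raises(InvalidVolumeError):
        compute_density(5, -1.0)
    with pytest.raises(InvalidCountError):
        compute_density(-1, 1.0)


@pytest.mark.parametrize("lon, lat, expected", [
    (113.10, 21.60, (0, 2)),
    (113.25, 21.00, (1, 0)),  # half-open: the boundary belongs to the upper cell
    (114.999, 22.999, (7, 7)),
])
def test_assign_cell_half_open_boxes(grid, lon, lat, expected):
    assert assign_cell(lon, lat, grid) == expected


def test_assign_cell_outside_domain(grid):
    with pytest.raises(OutOfDomainError):
        assign_cell(112.90, 21.50, grid)
    with pytest.raises(OutOfDomainError):
        assign_cell(113.5, 23.0, grid)  # upper edge is exclusive


@settings(max_examples=200, derandomize=True)
@given(lon=st.floats(113.0, 114.999), lat=st.floats(21.0, 22.999))
def test_assigned_cell_box_contains_point(lon, lat):
    grid = GridSpec(113.0, 21.0, 0.25, 8, 8)
    i, j = assign_cell(lon, lat, grid)
    lon_lo, lon_hi, lat_lo, lat_hi = grid.cell_bounds(i, j)
    assert lon_lo <= lon < lon_hi and lat_lo <= lat < lat_hi


def _rec(lon, lat, month, count, volume=1.0, year=2015, sid="S"):
    return SurveyRecord(station_id=sid, lon=lon, lat=lat, year=year,
                        month=month, count=count, volume=volume)


def test_aggregation_means_and_pools_years(grid):
    records = [
        _rec(113.05, 21.05, 4, 10, year=2014),
        _rec(113.10, 21.10, 4, 30, year=2017),  # same cell, other year
        _rec(113.05, 21.05, 6, 5),              # same cell, other month
    ]
    cells = aggregate_cells(records, grid)
    assert len(cells) == 2
    april = next(c for c in cells if c.month == 4)
    assert april.cell == (0, 0)
    assert april.mean_density == pytest.approx(20.0)
    assert april.n_stations == 2
    assert aggregate_cells([], grid) == []
    only = aggregate_cells(records[:1], grid)[0]
    assert only.mean_density == pytest.approx(10.0) and only.n_stations == 1


def test_aggregation_year_filter(grid):
    records = [_rec(113.05, 21.05, 4, 10, year=2014),
               _rec(113.05, 21.05, 4, 30, year=2018)]
    cells = aggregate_cells(records, grid, years=[2014])
    assert cells[0].n_stations == 1 and cells[0].mean_density == 10.0


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.tuples(st.floats(113.0, 114.99), st.floats(21.0, 22.99),
                          st.integers(0, 50)),
                min_size=1, max_size=30))
def test_aggregation_conserves_total_density(points):
    """Sum over cells of mean_density * n_stations equals the sum of the
    member record densities (per month)."""
    grid = GridSpec(113.0, 21.0, 0.25, 8, 8)
    records = [_rec(lon, lat, 4, count, volume=2.0) for lon, lat, count in points]
    cells = aggregate_cells(records, grid)
    total = sum(c.mean_density * c.n_stations for c in cells)
    assert total == pytest.approx(sum(r.density for r in records))
    assert sum(c.n_stations for c in cells) == len(records)


def _field(grid, values, mask=None, variable="sst", month=4):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isfinite(values)
    return EnvField(variable, "degC", grid, month,
                    np.where(mask, values, np.nan), mask)


def test_monthly_composite_averages_valid_only():
    grid = GridSpec(113.0, 21.0, 0.25, 2, 1)
    f1 = _field(grid, [[20.0, 25.0]])
    f2 = _field(grid, [[22.0, np.nan]])
    f3 = _field(grid, [[np.nan, np.nan]])
    out = monthly_composite([f1, f2, f3])
    assert out.values[0, 0] == pytest.approx(21.0)
    assert out.values[0, 1] == pytest.approx(25.0)
    assert out.mask.all()
    # a cell valid in no input stays masked
    out2 = monthly_composite([f3, f3])
    assert not out2.mask.any()


def test_monthly_composite_identity_and_idempotence(grid, rng):
    values = rng.uniform(20, 30, grid.shape)
    f = _field(grid, values)
    single = monthly_composite([f])
    np.testing.assert_allclose(single.values, values)
    triple = monthly_composite([f, f, f])
    np.testing.assert_allclose(triple.values, values)


def test_monthly_composite_rejects_grid_mismatch(grid):
    other = GridSpec(113.0, 21.0, 0.25, 4, 4)
    with pytest.raises(GridMismatchError):
        monthly_composite([
            _field(grid, np.full(grid.shape, 20.0)),
            _field(other, np.full(other.shape, 20.0)),
        ])


def test_attach_env_values_missing_and_flags(grid):
    cells = [CellDensity(cell=(0, 2), month=4, mean_density=5.0, n_stations=1)]
    values = np.full(grid.shape, 23.0)
    sst = _field(grid, values, variable="sst")
    sss = EnvField("sss", "1", grid, 4, np.full(grid.shape, 30.0),
                   np.ones(grid.shape, bool))
    chla = EnvField("chla", "mg m-3", grid, 4, np.full(grid.shape, 2.0),
                    np.ones(grid.shape, bool))
    out = attach_env(cells, [sst, sss, chla])
    assert out[0].env["sst"] == pytest.approx(23.0)
    assert out[0].complete

    masked = np.ones(grid.shape, bool)
    masked[2, 0] = False
    sst_masked = EnvField("sst", "degC", grid, 4,
                          np.where(masked, values, np.nan), masked)
    out = attach_env(cells, [sst_masked, sss, chla])
    assert out[0].env["sst"] is None and not out[0].complete

    with pytest.raises(MissingFieldError):
        attach_env(cells, [sst, sss])  # no chla field for April


def test_mask_invalid_sentinels_and_negative_chla():
    raw = np.array([20.0, -9999.0, np.nan, -0.5])
    assert mask_invalid(raw, "sst").tolist() == [True, False, False, True]
    assert mask_invalid(raw, "chla").tolist() == [True, False, False, False]


def test_survey_csv_roundtrip(tmp_path, grid):
    records = [_rec(113.05, 21.05, 4, 10, volume=0.4, sid="A"),
               _rec(114.30, 22.30, 9, 0, volume=0.2, sid="B")]
    path = tmp_path / "survey.csv"
    write_survey_csv(records, path)
    back = read_survey_csv(path, grid=grid)
    assert [r.station_id for r in back] == ["A", "B"]
    assert back[0].density == pytest.approx(25.0)  # recomputed, never read
    assert back[1].density == 0.0


def test_env_netcdf_roundtrip(tmp_path, grid, rng):
    fields = []
    for var, units in (("sst", "degC"), ("sss", "1"), ("chla", "mg m-3")):
        values = rng.uniform(1, 30, grid.shape)
        mask = rng.random(grid.shape) > 0.2
        fields.append(EnvField(var, units, grid, 6,
                               np.where(mask, values, np.nan), mask))
    path = tmp_path / "env_06.nc"
    write_env_netcdf(fields, path)
    back = read_env_netcdf(path)
    assert {f.variable for f in back} == {"sst", "sss", "chla"}
    for orig in fields:
        echo = next(f for f in back if f.variable == orig.variable)
        assert echo.month == 6 and echo.grid == grid
        np.testing.assert_array_equal(echo.mask, orig.mask)
        np.testing.assert_allclose(echo.values[echo.mask],
                                   orig.values[orig.mask], rtol=1e-6)


def test_regrid_nearest_identity_and_downscale(grid):
    f = _field(grid, np.arange(64, dtype=float).reshape(grid.shape))
    assert regrid_nearest(f, grid) is f
    fine = GridSpec(113.0, 21.0, 0.125, 16, 16)
    out = regrid_nearest(f, fine)
    # each fine cell takes the value of the coarse cell containing its center
    assert out.values[0, 0] == f.values[0, 0]
    assert out.values[15, 15] == f.values[7, 7]
    assert out.values[2, 3] == f.values[1, 1]
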
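"""Regridding and climatology against brute-force oracles."""

import numpy as np
import pytest
import xarray as xr

from hazecrop import aod_processing as ap


def make_field(values, res=0.1, lat0=30.0, lon0=110.0):
    values = np.asarray(values, dtype=float)
    nlat, nlon = values.shape
    return xr.DataArray(
        values,
        coords={
            "lat": lat0 + res * (np.arange(nlat) + 0.5),
            "lon": lon0 + res * (np.arange(nlon) + 0.5),
        },
        dims=("lat", "lon"),
        name="aod",
    )


def brute_force_block_mean(values, factor):
    """Independent loop-over-blocks oracle for the block average."""
    nlat, nlon = values.shape
    out = np.full((nlat // factor, nlon // factor), np.nan)
    for bi in range(out.shape[0]):
        for bj in range(out.shape[1]):
            block = values[bi * factor:(bi + 1) * factor, bj * factor:(bj + 1) * factor]
            if np.isfinite(block).any():
                out[bi, bj] = np.nanmean(block.ravel())
    return out


class TestRegrid:
    def test_constant_block_gives_constant(self):
        coarse = ap.regrid_block_average(make_field(np.full((5, 5), 0.4)), 5)
        assert coarse.shape == (1, 1)
        assert coarse.values.item() == pytest.approx(0.4)

    def test_single_survivor_mean(self):
        vals = np.full((5, 5), np.nan)
        vals[2, 3] = 0.6
        coarse = ap.regrid_block_average(make_field(vals), 5)
        assert coarse.values.item() == pytest.approx(0.6)

    def test_all_missing_block_stays_masked(self):
        coarse = ap.regrid_block_average(make_field(np.full((5, 5), np.nan)), 5)
        assert np.isnan(coarse.values.item())

    def test_matches_brute_force_bitwise_on_random_field(self):
        rng = np.random.default_rng(42)
        vals = rng.uniform(0, 1, (10, 10))
        vals[rng.random((10, 10)) < 0.3] = np.nan
        coarse = ap.regrid_block_average(make_field(vals), 5)
        expected = brute_force_block_mean(vals, 5)
        np.testing.assert_array_equal(coarse.values, expected)

    def test_coarse_centres_at_block_centroids(self):
        coarse = ap.regrid_block_average(make_field(np.zeros((10, 10))), 5)
        # fine centres 30.05..30.95; first block centroid (30.05+...+30.45)/5
        assert coarse["lat"].values == pytest.approx([30.25, 30.75])

    def test_non_divisible_axis_named_in_error(self):
        with pytest.raises(ValueError, match="lon"):
            ap.regrid_block_average(make_field(np.zeros((10, 9))), 5)

    def test_min_valid_fraction_masks_sparse_blocks(self):
        vals = np.full((5, 5), np.nan)
        vals[0, 0] = 0.5
        field = make_field(vals)
        assert ap.regrid_block_average(field, 5).values.item() == pytest.approx(0.5)
        strict = ap.regrid_block_average(field, 5, min_valid_fraction=0.5)
        assert np.isnan(strict.values.item())

    def test_regional_mean_preserved_without_masking(self):
        """Coarse-grid mean equals fine-grid mean when nothing is missing."""
        rng = np.random.default_rng(1)
        field = make_field(rng.uniform(0, 1, (20, 20)))
        coarse = ap.regrid_block_average(field, 5)
        assert float(coarse.mean()) == pytest.approx(float(field.mean()), abs=1e-12)


def make_series(stamps, fields):
    import pandas as pd

    arr = np.stack([np.asarray(f, dtype=float) for f in fields])
    nlat, nlon = arr.shape[1:]
    time = pd.to_datetime([f"{y}-{m:02d}-01" for y, m in stamps])
    da = xr.DataArray(
        arr,
        coords={"time": time,
                "lat": 30 + 0.5 * np.arange(nlat), "lon": 110 + 0.5 * np.arange(nlon)},
        dims=("time", "lat", "lon"),
        name="aod",
    )
    return da.assign_coords(month=("time", [m for _, m in stamps]))


class TestClimatology:
    def test_two_januaries_average(self):
        series = make_series(
            [(2010, 1), (2011, 1)], [np.full((2, 2), 0.3), np.full((2, 2), 0.5)]
        )
        clim = ap.monthly_climatology(series)
        assert clim.sel(month=1).values == pytest.approx(np.full((2, 2), 0.4))

    def test_cell_never_observed_stays_masked(self):
        jan = np.array([[np.nan, 0.2], [0.3, 0.4]])
        series = make_series([(2010, 1), (2011, 1)], [jan, jan])
        clim = ap.monthly_climatology(series).sel(month=1)
        assert np.isnan(clim.values[0, 0]) and clim.values[0, 1] == pytest.approx(0.2)

    def test_25_month_series_matches_accumulation_oracle(self):
        rng = np.random.default_rng(5)
        stamps = [(2010 + (m - 1) // 12, (m - 1) % 12 + 1) for m in range(4, 29)]
        fields = []
        for _ in stamps:
            f = rng.uniform(0, 1, (4, 4))
            f[rng.random((4, 4)) < 0.3] = np.nan
            fields.append(f)
        clim = ap.monthly_climatology(make_series(stamps, fields))
        # independent per-month accumulation
        for month in range(1, 13):
            member = [f for (y, m), f in zip(stamps, fields) if m == month]
            stack = np.stack(member)
            with np.errstate(invalid="ignore"):
                expected = np.nanmean(stack, axis=0)
            np.testing.assert_array_equal(clim.sel(month=month).values, expected)

    def test_constant_series_returns_constant(self):
        stamps = [(2010, m) for m in range(1, 13)]
        clim = ap.monthly_climatology(make_series(stamps, [np.full((3, 3), 0.7)] * 12))
        assert (clim.values == 0.7).all()

    def test_empty_series_rejected(self):
        series = make_series([(2010, 1)], [np.zeros((2, 2))]).isel(time=[])
        with pytest.raises(ValueError, match="empty"):
            ap.monthly_climatology(series)


class TestSeasonalMeans:
    @pytest.fixture()
    def monthly(self):
        vals = np.zeros((12, 2, 2))
        for i in range(12):
            vals[i] = i + 1.0
        stamps = [(2010, m) for m in range(1, 13)]
        return ap.monthly_climatology(make_series(stamps, list(vals)))

    def test_djf_is_mean_of_member_months(self, monthly):
        monthly.loc[{"month": 12}] = 0.6
        monthly.loc[{"month": 1}] = 0.8
        monthly.loc[{"month": 2}] = 0.7
        seas = ap.seasonal_means(monthly)
        assert seas["mean"].sel(season="DJF").values == pytest.approx(
            np.full((2, 2), 0.7)
        )
        assert (seas["n_months"].sel(season="DJF").values == 3).all()

    def test_masked_member_month_drops_from_mean(self, monthly):
        monthly.loc[{"month": 12, "lat": monthly["lat"][0], "lon": monthly["lon"][0]}] = np.nan
        seas = ap.seasonal_means(monthly)
        # remaining members are Jan=1 and Feb=2 -> mean 1.5
        assert seas["mean"].sel(season="DJF").values[0, 0] == pytest.approx(1.5)
        assert seas["n_months"].sel(season="DJF").values[0, 0] == 2

    def test_full_year_matches_brute_force_three_month_means(self, monthly):
        seas = ap.seasonal_means(monthly)
        for name, members in ap.SEASONS.items():
            expected = np.nanmean(
                np.stack([monthly.sel(month=m).values for m in members]), axis=0
            )
            np.testing.assert_array_equal(seas["mean"].sel(season=name).values, expected)

    def test_incomplete_year_rejected(self, monthly):
        with pytest.raises(ValueError, match="12"):
            ap.seasonal_means(monthly.sel(month=[1, 2, 3]))
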
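"""Full impact-report assembly on small hand-built reduction fields."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from hazecrop import crop_impact as ci
from hazecrop import synthetic_data as sd
from hazecrop.regions import default_regions
from hazecrop.solar_reduction import growing_window_mean


def build_fields(reduction_by_month, lats, lons):
    """Reduction Dataset with consistent direct/diffuse components.

    ``reduction_by_month`` maps month -> (lat, lon) fractional loss array;
    baseline split is 75% direct / 25% diffuse, both scaled equally so the
    cellwise global reduction equals the given fraction.
    """
    months = sorted(reduction_by_month)
    shape = (len(months), len(lats), len(lons))
    r = np.stack([np.asarray(reduction_by_month[m], dtype=float) for m in months])
    db = np.full(shape, 300.0)
    fb = np.full(shape, 100.0)
    da, fa = db * (1 - r), fb * (1 - r)
    coords = {"month": months, "lat": list(lats), "lon": list(lons)}
    dims = ("month", "lat", "lon")
    return xr.Dataset(
        {
            "reduction": (dims, 100.0 * ((db + fb) - (da + fa)) / (db + fb)),
            "direct_base": (dims, db),
            "diffuse_base": (dims, fb),
            "direct_aer": (dims, da),
            "diffuse_aer": (dims, fa),
        },
        coords=coords,
    )


@pytest.fixture(scope="module")
def uniform_fields():
    """10% loss everywhere, all 12 months, cells inside every region box."""
    lats = [35.0, 30.0, 29.0, 29.5]  # one row through each region's band
    lons = [115.0, 118.0, 112.0, 105.0]
    return build_fields({m: np.full((4, 4), 0.10) for m in range(1, 13)}, lats, lons)


@pytest.fixture(scope="module")
def models():
    return {
        "wheat": ci.YieldResponseModel("wheat", 0.4267),
        "rice": ci.YieldResponseModel("rice", 0.2189),
    }


@pytest.fixture(scope="module")
def table():
    return sd.generate_production_table(seed=0)


def test_zero_aod_everywhere_gives_all_zero_report(models, table):
    lats = [35.0, 30.0, 29.0, 29.5]
    lons = [115.0, 118.0, 112.0, 105.0]
    fields = build_fields({m: np.zeros((4, 4)) for m in range(1, 13)}, lats, lons)
    report = ci.build_report(fields, table, models)
    assert (report.regional["yield_reduction_pct"] == 0).all()
    assert (report.regional["production_loss_tonnes"] == 0).all()
    assert (report.national["national_reduction_pct"] == 0).all()
    assert (report.national["national_loss_tonnes"] == 0).all()


def test_k_equal_one_case_equals_plain_reduction_bitwise(uniform_fields, models, table):
    """The 'none' diffuse case must reproduce the unweighted global-reduction
    pipeline bit-for-bit."""
    report = ci.build_report(uniform_fields, table, models)
    none_rows = report.regional[report.regional["case"] == "none"]
    regions = {r.name: r for r in default_regions()}
    for _, row in none_rows.iterrows():
        reg = regions[row["region"]]
        mask = reg.mask(uniform_fields["reduction"])
        plain = uniform_fields["reduction"].where(mask)
        monthly = {
            int(m): float(plain.sel(month=m).mean(skipna=True))
            for m in uniform_fields["month"].values
        }
        sub = table[(table["crop"] == row["crop"]) & (table["region"] == row["region"])]
        wins = [growing_window_mean(monthly, int(h)) for h in sub["harvest_month"]]
        expected = float(np.average(wins, weights=sub["production_tonnes"]))
        assert row["window_radiation_reduction_pct"] == expected  # bitwise


def test_uniform_loss_report_matches_hand_arithmetic(uniform_fields, models, table):
    report = ci.build_report(uniform_fields, table, models)
    none = report.national[report.national["case"] == "none"]
    wheat = none[none["crop"] == "wheat"].iloc[0]
    # every region window is exactly 10% -> yield loss beta*10 everywhere
    expected_pct = 0.4267 * 10.0 * 0.75
    assert wheat["national_reduction_pct"] == pytest.approx(expected_pct, rel=1e-12)
    rice = none[none["crop"] == "rice"].iloc[0]
    assert rice["national_reduction_pct"] == pytest.approx(0.2189 * 10.0 * 0.45, rel=1e-12)


def test_tonnage_percent_identity(uniform_fields, models, table):
    """tonnes / national production x 100 equals the reported percent."""
    report = ci.build_report(uniform_fields, table, models)
    totals = table.groupby("crop")["production_tonnes"].sum()
    for _, row in report.national.iterrows():
        implied = 100.0 * row["national_loss_tonnes"] / totals[row["crop"]]
        assert implied == pytest.approx(row["national_reduction_pct"], rel=1e-12)


def test_higher_k_never_increases_loss_for_proportional_scaling(
    uniform_fields, models, table
):
    """With direct and diffuse scaled equally, k > 1 leaves the effective
    reduction unchanged; losses must not increase."""
    report = ci.build_report(uniform_fields, table, models)
    nat = report.national.set_index(["crop", "case"])
    for crop in ("wheat", "rice"):
        base = nat.loc[(crop, "none"), "national_reduction_pct"]
        for case in ("low", "moderate", "high"):
            assert nat.loc[(crop, case), "national_reduction_pct"] <= base + 1e-12


def test_diffuse_fertilization_reduces_loss_when_diffuse_rises(models, table):
    """Aerosol converts direct to diffuse: k > 1 must soften the loss."""
    lats, lons = [35.0], [115.0]
    months = {}
    for m in range(1, 13):
        months[m] = np.full((1, 1), 0.2)
    fields = build_fields(months, lats, lons)
    # re-partition the perturbed fluxes: same global, more diffuse
    fields["direct_aer"] -= 60.0
    fields["diffuse_aer"] += 60.0
    report = ci.build_report(fields, table, models)
    nat = report.national.set_index(["crop", "case"])
    assert (
        nat.loc[("wheat", "high"), "national_reduction_pct"]
        < nat.loc[("wheat", "none"), "national_reduction_pct"]
    )


def test_cloud_adjusted_columns_scale_by_one_minus_fraction(
    uniform_fields, models, table
):
    report = ci.build_report(uniform_fields, table, models, cloud_fraction=0.25)
    nat = report.national
    assert nat["national_reduction_pct_cloud_adjusted"].values == pytest.approx(
        0.75 * nat["national_reduction_pct"].values
    )


def test_missing_harvest_month_skips_pair_with_warning(models, caplog):
    lats, lons = [35.0], [115.0]
    fields = build_fields({m: np.full((1, 1), 0.1) for m in range(1, 13)}, lats, lons)
    table = pd.DataFrame(
        {
            "province": ["Henan", "Rest of China"],
            "region": ["NCP", ""],
            "crop": ["wheat", "wheat"],
            "production_tonnes": [1e8, 1.5e8],
            "harvest_month": [np.nan, np.nan],
        }
    )
    import logging

    with caplog.at_level(logging.WARNING, logger="hazecrop.crop_impact"):
        report = ci.build_report(fields, table, models)
    assert report.regional.empty
    assert any("harvest" in r.message for r in caplog.records)
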
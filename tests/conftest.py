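import numpy as np
import pytest
import xarray as xr

from hazecrop import aod_processing, solar_reduction, synthetic_data
from hazecrop.radiative_transfer import RTConfig, make_spectral_grid
from hazecrop.regions import default_regions


@pytest.fixture(scope="session")
def regions():
    return default_regions()


@pytest.fixture(scope="session")
def fast_rt():
    """Coarse spectral/diurnal resolution for unit tests of plumbing."""
    return RTConfig(wavelength_step=25.0, diurnal_nodes=6)


@pytest.fixture(scope="session")
def spectral_small():
    return make_spectral_grid(25.0)


def small_aod_field(values, lats=(33.0, 35.0), lons=(114.0, 116.0)):
    """Tiny (lat, lon) AOD field helper for reduction tests."""
    values = np.asarray(values, dtype=float)
    return xr.DataArray(
        values,
        coords={"lat": np.asarray(lats), "lon": np.asarray(lons)},
        dims=("lat", "lon"),
        name="aod",
    )


@pytest.fixture(scope="session")
def study_run(regions):
    """The default synthetic study conditions, run end to end once.

    Seed-0 monthly AOD record at 0.1 deg -> 0.5 deg block average ->
    monthly climatology -> reduction fields over the four region boxes at
    the default optics (1 nm spectral grid, 24 diurnal nodes), plus the
    default production table.
    """
    aod = synthetic_data.generate_aod_fields(synthetic_data.SyntheticAODConfig(seed=0))
    coarse = aod_processing.regrid_block_average(aod, 5)
    clim = aod_processing.monthly_climatology(coarse)
    where = xr.concat([r.mask(clim.isel(month=0)) for r in regions], dim="r").any("r")
    fields = solar_reduction.monthly_reduction_maps(clim, RTConfig(), where)
    table = synthetic_data.generate_production_table(seed=0)
    return {"aod": aod, "clim": clim, "fields": fields, "table": table}
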
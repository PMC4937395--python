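"""Quality handling, regridding and climatology of monthly AOD fields.

High-resolution satellite AOD retrievals are patchy (cloud cover, bright
surfaces), so the analysis first block-averages the 0.1-degree fields to a
0.5-degree grid using every available fine cell, then forms per-calendar-month
and seasonal climatologies.  Missing cells are NaN throughout; a coarse cell
is missing only when *all* of its fine members are missing (maximal data
retention), with the required fraction of valid members exposed as an option.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

SEASONS: dict[str, tuple[int, int, int]] = {
    "DJF": (12, 1, 2),
    "MAM": (3, 4, 5),
    "JJA": (6, 7, 8),
    "SON": (9, 10, 11),
}


def _check_grid(da: xr.DataArray) -> None:
    for axis in ("lat", "lon"):
        vals = da[axis].values
        if vals.size < 2:
            raise ValueError(f"degenerate grid: axis {axis!r} has fewer than 2 cells")
        steps = np.diff(vals)
        if not (steps > 0).all():
            raise ValueError(f"axis {axis!r} must be strictly ascending")
        if not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError(f"axis {axis!r} spacing is not uniform")
    if (da.values[np.isfinite(da.values)] < 0).any():
        raise ValueError("AOD must be >= 0 wherever unmasked")


def regrid_block_average(
    grid: xr.DataArray, factor: int = 5, min_valid_fraction: float = 0.0
) -> xr.DataArray:
    """Block-average a fine field onto a coarser grid.

    Each coarse cell is the arithmetic mean of its unmasked fine members and
    sits at the centroid of its ``factor x factor`` block.  With the default
    ``min_valid_fraction=0`` a coarse cell is masked only when every fine
    member is masked.

    Raises ``ValueError`` (naming the axis) if ``factor`` does not divide an
    axis length.
    """
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    _check_grid(grid)
    for axis in ("lat", "lon"):
        n = grid.sizes[axis]
        if n % factor:
            raise ValueError(
                f"factor {factor} does not divide axis {axis!r} length {n}"
            )
    # explicit block reshape so each coarse value is np.nanmean over its
    # 25 fine members in row-major order (bitwise-reproducible by a loop)
    da = grid.transpose(..., "lat", "lon")
    vals = da.values
    lead = vals.shape[:-2]
    nlat, nlon = vals.shape[-2:]
    blocks = vals.reshape(
        *lead, nlat // factor, factor, nlon // factor, factor
    ).swapaxes(-3, -2).reshape(*lead, nlat // factor, nlon // factor, factor * factor)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(blocks, axis=-1)
    if min_valid_fraction > 0:
        frac = np.isfinite(blocks).mean(axis=-1)
        mean = np.where(frac >= min_valid_fraction, mean, np.nan)
    coords = {
        k: v for k, v in da.coords.items() if "lat" not in v.dims and "lon" not in v.dims
    }
    coords["lat"] = da["lat"].values.reshape(-1, factor).mean(axis=1)
    coords["lon"] = da["lon"].values.reshape(-1, factor).mean(axis=1)
    coarse = xr.DataArray(mean, coords=coords, dims=da.dims, name=da.name)
    coarse.attrs.update(grid.attrs)
    return coarse


def monthly_climatology(series: xr.DataArray) -> xr.DataArray:
    """Per-calendar-month mean fields over a multi-year monthly series.

    ``series`` must have a ``time`` dim with a ``month`` coordinate (as
    produced by the synthetic generator) or a datetime ``time`` coordinate.
    Returns a field with a ``month`` dim (only observed months present; a
    full record yields all 12).  Cells never observed in a month are NaN.
    """
    if series.sizes.get("time", 0) == 0:
        raise ValueError("empty series")
    if "month" in series.coords:
        key = series["month"]
    else:
        key = series["time"].dt.month
    with np.errstate(invalid="ignore"):
        clim = series.groupby(key.rename("month")).mean("time", skipna=True)
    return clim


def seasonal_means(monthly: xr.DataArray) -> xr.Dataset:
    """Seasonal (DJF/MAM/JJA/SON) climatologies from 12 monthly mean fields.

    Each seasonal mean is the cellwise mean of its three member months over
    unmasked members, with a count of contributing months carried alongside.
    """
    if "month" not in monthly.dims or monthly.sizes["month"] != 12:
        raise ValueError("need all 12 monthly fields")
    means, counts = [], []
    for season, members in SEASONS.items():
        sel = monthly.sel(month=list(members))
        with np.errstate(invalid="ignore"):
            means.append(sel.mean("month", skipna=True))
        counts.append(sel.notnull().sum("month"))
    season_idx = xr.DataArray(list(SEASONS), dims="season", name="season")
    return xr.Dataset(
        {
            "mean": xr.concat(means, dim=season_idx),
            "n_months": xr.concat(counts, dim=season_idx),
        }
    )
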
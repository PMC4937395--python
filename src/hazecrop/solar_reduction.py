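"""Percent reduction of surface solar irradiance due to aerosol.

For every unmasked grid cell the two-stream pipeline is run twice — once
aerosol-free (the baseline E0) and once with the cell's AOD (E_a) — and the
reduction is ``100 * (E0 - E_a) / E0``.  The baseline depends only on
latitude and month and is cached.  Reduction fields keep the direct and
diffuse components of both runs so that diffuse-weighted sensitivity cases
can be formed downstream.

Regional statistics use quartiles (linear interpolation between closest
ranks) over unmasked region cells; seasonal statistics pool the cell values
of the three member months.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .aod_processing import SEASONS
from .radiative_transfer import RTConfig, make_spectral_grid, solar_geometry, surface_irradiance
from .radiative_transfer.geometry import MONTH_MID_DOY
from .regions import RegionDefinition

logger = logging.getLogger(__name__)

_COMPONENTS = ("reduction", "direct_base", "diffuse_base", "direct_aer", "diffuse_aer")


def reduction_map(
    aod: xr.DataArray,
    month: int,
    rt_config: RTConfig = RTConfig(),
    where: xr.DataArray | None = None,
    _baseline_cache: dict | None = None,
) -> xr.Dataset:
    """Percent-reduction field for one monthly mean AOD field.

    ``aod`` is a (lat, lon) field (NaN = missing); ``month`` selects the
    representative day (the 15th).  ``where`` optionally restricts the
    computation to a boolean sub-mask (cells outside it come back NaN).
    Returns a Dataset with ``reduction`` plus the baseline and perturbed
    direct/diffuse daily means.  Cells where the solver fails are masked and
    counted in the log.
    """
    if month not in MONTH_MID_DOY:
        raise ValueError("month must be 1..12")
    spectral = make_spectral_grid(rt_config.wavelength_step)
    cache = {} if _baseline_cache is None else _baseline_cache

    lat = aod["lat"].values
    data = {k: np.full(aod.shape, np.nan) for k in _COMPONENTS}
    valid = np.isfinite(aod.values)
    if where is not None:
        valid &= np.asarray(where.values, dtype=bool)
    n_failed = 0
    doy = MONTH_MID_DOY[month]
    for i, j in zip(*np.nonzero(valid)):
        key = (float(lat[i]), month)
        try:
            if key not in cache:
                geom = solar_geometry(lat[i], doy, rt_config.diurnal_nodes)
                cache[key] = (geom, surface_irradiance(0.0, geom, spectral, rt_config))
            geom, base = cache[key]
            pert = surface_irradiance(
                float(aod.values[i, j]), geom, spectral, rt_config
            )
        except (ValueError, RuntimeError) as err:
            n_failed += 1
            logger.warning("cell (%d, %d) failed: %s", i, j, err)
            continue
        data["reduction"][i, j] = 100.0 * (base.global_ - pert.global_) / base.global_
        data["direct_base"][i, j] = base.direct
        data["diffuse_base"][i, j] = base.diffuse
        data["direct_aer"][i, j] = pert.direct
        data["diffuse_aer"][i, j] = pert.diffuse
    if n_failed:
        logger.warning("reduction_map: %d cells failed and were masked", n_failed)
    ds = xr.Dataset(
        {k: (aod.dims, v) for k, v in data.items()}, coords=aod.coords
    )
    ds["reduction"].attrs["units"] = "%"
    ds.attrs["month"] = month
    return ds


def monthly_reduction_maps(
    monthly_aod: xr.DataArray,
    rt_config: RTConfig = RTConfig(),
    where: xr.DataArray | None = None,
) -> xr.Dataset:
    """Reduction fields for a 12-month climatology (``month`` dim), sharing
    one baseline cache across months."""
    cache: dict = {}
    out = [
        reduction_map(
            monthly_aod.sel(month=m), int(m), rt_config, where, _baseline_cache=cache
        )
        for m in monthly_aod["month"].values
    ]
    return xr.concat(out, dim=monthly_aod["month"])


def region_percentiles(
    fields: xr.Dataset | xr.DataArray,
    regions: Sequence[RegionDefinition],
    pooled_label: str = "ALL4",
) -> pd.DataFrame:
    """Quartiles (Q1, median, Q3) of cellwise reduction per region and season.

    ``fields`` is a reduction field with a ``month`` dim (seasonal rows pool
    the member months' cells) or a single-month field.  A pooled row over
    all given regions is emitted under ``pooled_label``.
    """
    red = fields["reduction"] if isinstance(fields, xr.Dataset) else fields
    rows = []
    seasons: dict[str, xr.DataArray]
    if "month" in red.dims:
        seasons = {s: red.sel(month=[m for m in mem if m in red["month"].values])
                   for s, mem in SEASONS.items()}
    else:
        seasons = {"single": red}

    def _stats(values: np.ndarray):
        values = values[np.isfinite(values)]
        if values.size == 0:
            return None
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        return q1, med, q3, values.size

    for season, field in seasons.items():
        pooled = []
        for reg in regions:
            mask = reg.mask(field).values
            vals = field.values[..., mask] if field.ndim > 2 else field.values[mask]
            pooled.append(vals.ravel())
            st = _stats(vals.ravel())
            if st is None:
                logger.warning("region %s has no unmasked cells in %s", reg.name, season)
                continue
            rows.append({"region": reg.name, "season": season,
                         "q1": st[0], "median": st[1], "q3": st[2], "n_cells": st[3]})
        st = _stats(np.concatenate(pooled)) if pooled else None
        if st is not None:
            rows.append({"region": pooled_label, "season": season,
                         "q1": st[0], "median": st[1], "q3": st[2], "n_cells": st[3]})
    return pd.DataFrame(rows)


def harvest_window_months(harvest_month: int) -> list[int]:
    """The three calendar months immediately before harvest (wrapping)."""
    if not (1 <= int(harvest_month) <= 12):
        raise ValueError("harvest month must be 1..12")
    h = int(harvest_month)
    return [(h - k - 1) % 12 + 1 for k in (3, 2, 1)]


def growing_window_mean(
    monthly_values: Mapping[int, float] | Sequence[float] | xr.DataArray,
    harvest_month: int,
) -> float:
    """Mean reduction over the three months before harvest.

    ``monthly_values`` maps month (1-12) to a reduction, or is a length-12
    sequence in calendar order, or a DataArray with a ``month`` dim (cells
    are averaged after the window mean; for a region series pass the
    region-mean values).
    """
    window = harvest_window_months(harvest_month)
    if isinstance(monthly_values, xr.DataArray):
        sel = monthly_values.sel(month=window)
        return float(sel.mean("month").mean(skipna=True))
    if isinstance(monthly_values, Mapping):
        return float(np.mean([monthly_values[m] for m in window]))
    vals = list(monthly_values)
    if len(vals) != 12:
        raise ValueError("need 12 monthly values in calendar order")
    return float(np.mean([vals[m - 1] for m in window]))


def region_monthly_means(
    fields: xr.Dataset | xr.DataArray,
    regions: Iterable[RegionDefinition],
    variables: Sequence[str] = _COMPONENTS,
) -> pd.DataFrame:
    """Unweighted means of reduction components over each region's unmasked
    cells, per month.  Long-format frame: region, month, variable, value."""
    ds = fields if isinstance(fields, xr.Dataset) else fields.to_dataset(name="reduction")
    rows = []
    for reg in regions:
        mask = reg.mask(ds["reduction"])
        for var in variables:
            if var not in ds:
                continue
            sub = ds[var].where(mask)
            for m in np.atleast_1d(ds["month"].values) if "month" in ds.dims else [ds.attrs.get("month")]:
                field = sub.sel(month=m) if "month" in sub.dims else sub
                rows.append({"region": reg.name, "month": int(m), "variable": var,
                             "value": float(field.mean(skipna=True))})
    return pd.DataFrame(rows)
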
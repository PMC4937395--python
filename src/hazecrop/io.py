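"""File formats: CF-style NetCDF for gridded fields, CSV for tables.

NetCDF is written through xarray's scipy backend (NetCDF-3 classic) so the
files are portable plain HDF-free containers; missing cells round-trip as a
fill value.  The flat CSV dialect for AOD is ``lon, lat, month, aod``; the
production table is ``province, region, crop, production_tonnes,
harvest_month``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import xarray as xr

_FILL = -9999.0
PRODUCTION_COLUMNS = ["province", "region", "crop", "production_tonnes", "harvest_month"]


def write_netcdf(data: xr.DataArray | xr.Dataset, path: str | Path) -> None:
    """Write a field with a fill value for NaN cells (NetCDF-3 classic)."""
    ds = data.to_dataset() if isinstance(data, xr.DataArray) else data
    encoding = {v: {"_FillValue": _FILL} for v in ds.data_vars}
    ds.to_netcdf(path, engine="scipy", encoding=encoding)


def read_netcdf(path: str | Path) -> xr.Dataset:
    """Read a field written by :func:`write_netcdf`; fill values become NaN."""
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


def aod_to_csv(aod: xr.DataArray, path: str | Path) -> None:
    """Flat CSV dialect: lon, lat, month, aod (missing cells omitted)."""
    df = aod.to_dataframe().reset_index()
    if "month" not in df.columns and "time" in df.columns:
        df["month"] = pd.to_datetime(df["time"]).dt.month
    df = df.dropna(subset=["aod"])[["lon", "lat", "month", "aod"]]
    df.to_csv(path, index=False)


def write_production_table(table: pd.DataFrame, path: str | Path) -> None:
    table[PRODUCTION_COLUMNS].to_csv(path, index=False)


def read_production_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"region": "string"})
    missing = set(PRODUCTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"production table missing columns: {sorted(missing)}")
    df["region"] = df["region"].fillna("").astype(str)
    if (df["production_tonnes"] < 0).any():
        raise ValueError("production must be >= 0")
    if df.duplicated(subset=["province", "crop"]).any():
        raise ValueError("duplicate (province, crop) rows")
    return df
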
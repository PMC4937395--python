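"""Synthetic monthly AOD fields and crop production tables.

The downstream analysis was designed around a satellite aerosol-optical-depth
(AOD) climatology over China: monthly 0.1-degree fields with strong regional
hotspots (AOD 0.4-0.8) over the four major polluted crop regions, a ~0.1
background, a winter-peaked seasonal cycle driven by heating emissions, and
a large fraction of missing retrievals (clouds, bright surfaces).  This
module generates fields with exactly that statistical structure so the whole
pipeline is testable without any satellite download, plus a provincial
production/harvest table consistent with the published regional shares.

All randomness flows through a single integer seed; regeneration with the
same configuration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .regions import CHINA_LAT, CHINA_LON, RegionDefinition, default_regions, validate_regions

#: (year, month) stamps emulating a two-year satellite record, Apr y0 .. Apr y0+2
DEFAULT_MONTHS: tuple[tuple[int, int], ...] = tuple(
    (2010 + (m - 1) // 12, (m - 1) % 12 + 1) for m in range(4, 4 + 25)
)

# national production totals (tonnes) chosen so the published absolute losses
# (2.0e7 t wheat at 8%, 5.9e6 t rice at 2%) are consistent with the percentages
DEFAULT_NATIONAL_TOTALS: dict[str, float] = {"wheat": 2.5e8, "rice": 2.95e8}

# regional production shares; the four-region totals are 75% (wheat), 45% (rice)
DEFAULT_REGION_SHARES: dict[str, dict[str, float]] = {
    "wheat": {"NCP": 0.47, "YRD": 0.19, "CEC": 0.05, "SCB": 0.04},
    "rice": {"NCP": 0.03, "YRD": 0.15, "CEC": 0.20, "SCB": 0.07},
}

# provinces per region and their harvest months; wheat is harvested in early
# summer (later in the colder north), rice in the four regions mainly in July
DEFAULT_PROVINCES: dict[str, list[str]] = {
    "NCP": ["Hebei", "Henan", "Shandong"],
    "YRD": ["Jiangsu", "Anhui"],
    "CEC": ["Hubei", "Hunan"],
    "SCB": ["Sichuan"],
}
DEFAULT_HARVEST_MONTHS: dict[str, dict[str, int]] = {
    "wheat": {
        "Hebei": 8,
        "Henan": 6,
        "Shandong": 6,
        "Jiangsu": 6,
        "Anhui": 6,
        "Hubei": 5,
        "Hunan": 5,
        "Sichuan": 5,
    },
    "rice": {
        "Hebei": 10,
        "Henan": 10,
        "Shandong": 10,
        "Jiangsu": 7,
        "Anhui": 7,
        "Hubei": 7,
        "Hunan": 7,
        "Sichuan": 7,
    },
}


@dataclass(frozen=True)
class SyntheticAODConfig:
    """Configuration of the synthetic AOD generator.

    Attributes
    ----------
    hotspot_range : (float, float)
        Uniform AOD range inside region boxes before seasonal modulation.
    background : float
        Mean AOD outside the regions.
    background_noise : float
        Gaussian noise s.d. added to background cells (clipped at 0).
    seasonal_amplitude : float
        Amplitude of the multiplicative seasonal cycle; the factor is
        ``1 + a*cos(2*pi*(month-1)/12)``, peaking in January.
    missing_fraction : float
        Fraction of cells flagged missing each month, uniformly at random.
    seed : int
        RNG seed; same config implies a bit-identical field.
    resolution : float
        Grid spacing in degrees (cell centres).
    months : sequence of (year, month)
        Month stamps to generate, in order.
    """

    hotspot_range: tuple[float, float] = (0.4, 0.8)
    background: float = 0.1
    background_noise: float = 0.02
    seasonal_amplitude: float = 0.3
    missing_fraction: float = 0.3
    seed: int = 0
    resolution: float = 0.1
    months: Sequence[tuple[int, int]] = field(default=DEFAULT_MONTHS)

    def __post_init__(self) -> None:
        lo, hi = self.hotspot_range
        if not (0 <= lo <= hi):
            raise ValueError("hotspot range must satisfy 0 <= lo <= hi")
        if self.background < 0:
            raise ValueError("background AOD must be >= 0")
        if not (0 <= self.missing_fraction < 1):
            raise ValueError("missing fraction must be in [0, 1)")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if len(self.months) == 0:
            raise ValueError("month list is empty")


def seasonal_factor(month, amplitude: float = 0.3):
    """Multiplicative seasonal AOD modulation, maximum in January (m=1)."""
    month = np.asarray(month)
    return 1.0 + amplitude * np.cos(2.0 * np.pi * (month - 1) / 12.0)


def grid_axes(resolution: float) -> tuple[np.ndarray, np.ndarray]:
    """Cell-centre lon/lat axes covering the mainland-China extent."""
    nlon = int(round((CHINA_LON[1] - CHINA_LON[0]) / resolution))
    nlat = int(round((CHINA_LAT[1] - CHINA_LAT[0]) / resolution))
    if nlon < 2 or nlat < 2:
        raise ValueError("degenerate grid: fewer than 2 cells per axis")
    lon = CHINA_LON[0] + resolution * (np.arange(nlon) + 0.5)
    lat = CHINA_LAT[0] + resolution * (np.arange(nlat) + 0.5)
    return lon, lat


def generate_aod_fields(
    config: SyntheticAODConfig = SyntheticAODConfig(),
    regions: Sequence[RegionDefinition] | None = None,
) -> xr.DataArray:
    """Generate a monthly AOD time-series with regional hotspots.

    Returns a ``DataArray`` with dims ``(time, lat, lon)``; missing cells are
    NaN.  The ``time`` coordinate is the first day of each month; ``year`` and
    ``month`` auxiliary coordinates carry the stamps.
    """
    if regions is None:
        regions = default_regions()
    validate_regions(regions)

    lon, lat = grid_axes(config.resolution)
    rng = np.random.default_rng(config.seed)
    lon2 = lon[np.newaxis, :]
    lat2 = lat[:, np.newaxis]
    region_mask = np.zeros((lat.size, lon.size), dtype=bool)
    for reg in regions:
        region_mask |= reg.contains(lon2, lat2)

    lo, hi = config.hotspot_range
    fields = np.empty((len(config.months), lat.size, lon.size))
    for i, (_, month) in enumerate(config.months):
        s = float(seasonal_factor(month, config.seasonal_amplitude))
        aod = rng.normal(config.background, config.background_noise, region_mask.shape)
        np.clip(aod, 0.0, None, out=aod)
        hot = rng.uniform(lo * s, hi * s, region_mask.shape)
        aod[region_mask] = hot[region_mask]
        if config.missing_fraction > 0:
            miss = rng.random(region_mask.shape) < config.missing_fraction
            aod[miss] = np.nan
        fields[i] = aod

    years = [y for y, _ in config.months]
    months = [m for _, m in config.months]
    time = pd.to_datetime([f"{y:04d}-{m:02d}-01" for y, m in config.months])
    da = xr.DataArray(
        fields,
        coords={"time": time, "lat": lat, "lon": lon},
        dims=("time", "lat", "lon"),
        name="aod",
        attrs={"long_name": "aerosol optical depth at 550 nm", "units": "1"},
    )
    da = da.assign_coords(
        year=("time", np.asarray(years)), month=("time", np.asarray(months))
    )
    return da


def _split_province_production(
    rng: np.random.Generator, total: float, n: int, jitter: float = 0.1
) -> np.ndarray:
    """Split a regional total over n provinces, roughly equally (seeded jitter)."""
    w = 1.0 + jitter * rng.uniform(-1.0, 1.0, n)
    w /= w.sum()
    return total * w


def generate_production_table(
    seed: int = 0,
    totals: Mapping[str, float] | None = None,
    region_shares: Mapping[str, Mapping[str, float]] | None = None,
    provinces: Mapping[str, Sequence[str]] | None = None,
    harvest_months: Mapping[str, Mapping[str, int]] | None = None,
) -> pd.DataFrame:
    """Build a provincial production/harvest table from regional shares.

    Columns: ``province, region, crop, production_tonnes, harvest_month``.
    Per-region production sums equal ``share * national total``; production
    outside the four regions is collected in a ``Rest of China`` row with
    region ``""``.
    """
    totals = dict(DEFAULT_NATIONAL_TOTALS if totals is None else totals)
    region_shares = {
        c: dict(s)
        for c, s in (DEFAULT_REGION_SHARES if region_shares is None else region_shares).items()
    }
    provinces = dict(DEFAULT_PROVINCES if provinces is None else provinces)
    harvest_months = {
        c: dict(h)
        for c, h in (DEFAULT_HARVEST_MONTHS if harvest_months is None else harvest_months).items()
    }
    rng = np.random.default_rng(seed)

    rows = []
    for crop, shares in region_shares.items():
        total = totals[crop]
        share_sum = sum(shares.values())
        if share_sum > 1.0 + 1e-12:
            raise ValueError(f"{crop}: regional shares sum to {share_sum:.3f} > 1")
        for region, share in shares.items():
            provs = list(provinces[region])
            prod = _split_province_production(rng, share * total, len(provs))
            # force exact regional sums (rounding closure on the last province)
            prod[-1] = share * total - prod[:-1].sum()
            for name, p in zip(provs, prod):
                rows.append(
                    {
                        "province": name,
                        "region": region,
                        "crop": crop,
                        "production_tonnes": p,
                        "harvest_month": harvest_months[crop].get(name, np.nan),
                    }
                )
        rows.append(
            {
                "province": "Rest of China",
                "region": "",
                "crop": crop,
                "production_tonnes": (1.0 - share_sum) * total,
                "harvest_month": np.nan,
            }
        )
    df = pd.DataFrame(rows)
    dup = df.duplicated(subset=["province", "crop"])
    if dup.any():
        raise ValueError("duplicate (province, crop) rows in production table")
    return df
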
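"""High-pollution, high-production analysis regions.

The four regions of interest — North China Plain (NCP), Yangtze River
Delta (YRD), central eastern China (CEC) and Sichuan Basin (SCB) — are
represented as lon/lat bounding boxes.  Published maps outline the regions
without printing coordinates, so the default boxes below are approximate
and fully overridable.

Boxes are half-open (``lon_min <= lon < lon_max``) so that regions sharing
an edge do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import xarray as xr

#: mainland-China extent used for the analysis grid (degrees east / north)
CHINA_LON = (73.0, 135.0)
CHINA_LAT = (18.0, 54.0)


@dataclass(frozen=True)
class RegionDefinition:
    """A rectangular analysis region.

    Parameters
    ----------
    name : str
        Region short name, e.g. ``"NCP"``.
    region_id : int
        Integer id (1-4 for the four standard regions).
    lon_min, lon_max, lat_min, lat_max : float
        Bounding box in degrees; half-open in both axes.
    """

    name: str
    region_id: int
    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float

    def __post_init__(self) -> None:
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError(f"region {self.name}: degenerate bounding box")
        if not (
            CHINA_LON[0] <= self.lon_min
            and self.lon_max <= CHINA_LON[1]
            and CHINA_LAT[0] <= self.lat_min
            and self.lat_max <= CHINA_LAT[1]
        ):
            raise ValueError(f"region {self.name}: box outside mainland-China extent")

    def contains(self, lon, lat):
        """Element-wise membership test; broadcasts lon against lat."""
        lon = np.asarray(lon)
        lat = np.asarray(lat)
        return (
            (lon >= self.lon_min)
            & (lon < self.lon_max)
            & (lat >= self.lat_min)
            & (lat < self.lat_max)
        )

    def mask(self, grid: xr.DataArray) -> xr.DataArray:
        """Boolean mask of this region on a field with ``lon``/``lat`` coords."""
        lon2, lat2 = xr.broadcast(grid["lon"], grid["lat"])
        out = xr.DataArray(
            self.contains(lon2.values, lat2.values),
            coords=lon2.coords,
            dims=lon2.dims,
        )
        return out.transpose(*[d for d in grid.dims if d in out.dims])


def default_regions() -> list[RegionDefinition]:
    """The four standard regions with approximate default boxes."""
    return [
        RegionDefinition("NCP", 1, 113.0, 120.0, 34.0, 41.0),
        RegionDefinition("YRD", 2, 117.0, 122.0, 29.0, 34.0),
        RegionDefinition("CEC", 3, 110.0, 117.0, 26.0, 32.0),
        RegionDefinition("SCB", 4, 103.0, 108.0, 28.0, 32.0),
    ]


def validate_regions(regions: Iterable[RegionDefinition]) -> None:
    """Check uniqueness of ids and pairwise non-overlap; raise ValueError."""
    regions = list(regions)
    ids = [r.region_id for r in regions]
    if len(set(ids)) != len(ids):
        raise ValueError("region ids are not unique")
    for i, a in enumerate(regions):
        for b in regions[i + 1 :]:
            # half-open boxes overlap iff the open interiors intersect
            if (
                a.lon_min < b.lon_max
                and b.lon_min < a.lon_max
                and a.lat_min < b.lat_max
                and b.lat_min < a.lat_max
            ):
                raise ValueError(f"regions {a.name} and {b.name} overlap")
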
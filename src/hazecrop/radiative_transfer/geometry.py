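"""Solar geometry: declination, daylight hour-angle nodes, cosine of the
solar zenith angle.

The diurnal integral of irradiance is evaluated by a midpoint rule over the
hour angle between sunrise and sunset; daily means are expressed over the
full 24 h day (daylight fraction times the daylight-mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

OBLIQUITY_DEG = 23.44


def declination_deg(day_of_year: float) -> float:
    """Solar declination (degrees) from the standard sinusoidal approximation."""
    return OBLIQUITY_DEG * np.sin(2.0 * np.pi * (284 + day_of_year) / 365.0)


@dataclass(frozen=True)
class SolarGeometry:
    """Daylight quadrature for one latitude and day.

    ``mu0`` holds the cosine of the solar zenith angle at midpoint hour-angle
    nodes between sunrise and sunset (empty in polar night, with
    ``daylight_fraction`` 0).  The daily (24 h) mean of a quantity q(mu0) is
    ``daylight_fraction * mean(q(mu0))``.
    """

    latitude: float
    day_of_year: int
    mu0: np.ndarray
    daylight_fraction: float

    @property
    def is_polar_night(self) -> bool:
        return self.mu0.size == 0


def solar_geometry(latitude: float, day_of_year: int, n_nodes: int = 24) -> SolarGeometry:
    """Build daylight mu0 nodes for a latitude/day.

    Nodes are midpoints of ``n_nodes`` equal hour-angle intervals spanning
    sunrise to sunset, symmetric about solar noon.  Polar night yields an
    empty node set.
    """
    if not (-90.0 <= latitude <= 90.0):
        raise ValueError("latitude out of range")
    if not (1 <= day_of_year <= 366):
        raise ValueError("day of year out of range")
    phi = np.deg2rad(latitude)
    dec = np.deg2rad(declination_deg(day_of_year))
    cos_hs = -np.tan(phi) * np.tan(dec)
    if cos_hs >= 1.0:  # polar night
        return SolarGeometry(latitude, day_of_year, np.empty(0), 0.0)
    hs = np.pi if cos_hs <= -1.0 else float(np.arccos(cos_hs))
    edges = np.linspace(-hs, hs, n_nodes + 1)
    h = 0.5 * (edges[:-1] + edges[1:])
    mu0 = np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.cos(h)
    mu0 = np.clip(mu0, 0.0, 1.0)
    keep = mu0 > 0
    return SolarGeometry(latitude, day_of_year, mu0[keep], hs / np.pi)


#: representative day-of-year for each month (the 15th, non-leap calendar)
MONTH_MID_DOY: dict[int, int] = {
    1: 15, 2: 46, 3: 74, 4: 105, 5: 135, 6: 166,
    7: 196, 8: 227, 9: 258, 10: 288, 11: 319, 12: 349,
}
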
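"""Extraterrestrial solar spectrum on the analysis wavelength grid.

The spectrum is a synthetic smooth surrogate: a 5772 K blackbody scaled so
the total (all-wavelength) irradiance equals the 1361 W m^-2 solar constant.
It reproduces the broadband shape of the solar spectrum but carries no
Fraunhofer-line structure.  Every output of this package that matters
downstream is a *ratio* of irradiances, which is invariant to the absolute
spectrum (asserted in the test suite), so the surrogate is adequate here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

H = 6.62607015e-34  # J s
C = 2.99792458e8  # m s^-1
KB = 1.380649e-23  # J K^-1
SIGMA = 5.670374419e-8  # W m^-2 K^-4
T_SUN = 5772.0  # K
SOLAR_CONSTANT = 1361.0  # W m^-2


def blackbody_solar_spectrum(wavelength_nm) -> np.ndarray:
    """Spectral irradiance (W m^-2 nm^-1) of the blackbody surrogate sun.

    Synthetic stand-in for a measured reference spectrum; smooth by
    construction.
    """
    lam = np.asarray(wavelength_nm, dtype=float) * 1e-9  # m
    if (lam <= 0).any():
        raise ValueError("wavelengths must be positive")
    # Planck spectral radiance -> irradiance shape; normalise so the
    # all-wavelength integral equals the solar constant.
    b = (2 * H * C**2 / lam**5) / np.expm1(H * C / (lam * KB * T_SUN))
    scale = SOLAR_CONSTANT * np.pi / (SIGMA * T_SUN**4)
    return b * scale * 1e-9  # per nm


@dataclass(frozen=True)
class SpectralGrid:
    """Wavelength nodes (nm) spanning [300, 750] with extraterrestrial
    irradiance (W m^-2 nm^-1) at each node."""

    wavelength_nm: np.ndarray
    irradiance: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelength_nm, dtype=float)
        e = np.asarray(self.irradiance, dtype=float)
        if w.ndim != 1 or w.size < 2 or (np.diff(w) <= 0).any():
            raise ValueError("wavelength nodes must be strictly increasing")
        if not (w[0] == 300.0 and w[-1] == 750.0):
            raise ValueError("wavelength grid must span exactly [300, 750] nm")
        if (e <= 0).any():
            raise ValueError("extraterrestrial irradiance must be positive")
        object.__setattr__(self, "wavelength_nm", w)
        object.__setattr__(self, "irradiance", e)


def make_spectral_grid(step_nm: float = 1.0, scale: float = 1.0) -> SpectralGrid:
    """Uniform grid from 300 to 750 nm with the surrogate solar spectrum.

    ``step_nm`` must divide 450 nm; ``scale`` multiplies the spectrum (used
    by the scale-invariance tests).
    """
    n = round(450.0 / step_nm)
    if abs(n * step_nm - 450.0) > 1e-9:
        raise ValueError("step must divide the 450 nm band")
    w = np.linspace(300.0, 750.0, n + 1)
    return SpectralGrid(w, blackbody_solar_spectrum(w) * scale)
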
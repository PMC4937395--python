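"""Molecular optical depths: Rayleigh scattering and ozone absorption.

Rayleigh optical depth uses the compact lambda^-4 parameterization of
Hansen & Travis (1974), scaled by the surface-pressure ratio.  Ozone uses a
coarse embedded cross-section table (Huggins-band edge below ~350 nm and the
Chappuis band across the visible), linearly interpolated; the table is
approximate, which is adequate because ozone contributes only a small,
AOD-independent attenuation that largely cancels in the reduction ratios.
"""

from __future__ import annotations

import numpy as np

P0_HPA = 1013.25
DU_TO_CM2 = 2.6867e16  # molecules cm^-2 per Dobson unit


def rayleigh_optical_depth(wavelength_nm, surface_pressure_hpa: float = P0_HPA):
    """Rayleigh column optical depth at sea level pressure ratio.

    tau = (p/p0) * 0.008569 lam^-4 (1 + 0.0113 lam^-2 + 0.00013 lam^-4),
    lam in micrometres (Hansen & Travis 1974).
    """
    lam = np.asarray(wavelength_nm, dtype=float)
    if (lam < 240.0).any() or (lam > 30000.0).any():
        raise ValueError("wavelength outside the supported 240-30000 nm range")
    lam_um = lam * 1e-3
    inv2 = lam_um**-2
    inv4 = inv2**2
    tau = 0.008569 * inv4 * (1.0 + 0.0113 * inv2 + 0.00013 * inv4)
    return tau * (surface_pressure_hpa / P0_HPA)


# approximate ozone absorption cross sections (cm^2 molecule^-1) at 298 K;
# Huggins tail 300-360 nm, near-zero window, Chappuis band 440-750 nm
_OZONE_WL_NM = np.array(
    [300, 305, 310, 315, 320, 325, 330, 335, 340, 345, 350, 360, 400, 440,
     470, 500, 530, 550, 570, 590, 610, 630, 650, 670, 700, 730, 750],
    dtype=float,
)
_OZONE_XS = np.array(
    [3.9e-19, 2.0e-19, 1.0e-19, 5.0e-20, 2.6e-20, 1.3e-20, 6.6e-21, 3.3e-21,
     1.6e-21, 8.0e-22, 4.0e-22, 1.0e-22, 1.0e-23, 6.0e-22, 1.4e-21, 3.0e-21,
     4.4e-21, 4.8e-21, 5.0e-21, 4.6e-21, 4.0e-21, 3.2e-21, 2.4e-21, 1.8e-21,
     1.1e-21, 7.0e-22, 5.5e-22],
)


def ozone_cross_section(wavelength_nm):
    """Approximate ozone cross section (cm^2), interpolated from the table."""
    lam = np.asarray(wavelength_nm, dtype=float)
    return np.interp(lam, _OZONE_WL_NM, _OZONE_XS, left=_OZONE_XS[0], right=_OZONE_XS[-1])


def ozone_optical_depth(wavelength_nm, column_du: float = 300.0):
    """Ozone column optical depth for a column amount in Dobson units."""
    if column_du < 0:
        raise ValueError("ozone column must be >= 0")
    return ozone_cross_section(wavelength_nm) * column_du * DU_TO_CM2
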
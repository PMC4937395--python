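"""Layered optical properties of one atmospheric column.

The column combines three constituents per layer and wavelength:

* aerosol — spectral AOD ``aod_550 * (lam/550)^-alpha`` split vertically as
  a well-mixed boundary layer (uniform density up to the PBL top) with
  exponential decay above, single-scattering albedo ``ssa`` and asymmetry
  parameter ``g``;
* Rayleigh scattering — conservative (omega=1, g=0), pressure-weighted
  (scale height 8 km) so the layer depths sum to the column Rayleigh depth;
* ozone — pure absorption, placed in the stratospheric layers (15-35 km).

Layers are stored surface -> top of atmosphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import ozone_optical_depth, rayleigh_optical_depth
from .spectrum import SpectralGrid

#: default layer edges in km, surface to TOA
DEFAULT_EDGES_KM = (0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.2, 3.2, 5.0, 8.0, 12.0, 20.0, 35.0, 50.0)
PRESSURE_SCALE_KM = 8.0
OZONE_LAYER_KM = (15.0, 35.0)


@dataclass(frozen=True)
class AtmosphericColumn:
    """Per-layer, per-wavelength optical properties (surface -> TOA).

    ``tau_aerosol``, ``tau_rayleigh``, ``tau_ozone`` have shape
    ``(n_wavelength, n_layer)``; ``ssa_aerosol`` / ``g_aerosol`` are scalars
    (spectrally grey aerosol); ``surface_albedo`` is Lambertian.
    """

    edges_km: np.ndarray
    wavelength_nm: np.ndarray
    tau_aerosol: np.ndarray
    tau_rayleigh: np.ndarray
    tau_ozone: np.ndarray
    ssa_aerosol: float
    g_aerosol: float
    surface_albedo: float
    pbl_km: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ssa_aerosol <= 1.0):
            raise ValueError("single-scattering albedo must be in [0, 1]")
        if not (-1.0 < self.g_aerosol < 1.0):
            raise ValueError("asymmetry parameter must be in (-1, 1)")
        if not (0.0 <= self.surface_albedo <= 1.0):
            raise ValueError("surface albedo must be in [0, 1]")
        for name in ("tau_aerosol", "tau_rayleigh", "tau_ozone"):
            if (getattr(self, name) < 0).any():
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_layers(self) -> int:
        return self.edges_km.size - 1

    def total_tau(self) -> np.ndarray:
        """Column extinction optical depth per wavelength."""
        return (self.tau_aerosol + self.tau_rayleigh + self.tau_ozone).sum(axis=-1)

    def mixed_layer_properties(self):
        """Combined (tau, omega, ssa-weighted g) per wavelength and layer."""
        tau = self.tau_aerosol + self.tau_rayleigh + self.tau_ozone
        scat = self.ssa_aerosol * self.tau_aerosol + self.tau_rayleigh
        with np.errstate(invalid="ignore", divide="ignore"):
            omega = np.where(tau > 0, scat / np.where(tau > 0, tau, 1.0), 0.0)
            g = np.where(scat > 0, self.g_aerosol * self.ssa_aerosol * self.tau_aerosol
                         / np.where(scat > 0, scat, 1.0), 0.0)
        return tau, omega, g


def _layer_weights_profile(edges: np.ndarray, pbl_km: float, scale_km: float) -> np.ndarray:
    """Normalised aerosol layer weights for a uniform-PBL + exponential-tail
    density profile (continuous at the PBL top)."""
    z0, z1 = edges[:-1], edges[1:]
    # integral of the unnormalised density over each layer
    in_pbl = np.clip(z1, None, pbl_km) - np.clip(z0, None, pbl_km)
    in_pbl = np.clip(in_pbl, 0.0, None)
    a0 = np.clip(z0, pbl_km, None) - pbl_km
    a1 = np.clip(z1, pbl_km, None) - pbl_km
    above = scale_km * (np.exp(-a0 / scale_km) - np.exp(-a1 / scale_km))
    w = in_pbl + above
    return w / w.sum()


def _overlap_weights(edges: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    z0, z1 = edges[:-1], edges[1:]
    ov = np.clip(np.minimum(z1, band[1]) - np.maximum(z0, band[0]), 0.0, None)
    if ov.sum() == 0:  # column top below the band: put it in the top layer
        ov = np.zeros_like(z0)
        ov[-1] = 1.0
    return ov / ov.sum()


def build_column(
    aod_550: float,
    spectral: SpectralGrid,
    pbl_km: float = 1.0,
    angstrom_exponent: float = 1.0,
    ozone_du: float = 300.0,
    ssa: float = 0.80,
    asymmetry: float = 0.65,
    surface_albedo: float = 0.2,
    scale_height_km: float = 1.5,
    surface_pressure_hpa: float = 1013.25,
    edges_km=DEFAULT_EDGES_KM,
    rayleigh: bool = True,
) -> AtmosphericColumn:
    """Assemble an :class:`AtmosphericColumn` from scalar inputs.

    Spectral aerosol depth follows the Angstrom law
    ``aod_550 * (lam/550)^-alpha``; layer aerosol depths sum to the spectral
    column value to round-off.  Set ``ozone_du=0`` or ``rayleigh=False`` to
    disable the molecular constituents.
    """
    if aod_550 < 0:
        raise ValueError("AOD must be >= 0")
    if pbl_km <= 0:
        raise ValueError("PBL height must be positive")
    edges = np.asarray(edges_km, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("layer edges must be strictly increasing, surface to TOA")

    lam = spectral.wavelength_nm
    aod_spectral = aod_550 * (lam / 550.0) ** (-angstrom_exponent)
    w_aer = _layer_weights_profile(edges, pbl_km, scale_height_km)
    tau_aer = aod_spectral[:, None] * w_aer[None, :]

    if rayleigh:
        tau_r_col = rayleigh_optical_depth(lam, surface_pressure_hpa)
        p = np.exp(-edges / PRESSURE_SCALE_KM)
        w_ray = (p[:-1] - p[1:]) / (p[0] - p[-1])
        tau_ray = tau_r_col[:, None] * w_ray[None, :]
    else:
        tau_ray = np.zeros_like(tau_aer)

    if ozone_du > 0:
        tau_o_col = ozone_optical_depth(lam, ozone_du)
        w_o3 = _overlap_weights(edges, OZONE_LAYER_KM)
        tau_o3 = tau_o_col[:, None] * w_o3[None, :]
    else:
        tau_o3 = np.zeros_like(tau_aer)

    return AtmosphericColumn(
        edges_km=edges,
        wavelength_nm=lam,
        tau_aerosol=tau_aer,
        tau_rayleigh=tau_ray,
        tau_ozone=tau_o3,
        ssa_aerosol=ssa,
        g_aerosol=asymmetry,
        surface_albedo=surface_albedo,
        pbl_km=pbl_km,
    )
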
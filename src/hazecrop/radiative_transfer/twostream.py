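"""Delta-Eddington two-stream radiative transfer for a layered column.

Each layer's diffuse reflectance/transmittance and beam-generated source
fluxes are obtained in closed form from the Eddington two-stream solution
after delta-scaling (the forward-scattering peak is folded into the direct
beam: f = g**2, tau' = (1 - w*f) tau, w' = (1-f) w / (1 - w*f),
g' = g / (1+g)).  Layers are combined top-down by the adding method, with a
Lambertian surface closing the column.

Reported components follow the usual convention: the *direct* beam is the
unscaled Beer-Lambert transmission exp(-tau/mu0); the forward-scattered
spike retained by delta-scaling is counted as diffuse.  Global = direct +
diffuse holds exactly by construction.

All routines broadcast over arbitrary leading axes (wavelength, solar node,
grid cell); the only Python loop is over layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .column import AtmosphericColumn

_OMEGA_MAX = 1.0 - 1e-9  # conservative-scattering limit is approached, not hit
_RESONANCE_TOL = 1e-4  # |lam*mu0 - 1| guard for the beam particular solution


def _layer_quantities(tau, omega, g, mu):
    """Closed-form delta-Eddington layer properties.

    Returns (rdif, tdif, rbeam, tbeam, mbeam): diffuse reflectance and
    transmittance, beam-generated upward/downward diffuse source fluxes per
    unit perpendicular beam flux at the layer top, and the (scaled) beam
    transmission through the layer.
    """
    f = g * g
    tau_s = (1.0 - omega * f) * tau
    with np.errstate(invalid="ignore", divide="ignore"):
        omega_s = np.where(tau > 0, (1.0 - f) * omega / (1.0 - omega * f), 0.0)
    omega_s = np.minimum(omega_s, _OMEGA_MAX)
    g_s = g / (1.0 + g)

    g1 = (7.0 - omega_s * (4.0 + 3.0 * g_s)) / 4.0
    g2 = -(1.0 - omega_s * (4.0 - 3.0 * g_s)) / 4.0
    g3 = (2.0 - 3.0 * g_s * mu) / 4.0
    g4 = 1.0 - g3
    lam = np.sqrt((g1 - g2) * (g1 + g2))
    gam = g2 / (g1 + lam)

    e = np.exp(-lam * tau_s)
    mbeam = np.exp(-tau_s / mu)
    denom_h = 1.0 - (gam * e) ** 2

    rdif = gam * (1.0 - e * e) / denom_h
    tdif = e * (1.0 - gam * gam) / denom_h

    # particular (beam-source) solution; eta blow up at lam*mu = 1 cancels
    # against the homogeneous coefficients, the guard keeps the cancellation
    # benign in floating point
    dp = 1.0 / (mu * mu) - lam * lam
    dp = np.where(np.abs(dp) * mu * mu < _RESONANCE_TOL,
                  np.where(dp >= 0, 1.0, -1.0) * _RESONANCE_TOL / (mu * mu), dp)
    inv_mu = 1.0 / mu
    eta_up = omega_s * ((inv_mu - g1) * g3 - g2 * g4) / dp
    eta_dn = -omega_s * ((g1 + inv_mu) * g4 + g2 * g3) / dp

    a = (eta_dn * gam * e - eta_up * mbeam) / denom_h
    b = -eta_dn - a * gam * e
    rbeam = a * e + b * gam + eta_up
    tbeam = a * gam + b * e + eta_dn * mbeam
    return rdif, tdif, rbeam, tbeam, mbeam


def delta_eddington_fluxes(tau, omega, g, mu0, surface_albedo):
    """Surface fluxes for a multilayer column, per unit extraterrestrial
    perpendicular flux.

    Parameters broadcast: ``tau``/``omega``/``g`` have a trailing layer axis
    ordered top -> bottom; ``mu0`` matches the leading axes.

    Returns a dict with ``direct`` (mu0*exp(-tau_tot/mu0), horizontal,
    unscaled), ``diffuse``, ``global`` downward surface fluxes and ``up_toa``
    (upward diffuse flux at the top of atmosphere).
    """
    tau = np.asarray(tau, dtype=float)
    omega = np.asarray(omega, dtype=float)
    g = np.asarray(g, dtype=float)
    mu0 = np.asarray(mu0, dtype=float)
    if (mu0 <= 0).any() or (mu0 > 1).any():
        raise ValueError("mu0 must lie in (0, 1]")
    nlay = tau.shape[-1]

    first = True
    for k in range(nlay):
        rd, td, rb, tb, m = _layer_quantities(
            tau[..., k], omega[..., k], np.broadcast_to(g[..., k], tau[..., k].shape), mu0
        )
        if first:
            rb_s, tb_s, rdif_below, tdif_s, ms = rb, tb, rd, td, m
            first = False
            continue
        denom = 1.0 - rdif_below * rd
        d = (tb_s + ms * rb * rdif_below) / denom
        u = ms * rb + d * rd
        rb_s = rb_s + tdif_s * u
        tb_s = ms * tb + d * td
        rdif_below = rd + td * td * rdif_below / denom
        tdif_s = tdif_s * td / denom
        ms = ms * m

    alb = surface_albedo
    denom = 1.0 - rdif_below * alb
    d_ground = (tb_s + ms * mu0 * alb * rdif_below) / denom
    u_ground = (ms * mu0 + d_ground) * alb
    up_toa = rb_s + tdif_s * u_ground

    tau_tot = tau.sum(axis=-1)
    direct = mu0 * np.exp(-tau_tot / mu0)
    # scaled direct + diffuse is the physical global flux; re-split so the
    # delta-scaled forward spike counts as diffuse
    global_down = ms * mu0 + d_ground
    diffuse = np.maximum(global_down - direct, 0.0)
    global_down = direct + diffuse

    for name, arr in (("diffuse", diffuse), ("up_toa", up_toa)):
        if not np.isfinite(arr).all():
            bad = int(np.count_nonzero(~np.isfinite(arr)))
            raise RuntimeError(
                f"two-stream solution ill-conditioned: {bad} non-finite {name} "
                f"values; layer tau range [{tau.min():.3g}, {tau.max():.3g}]"
            )
    return {
        "direct": direct,
        "diffuse": diffuse,
        "global": global_down,
        "up_toa": up_toa,
    }


@dataclass(frozen=True)
class TwoStreamResult:
    """Normalized (unit extraterrestrial flux) surface result at one
    wavelength and solar position."""

    direct_transmittance: float
    direct_flux: float
    diffuse_flux: float
    global_flux: float
    up_toa: float


def two_stream_solve(
    column: AtmosphericColumn, mu0: float, wavelength_index: int
) -> TwoStreamResult:
    """Solve one wavelength of a column at one solar zenith cosine.

    Thin scalar wrapper over :func:`delta_eddington_fluxes`; the column's
    surface->TOA layer order is flipped to the solver's top-down order.
    """
    if not (0.0 < mu0 <= 1.0):
        raise ValueError("mu0 must lie in (0, 1]")
    tau, omega, g = column.mixed_layer_properties()
    sl = (wavelength_index, slice(None, None, -1))
    out = delta_eddington_fluxes(
        tau[sl], omega[sl], g[sl], np.asarray(mu0, dtype=float), column.surface_albedo
    )
    return TwoStreamResult(
        direct_transmittance=float(np.exp(-tau[wavelength_index].sum() / mu0)),
        direct_flux=float(out["direct"]),
        diffuse_flux=float(out["diffuse"]),
        global_flux=float(out["global"]),
        up_toa=float(out["up_toa"]),
    )
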
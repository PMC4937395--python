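"""Independent Monte-Carlo photon-transport oracle for plane-parallel
columns with Henyey-Greenstein scattering and a Lambertian floor.

Used only as a reference in tests; deliberately shares no code with the
two-stream solver.  Fluxes are returned per unit extraterrestrial flux on a
plane perpendicular to the beam, matching the solver's normalization
(incident horizontal flux = mu0).
"""

from __future__ import annotations

import numpy as np


def _hg_scatter(rng: np.random.Generator, mu: np.ndarray, g: float) -> np.ndarray:
    """New direction cosines after Henyey-Greenstein scattering."""
    u = rng.random(mu.size)
    if abs(g) < 1e-8:
        cos_t = 2.0 * u - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        cos_t = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    cos_t = np.clip(cos_t, -1.0, 1.0)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = 2.0 * np.pi * rng.random(mu.size)
    sin_mu = np.sqrt(np.clip(1.0 - mu * mu, 0.0, None))
    out = mu * cos_t - sin_mu * sin_t * np.cos(phi)
    out = np.clip(out, -1.0, 1.0)
    return np.where(np.abs(out) < 1e-12, 1e-12, out)  # avoid horizontal rays


def mc_surface_fluxes(
    tau: float,
    omega: float,
    g: float,
    mu0: float,
    albedo: float = 0.0,
    n_photons: int = 1_000_000,
    seed: int = 12345,
    max_events: int = 10_000,
    weight_cutoff: float = 1e-9,
):
    """Monte-Carlo direct/diffuse downward surface flux and TOA reflectance.

    Absorption is handled by weight reduction (factor ``omega`` per
    scattering event); photons are dropped below ``weight_cutoff``.
    """
    rng = np.random.default_rng(seed)
    # optical-depth coordinate z in [0, tau] from the top; mu > 0 = downward
    z = np.zeros(n_photons)
    mu = np.full(n_photons, mu0)
    w = np.ones(n_photons)
    scattered = np.zeros(n_photons, dtype=bool)

    direct = diffuse_down = up_toa = 0.0

    for _ in range(max_events):
        if z.size == 0:
            break
        z_new = z + mu * (-np.log(rng.random(z.size)))
        hit_floor = (mu > 0) & (z_new >= tau)
        hit_top = (mu < 0) & (z_new <= 0.0)
        inside = ~(hit_floor | hit_top)

        up_toa += w[hit_top].sum()
        wf, sf = w[hit_floor], scattered[hit_floor]
        direct += wf[~sf].sum()
        diffuse_down += wf[sf].sum()

        if albedo > 0.0 and wf.size:
            wr = wf * albedo
            keep = wr > weight_cutoff
            n_r = int(keep.sum())
            refl = (
                np.full(n_r, tau),
                -np.sqrt(rng.random(n_r)),  # Lambertian flux sampling, upward
                wr[keep],
                np.ones(n_r, dtype=bool),
            )
        else:
            refl = (np.empty(0), np.empty(0), np.empty(0), np.empty(0, dtype=bool))

        zi, mui, wi = z_new[inside], mu[inside], w[inside] * omega
        alive = wi > weight_cutoff
        zi, mui, wi = zi[alive], mui[alive], wi[alive]
        mui = _hg_scatter(rng, mui, g)

        z = np.concatenate([zi, refl[0]])
        mu = np.concatenate([mui, refl[1]])
        w = np.concatenate([wi, refl[2]])
        scattered = np.concatenate([np.ones(zi.size, dtype=bool), refl[3]])

    norm = mu0 / n_photons  # per-photon horizontal flux contribution
    return {
        "direct": direct * norm,
        "diffuse": diffuse_down * norm,
        "global": (direct + diffuse_down) * norm,
        "up_toa": up_toa * norm,
    }
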
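"""Free-electron Compton (Klein-Nishina) cross sections and angular sampling.

The incoherent channel of the photon transport uses the free-electron
Klein-Nishina formula without binding or Doppler corrections, which is a
few-percent approximation for low-Z media above ~30 keV.  All quantities are
per electron; energies in keV, cross sections in m^2.
"""
from __future__ import annotations

import numpy as np

from ._constants import ELECTRON_REST_KEV, R_ELECTRON_M

# Gauss-Legendre nodes for the angular integrals (smooth integrand; 64 points
# give ~machine precision over 10-200 keV)
_GL_X, _GL_W = np.polynomial.legendre.leggauss(64)


def kn_differential(costheta, energy_kev):
    """Klein-Nishina dsigma/dOmega [m^2/sr] at scattering angle theta."""
    costheta = np.asarray(costheta, dtype=float)
    eps = np.asarray(energy_kev, dtype=float) / ELECTRON_REST_KEV
    kappa = 1.0 / (1.0 + eps * (1.0 - costheta))  # E'/E
    sin2 = 1.0 - costheta**2
    return 0.5 * R_ELECTRON_M**2 * kappa**2 * (kappa + 1.0 / kappa - sin2)


def kn_total_cross_section(energy_kev):
    """Total Klein-Nishina cross section per electron [m^2]."""
    mu = _GL_X[:, None]
    w = _GL_W[:, None]
    e = np.atleast_1d(np.asarray(energy_kev, dtype=float))[None, :]
    integrand = kn_differential(mu, e)
    sigma = 2.0 * np.pi * np.sum(w * integrand, axis=0)
    return sigma if np.ndim(energy_kev) else float(sigma[0])


def kn_mean_energy_transfer_fraction(energy_kev):
    """Mean fraction of the photon energy given to the Compton electron.

    f_tr(E) = <1 - E'/E> averaged over the Klein-Nishina angular
    distribution; the energy-transfer cross section is f_tr * sigma_KN.
    """
    mu = _GL_X[:, None]
    w = _GL_W[:, None]
    e = np.atleast_1d(np.asarray(energy_kev, dtype=float))[None, :]
    eps = e / ELECTRON_REST_KEV
    kappa = 1.0 / (1.0 + eps * (1.0 - mu))
    dsig = kn_differential(mu, e)
    num = np.sum(w * (1.0 - kappa) * dsig, axis=0)
    den = np.sum(w * dsig, axis=0)
    frac = num / den
    return frac if np.ndim(energy_kev) else float(frac[0])


def kn_pdf_costheta(costheta, energy_kev):
    """Normalised pdf of cos(theta) under Klein-Nishina at a fixed energy."""
    dsig = kn_differential(costheta, energy_kev)
    sigma = kn_total_cross_section(energy_kev)
    return 2.0 * np.pi * dsig / sigma


def sample_costheta(rng: np.random.Generator, energy_kev: float, n: int):
    """Draw n scattering-angle cosines from the Klein-Nishina distribution.

    Vectorised rejection sampling against a uniform proposal in cos(theta)
    with a grid-estimated majorant (exact: the majorant is inflated by 1e-6
    and the KN density is monotone-free of narrow spikes).
    """
    grid = np.linspace(-1.0, 1.0, 2001)
    majorant = kn_differential(grid, energy_kev).max() * (1.0 + 1e-6)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(int((n - filled) * 2.2), 256)
        cand = rng.uniform(-1.0, 1.0, size=m)
        accept = rng.uniform(0.0, majorant, size=m) < kn_differential(cand, energy_kev)
        good = cand[accept]
        take = min(good.size, n - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    return out
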
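"""Deterministic oracles shared by the test modules.

These are computed independently of the implementation paths they check:
quadrature over tabulated coefficients and the Klein-Nishina density, never
Monte Carlo sampling.
"""
import numpy as np

import pbilung as P
from pbilung import dose_mc as dm
from pbilung._constants import ELECTRON_REST_KEV
from pbilung.compton import kn_differential, kn_mean_energy_transfer_fraction


def water_depth_dose_oracle(depth_m: np.ndarray, energy_kev: float, radius_m: float):
    """Depth-dose (arbitrary scale) in a beam-aligned water cylinder.

    Primary: attenuated beam times the energy-transfer coefficient.
    Build-up: once-scattered photons emitted along the axis with the
    Klein-Nishina angular weight, attenuated over their slant path and
    depositing while the path stays within ~0.7 of the cylinder radius
    (the mean lateral escape length of an interior point).
    """
    xs = dm.build_cross_sections([P.WATER])

    def mu_lin(channel, e):
        return xs.channel_at("water", channel, e) * 1000.0  # 1/m at unit density

    mu_t = mu_lin("photoelectric", energy_kev) + mu_lin("incoherent", energy_kev)
    mu_inc = mu_lin("incoherent", energy_kev)
    f_tr0 = kn_mean_energy_transfer_fraction(energy_kev)
    mu_en0 = mu_lin("photoelectric", energy_kev) + f_tr0 * mu_lin("incoherent", energy_kev)

    primary = np.exp(-mu_t * depth_m) * mu_en0

    cos_g = np.linspace(-0.999, 0.999, 201)
    w_kn = kn_differential(cos_g, energy_kev)
    w_kn = w_kn / np.trapezoid(w_kn, cos_g)
    e_sc = energy_kev / (1 + energy_kev / ELECTRON_REST_KEV * (1 - cos_g))
    f_tr = kn_mean_energy_transfer_fraction(e_sc)
    mu_en_sc = np.array([
        mu_lin("photoelectric", e) + f * mu_lin("incoherent", e) for e, f in zip(e_sc, f_tr)
    ])
    sin_g = np.sqrt(1 - cos_g**2)
    path_cap = np.where(sin_g > 1e-6, 0.7 * radius_m / sin_g, np.inf)

    build = np.zeros_like(depth_m)
    dstep = depth_m[1] - depth_m[0]
    for x0 in depth_m:
        src = mu_inc * np.exp(-mu_t * x0)
        for j, xd in enumerate(depth_m):
            dx = xd - x0
            with np.errstate(divide="ignore", invalid="ignore"):
                s = np.where(np.abs(cos_g) > 1e-3, dx / cos_g, np.inf)
            ok = (s > 0) & (s < path_cap)
            if not ok.any():
                continue
            contrib = (
                w_kn[ok] * (e_sc[ok] / energy_kev) * mu_en_sc[ok]
                * np.exp(-mu_t * s[ok]) / np.abs(cos_g[ok])
            )
            build[j] += src * np.trapezoid(contrib, cos_g[ok]) * dstep
    return primary + build
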
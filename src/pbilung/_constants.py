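"""Physical constants (CODATA) and unit helpers used across the package."""

# classical electron radius [m]
R_ELECTRON_M = 2.8179403262e-15
# Avogadro constant [1/mol]
N_AVOGADRO = 6.02214076e23
# electron rest energy [keV]
ELECTRON_REST_KEV = 510.99895
# hc [keV * m]
HC_KEV_M = 1.23984193e-9
# 1 keV in joule
KEV_TO_J = 1.602176634e-16
# sigma -> FWHM for a Gaussian
FWHM_PER_SIGMA = 2.3548200450309493  # 2*sqrt(2*ln 2)


def wavelength_m(energy_kev: float):
    """Photon wavelength [m] for energy in keV."""
    return HC_KEV_M / energy_kev
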
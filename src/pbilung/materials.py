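"""Materials, X-ray optical constants and the dose-normalisation factor.

A :class:`Material` is a named mass density plus an elemental composition.
From it the module computes the complex refractive index decrement
``n = 1 - delta + i*beta`` (``delta`` from the electron density with
``f1 ~ Z``, exact to <0.1% for Z<=20 above 10 keV; ``beta`` from the total
mass attenuation coefficient), linear attenuation ``mu = 4*pi*beta/lambda``,
the mass energy-absorption coefficient, and the air-kerma normalisation
factor ``R_ab,air = E_ph * (mu_en/rho)_air`` that renders the biomedical
image-quality characteristic dimensionless.

Two composition conventions are supported.  ``from_mass_fractions`` is the
physically standard one.  ``from_formula`` parses a stoichiometric formula
(numbers are atoms per formula unit).  The registry ships the ICRU-44 lung
composition in both readings: ``LUNG_ICRU44`` (mass fractions) and
``LUNG_ICRU44_STOICH``, in which the ICRU-44 percentage figures are read as
atomic abundances.  The latter matches the convention of widely used
formula-parser front-ends to delta/beta calculators and is the convention
behind the published lung delta/beta ratios used for TIE-Hom phase retrieval
at IMBL-style beamlines (1.91/1.80/1.67/1.55 x10^3 at 50/60/70/80 keV); the
mass-fraction reading gives ratios ~7% higher.  The ratio delta/beta is
independent of density in both cases.
"""
from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field

import numpy as np

from ._constants import KEV_TO_J, N_AVOGADRO, R_ELECTRON_M, wavelength_m
from . import xraydata

__all__ = [
    "ElementComposition",
    "Material",
    "OpticalConstants",
    "optical_constants",
    "delta_beta_ratio",
    "mu_en_over_rho",
    "r_ab_air",
    "REGISTRY",
    "AIR",
    "LUNG_ICRU44",
    "LUNG_ICRU44_STOICH",
    "SOFT_TISSUE",
    "BONE_CORTICAL",
    "WATER",
    "VACUUM",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)([0-9]*\.?[0-9]*)")


@dataclass(frozen=True)
class ElementComposition:
    """Mass-fraction composition: tuples of (element symbol, mass fraction)."""

    entries: tuple[tuple[str, float], ...]

    def __post_init__(self):
        for sym, w in self.entries:
            xraydata.atomic_number(sym)  # raises on unknown element
            if w < 0:
                raise ValueError(f"negative mass fraction for {sym}")
        total = sum(w for _, w in self.entries)
        if self.entries and abs(total - 1.0) > 1e-6:
            raise ValueError(f"mass fractions sum to {total}, expected 1 within 1e-6")

    @classmethod
    def from_mass_fractions(cls, fractions: dict[str, float]) -> "ElementComposition":
        total = sum(fractions.values())
        return cls(tuple((s, w / total) for s, w in fractions.items()))

    @classmethod
    def from_formula(cls, formula: str) -> "ElementComposition":
        """Stoichiometric parse: trailing numbers are atoms per formula unit."""
        counts: dict[str, float] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if m.start() != pos or not m.group(1):
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0.0) + float(m.group(2) or 1.0)
        if pos != len(formula) or not counts:
            raise ValueError(f"cannot parse formula {formula!r}")
        masses = {s: n * xraydata.atomic_weight(s) for s, n in counts.items()}
        return cls.from_mass_fractions(masses)

    def electrons_per_kg(self) -> float:
        """Electron density per unit mass, N_A * sum(w_i Z_i / A_i) [1/kg]."""
        zs = sum(w * xraydata.atomic_number(s) / xraydata.atomic_weight(s) for s, w in self.entries)
        return N_AVOGADRO * zs * 1e3  # per gram -> per kg


@dataclass(frozen=True)
class Material:
    """A named material: density [g/cm^3] and elemental composition."""

    name: str
    density: float  # g/cm^3
    composition: ElementComposition
    # optional per-material reference tables (cm^2/g on the standard grid);
    # take precedence over the element mixture rule when present
    mu_rho_table: tuple[float, ...] | None = field(default=None, repr=False)
    mu_en_rho_table: tuple[float, ...] | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.density < 0 or (self.density == 0 and self.composition.entries):
            raise ValueError("density must be > 0 for a non-vacuum material")

    @classmethod
    def from_formula(cls, name: str, formula: str, density: float) -> "Material":
        return cls(name, density, ElementComposition.from_formula(formula))

    def with_density(self, density: float) -> "Material":
        return Material(self.name, density, self.composition, self.mu_rho_table, self.mu_en_rho_table)

    def mu_rho(self, energy_kev):
        """Total mass attenuation coefficient [m^2/kg]."""
        if self.mu_rho_table is not None:
            cm2g = xraydata.loglog_interp(energy_kev, self.mu_rho_table)
        else:
            cm2g = sum(w * xraydata.element_mu_rho(s, energy_kev) for s, w in self.composition.entries)
            if not self.composition.entries:
                cm2g = np.zeros_like(np.asarray(energy_kev, dtype=float)) if np.ndim(energy_kev) else 0.0
                xraydata.loglog_interp(energy_kev, np.ones_like(xraydata.ENERGY_GRID_KEV))  # range check
        return cm2g * 0.1  # cm^2/g -> m^2/kg

    def mu_en_rho(self, energy_kev):
        """Mass energy-absorption coefficient [m^2/kg]."""
        if self.mu_en_rho_table is not None:
            cm2g = xraydata.loglog_interp(energy_kev, self.mu_en_rho_table)
        else:
            cm2g = sum(w * xraydata.element_mu_en_rho(s, energy_kev) for s, w in self.composition.entries)
            if not self.composition.entries:
                cm2g = np.zeros_like(np.asarray(energy_kev, dtype=float)) if np.ndim(energy_kev) else 0.0
                xraydata.loglog_interp(energy_kev, np.ones_like(xraydata.ENERGY_GRID_KEV))
        return cm2g * 0.1


@dataclass(frozen=True)
class OpticalConstants:
    """delta, beta, mu and mu_en/rho of a material at one photon energy."""

    energy: float  # keV
    delta: float
    beta: float
    mu: float  # 1/m
    mu_en_rho: float  # m^2/kg


def optical_constants(material: Material, energy_kev: float) -> OpticalConstants:
    """X-ray optical constants at ``energy_kev`` (10-150 keV).

    delta comes from the electron density (forward scattering, f1 ~ Z);
    beta from the total mass attenuation via mu = 4*pi*beta/lambda.  The
    ratio delta/beta is independent of the mass density.
    """
    lam = wavelength_m(energy_kev)
    rho_kg_m3 = material.density * 1e3
    mu = material.mu_rho(energy_kev) * rho_kg_m3  # 1/m
    n_e = material.composition.electrons_per_kg() * rho_kg_m3  # 1/m^3
    delta = R_ELECTRON_M * lam**2 * n_e / (2.0 * np.pi)
    beta = mu * lam / (4.0 * np.pi)
    return OpticalConstants(energy_kev, delta, beta, mu, material.mu_en_rho(energy_kev))


def delta_beta_ratio(material: Material, energy_kev: float) -> float:
    """delta/beta for a material; density cancels."""
    oc = optical_constants(material, energy_kev)
    if oc.beta == 0.0:
        raise ValueError(f"material {material.name!r} has zero absorption; delta/beta undefined")
    return oc.delta / oc.beta


def mu_en_over_rho(material: Material, energy_kev: float) -> float:
    """Mass energy-absorption coefficient [m^2/kg], mixture rule."""
    return material.mu_en_rho(energy_kev)


def r_ab_air(energy_kev: float) -> float:
    """Kerma normalisation factor R_ab,air = E_ph * (mu_en/rho)_air [J m^2/kg].

    Dividing an absorbed dose by it yields the photon fluence that would
    deliver that dose as air kerma; it makes the biomedical image-quality
    characteristic dimensionless.
    """
    return energy_kev * KEV_TO_J * AIR.mu_en_rho(energy_kev)


# ---------------------------------------------------------------------------
# canonical materials

VACUUM = Material("vacuum", 0.0, ElementComposition(()))
WATER = Material(
    "water", 1.000, ElementComposition.from_mass_fractions({"H": 0.111894, "O": 0.888106}),
    mu_rho_table=tuple(xraydata.WATER_MU_RHO), mu_en_rho_table=tuple(xraydata.WATER_MU_EN_RHO),
)
AIR = Material(
    "air", 1.20479e-3,
    ElementComposition.from_mass_fractions({"C": 0.000124, "N": 0.755268, "O": 0.231781, "Ar": 0.012827}),
    mu_rho_table=tuple(xraydata.AIR_MU_RHO), mu_en_rho_table=tuple(xraydata.AIR_MU_EN_RHO),
)

_LUNG_ICRU44_PCT = {"H": 10.3, "C": 10.5, "N": 3.1, "O": 74.9, "Na": 0.2, "P": 0.2, "S": 0.3, "Cl": 0.3, "K": 0.2}
LUNG_ICRU44 = Material("lung", 1.050, ElementComposition.from_mass_fractions(_LUNG_ICRU44_PCT))
#: ICRU-44 lung percentages read as atomic abundances (formula-parser
#: convention); source of the published delta/beta ratios used for TIE-Hom.
LUNG_ICRU44_STOICH = Material.from_formula(
    "lung_stoich", "H10.3C10.5N3.1O74.9Na0.2P0.2S0.3Cl0.3K0.2", 1.050
)
SOFT_TISSUE = Material(
    "soft_tissue", 1.060,
    ElementComposition.from_mass_fractions(
        {"H": 10.2, "C": 14.3, "N": 3.4, "O": 70.8, "Na": 0.2, "P": 0.3, "S": 0.3, "Cl": 0.2, "K": 0.3}
    ),
)
BONE_CORTICAL = Material(
    "bone", 1.920,
    ElementComposition.from_mass_fractions(
        {"H": 3.4, "C": 15.5, "N": 4.2, "O": 43.5, "Na": 0.1, "Mg": 0.2, "P": 10.3, "S": 0.3, "Ca": 22.5}
    ),
)

REGISTRY: dict[str, Material] = {
    m.name: m for m in (VACUUM, WATER, AIR, LUNG_ICRU44, LUNG_ICRU44_STOICH, SOFT_TISSUE, BONE_CORTICAL)
}


# ---------------------------------------------------------------------------
# external interfaces

def registry_config_section() -> dict:
    """Materials registry as a config-file section."""
    return {
        name: {
            "density_g_cm3": m.density,
            "composition": {s: w for s, w in m.composition.entries},
        }
        for name, m in REGISTRY.items()
    }


def coefficients_csv(materials=None, energies_kev=None) -> str:
    """CSV export of delta, beta, mu and mu_en/rho on an energy grid."""
    materials = list(REGISTRY.values()) if materials is None else materials
    energies_kev = xraydata.ENERGY_GRID_KEV if energies_kev is None else energies_kev
    buf = _io.StringIO()
    buf.write("material,energy_keV,delta,beta,mu_per_m,mu_en_rho_m2_kg\n")
    for m in materials:
        for e in energies_kev:
            oc = optical_constants(m, float(e))
            buf.write(f"{m.name},{e:g},{oc.delta:.6e},{oc.beta:.6e},{oc.mu:.6e},{oc.mu_en_rho:.6e}\n")
    return buf.getvalue()
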
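"""Voxel Monte Carlo photon transport for kerma-to-dose conversion.

Mono-energetic photons enter the phantom through a horizontal band of
slices (the illuminated rows, emulating the limited beam height) from
uniformly random projection angles in [0, 360) degrees, and are tracked
with Woodcock (delta) tracking through the voxel grid.  Physics:

* photoelectric absorption deposits the full photon energy locally;
* incoherent scattering samples the free-electron Klein-Nishina angular
  distribution; the Compton-electron energy is deposited in the interaction
  voxel (kerma approximation -- CSDA electron ranges at <= 80 keV are below
  the working voxel size);
* coherent (Rayleigh) scattering, off by default, changes direction only;
* photons below the energy cutoff deposit their remaining energy locally.

Channel decomposition is anchored to the tabulated coefficients: the
photoelectric channel is defined as mu_en/rho minus the Klein-Nishina
energy-transfer part, so in a thin medium the expected deposition
coefficient equals the tabulated mass energy-absorption coefficient and the
dose-to-kerma ratio of thin air tends to 1 by construction -- the MC then
tests the transport, not the tables.  Runs are batch-deterministic: photon
batches use seeds spawned from (seed, batch index), so results are
independent of execution order, and per-batch sums provide the statistical
errors of every reported ratio.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._constants import KEV_TO_J
from .compton import kn_differential, kn_mean_energy_transfer_fraction, kn_total_cross_section
from ._constants import R_ELECTRON_M
from . import xraydata
from .materials import Material
from .phantom import VoxelPhantom


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo run configuration."""

    energy: float = 70.0  # keV
    n_photons: int = 200_000
    illuminated_rows: tuple[int, int] | None = None  # (z_lo, z_hi) slice band
    rebin_factor: int = 8
    seed: int = 0
    energy_cutoff: float = 10.0  # keV
    batch_size: int = 50_000
    rayleigh: bool = False
    angle_deg: float | None = None  # fix the projection angle (default: random 360)

    def __post_init__(self):
        if self.n_photons <= 0 or self.batch_size <= 0:
            raise ValueError("n_photons and batch_size must be positive")
        if self.energy_cutoff < xraydata.ENERGY_GRID_KEV[0]:
            raise ValueError("energy cutoff below the tabulated range")


@dataclass
class CrossSectionSet:
    """Per-material partial mass interaction coefficients [m^2/kg]."""

    energies: np.ndarray  # keV grid
    materials: dict[str, Material]
    photoelectric: dict[str, np.ndarray]
    incoherent: dict[str, np.ndarray]
    coherent: dict[str, np.ndarray]

    def total(self, name: str) -> np.ndarray:
        return self.photoelectric[name] + self.incoherent[name] + self.coherent[name]

    def channel_at(self, name: str, channel: str, energy_kev) -> np.ndarray:
        tab = getattr(self, channel)[name]
        loge = np.log(np.asarray(energy_kev, dtype=float))
        safe = np.log(np.clip(tab, 1e-300, None))
        return np.exp(np.interp(loge, np.log(self.energies), safe)) * (tab.max() > 0)


def build_cross_sections(
    materials: dict[str, Material] | list[Material],
    energies_kev=None,
) -> CrossSectionSet:
    """Decompose total attenuation into interaction channels per material.

    incoherent = (electrons/kg) * sigma_KN; photoelectric = mu_en/rho -
    f_tr * incoherent (clipped >= 0); coherent = total - incoherent -
    photoelectric (clipped >= 0).  The three parts sum to the tabulated
    total wherever the clips do not bind (everywhere for the tissues in
    scope above 10 keV).
    """
    if not isinstance(materials, dict):
        materials = {m.name: m for m in materials}
    e = np.asarray(xraydata.ENERGY_GRID_KEV if energies_kev is None else energies_kev, dtype=float)
    sigma = kn_total_cross_section(e)
    f_tr = kn_mean_energy_transfer_fraction(e)
    pe, inc, coh = {}, {}, {}
    for name, m in materials.items():
        if not m.composition.entries:  # vacuum
            pe[name] = np.zeros_like(e)
            inc[name] = np.zeros_like(e)
            coh[name] = np.zeros_like(e)
            continue
        total = np.asarray([m.mu_rho(x) for x in e])
        mu_en = np.asarray([m.mu_en_rho(x) for x in e])
        inc[name] = m.composition.electrons_per_kg() * sigma
        pe[name] = np.clip(mu_en - f_tr * inc[name], 0.0, None)
        coh[name] = np.clip(total - inc[name] - pe[name], 0.0, None)
    return CrossSectionSet(e, dict(materials), pe, inc, coh)


@dataclass
class DoseMap:
    """Per-voxel deposited energy with masses and batch statistics."""

    deposited_kev: np.ndarray  # (nz, ny, nx)
    mass_kg: np.ndarray
    error_kev: np.ndarray  # 1-sigma statistical error per voxel
    n_photons: int
    energy_kev: float
    escaped_kev: float
    illuminated_rows: tuple[int, int]
    fluence_per_m2: float
    # per-batch deposited energy per label, whole volume and illuminated band
    batch_label_kev: np.ndarray = field(default=None)  # (n_batches, 4)
    batch_label_kev_band: np.ndarray = field(default=None)
    batch_total_kev: np.ndarray = field(default=None)
    batch_band_kev: np.ndarray = field(default=None)

    def dose_gy(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = self.deposited_kev * KEV_TO_J / self.mass_kg
        return np.where(self.mass_kg > 0, d, 0.0)

    def energy_ledger_rel_error(self) -> float:
        """|deposited + escaped - injected| / injected."""
        injected = self.n_photons * self.energy_kev
        return abs(self.deposited_kev.sum() + self.escaped_kev - injected) / injected


def _sample_source(rng, n, extent_m, band_m, angle_deg=None):
    """Entry positions/directions: uniform planar fluence over a band.

    Photons start on a virtual entrance plane wide enough to cover the grid
    at any projection angle (the x-y diagonal); direction is horizontal at
    a uniform random angle (or fixed at ``angle_deg``).  Returns
    (pos, dir, fluence width).
    """
    ex, ey, _ = extent_m
    if angle_deg is None:
        theta = rng.uniform(0.0, 2.0 * np.pi, n)
    else:
        theta = np.full(n, np.deg2rad(angle_deg))
    d = np.stack([np.cos(theta), np.sin(theta), np.zeros(n)], axis=1)
    w0 = np.hypot(ex, ey)  # beam width covering the grid at any angle
    t = rng.uniform(-0.5 * w0, 0.5 * w0, n)
    z = rng.uniform(band_m[0], band_m[1], n)
    centre = np.array([ex / 2.0, ey / 2.0])
    perp = np.stack([-d[:, 1], d[:, 0]], axis=1)
    start = centre[None, :] + perp * t[:, None] - d[:, :2] * w0
    pos = np.column_stack([start, z])
    return pos, d, w0


def _advance_to_box(pos, direc, extent_m):
    """Move photons to their grid-entry point; returns mask of hits."""
    lo = np.zeros(3)
    hi = np.asarray(extent_m)
    with np.errstate(divide="ignore"):
        inv = 1.0 / direc
    t1 = (lo - pos) * inv
    t2 = (hi - pos) * inv
    tmin = np.nanmax(np.minimum(t1, t2), axis=1)
    tmax = np.nanmin(np.maximum(t1, t2), axis=1)
    hit = (tmax > np.maximum(tmin, 0.0))
    adv = np.where(hit, np.clip(tmin, 0.0, None) + 1e-9, 0.0)
    pos_new = pos + direc * adv[:, None]
    return pos_new, hit


def _rotate_directions(d, cos_t, phi):
    """Rotate unit vectors ``d`` by polar angle theta and azimuth phi."""
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    # orthonormal basis (u, v, d)
    small = np.abs(d[:, 2]) < 0.99
    a = np.where(small[:, None], np.array([0.0, 0.0, 1.0])[None, :], np.array([1.0, 0.0, 0.0])[None, :])
    u = np.cross(a, d)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    return (
        d * cos_t[:, None]
        + (u * np.cos(phi)[:, None] + v * np.sin(phi)[:, None]) * sin_t[:, None]
    )


def _sample_kn_costheta(rng, energies_kev):
    """Vectorised Klein-Nishina cos(theta) sampling at mixed energies."""
    n = energies_kev.size
    out = np.empty(n)
    todo = np.arange(n)
    majorant = R_ELECTRON_M**2  # dsigma/dOmega at cos(theta) = 1
    while todo.size:
        cand = rng.uniform(-1.0, 1.0, todo.size)
        accept = rng.uniform(0.0, majorant, todo.size) < kn_differential(cand, energies_kev[todo])
        out[todo[accept]] = cand[accept]
        todo = todo[~accept]
    return out


def run_mc(phantom: VoxelPhantom, config: MCConfig, seed: int | None = None) -> DoseMap:
    """Transport ``config.n_photons`` photons; deterministic under the seed."""
    seed = config.seed if seed is None else seed
    labels = phantom.labels
    nz, ny, nx = labels.shape
    voxel_m = phantom.voxel_size * 1e-3
    extent_m = (nx * voxel_m, ny * voxel_m, nz * voxel_m)
    rho = phantom.density_map() * 1e3  # kg/m^3
    mass = rho * voxel_m**3

    xs = build_cross_sections({int(k): v for k, v in phantom.label_materials.items()}.values())
    mat_names = [phantom.label_materials[lab].name if lab in phantom.label_materials
                 else None for lab in range(4)]

    rows = config.illuminated_rows or (0, nz)
    band_m = (rows[0] * voxel_m, rows[1] * voxel_m)
    lab_flat = labels.reshape(-1)

    channels = ["photoelectric", "incoherent"] + (["coherent"] if config.rayleigh else [])

    def mu_rho_used(name, e):  # transported interaction coefficient [m^2/kg]
        out = np.zeros_like(e)
        for ch in channels:
            out = out + xs.channel_at(name, ch, e)
        return out

    dose = np.zeros(labels.size)
    dose_sq = np.zeros(labels.size)
    escaped = 0.0
    n_batches = int(np.ceil(config.n_photons / config.batch_size))
    batch_label = np.zeros((n_batches, 4))
    batch_label_band = np.zeros((n_batches, 4))
    band_vox = np.zeros(labels.size, dtype=bool)
    band_vox.reshape(labels.shape)[rows[0]:rows[1]] = True

    rho_flat = rho.reshape(-1)
    rho_max = {name: (rho_flat[lab_flat == lab].max() if np.any(lab_flat == lab) else 0.0)
               for lab, name in enumerate(mat_names) if name is not None}

    seeds = np.random.SeedSequence(seed).spawn(n_batches)
    w0 = None
    for b in range(n_batches):
        rng = np.random.default_rng(seeds[b])
        n = min(config.batch_size, config.n_photons - b * config.batch_size)
        pos, direc, w0 = _sample_source(rng, n, extent_m, band_m, config.angle_deg)
        pos, hit = _advance_to_box(pos, direc, extent_m)
        energy = np.full(n, config.energy, dtype=np.float64)
        escaped += energy[~hit].sum()
        pos, direc, energy = pos[hit], direc[hit], energy[hit]
        dose_b = np.zeros(labels.size)

        while energy.size:
            # per-photon majorant over materials present
            mu_maj = np.zeros(energy.size)
            for lab, name in enumerate(mat_names):
                if name is None or rho_max.get(name, 0.0) == 0.0:
                    continue
                mu_maj = np.maximum(mu_maj, mu_rho_used(name, energy) * rho_max[name])
            mu_maj = np.maximum(mu_maj, 1e-12)
            step = -np.log(rng.uniform(size=energy.size)) / mu_maj
            pos = pos + direc * step[:, None]
            ij = np.floor(pos / voxel_m).astype(np.int64)
            inside = (
                (ij[:, 0] >= 0) & (ij[:, 0] < nx)
                & (ij[:, 1] >= 0) & (ij[:, 1] < ny)
                & (ij[:, 2] >= 0) & (ij[:, 2] < nz)
            )
            escaped += energy[~inside].sum()
            pos, direc, energy, ij, mu_maj = (
                pos[inside], direc[inside], energy[inside], ij[inside], mu_maj[inside]
            )
            if not energy.size:
                break
            flat_idx = (ij[:, 2] * ny + ij[:, 1]) * nx + ij[:, 0]
            lab_here = lab_flat[flat_idx]
            mu_here = np.zeros(energy.size)
            pe_here = np.zeros(energy.size)
            inc_here = np.zeros(energy.size)
            for lab, name in enumerate(mat_names):
                sel = lab_here == lab
                if name is None or not np.any(sel):
                    continue
                e_sel = energy[sel]
                mu_here[sel] = mu_rho_used(name, e_sel) * rho_flat[flat_idx[sel]]
                pe_here[sel] = xs.channel_at(name, "photoelectric", e_sel) * rho_flat[flat_idx[sel]]
                inc_here[sel] = xs.channel_at(name, "incoherent", e_sel) * rho_flat[flat_idx[sel]]
            u = rng.uniform(size=energy.size)
            real = u < mu_here / mu_maj
            if np.any(real):
                r_idx = np.flatnonzero(real)
                u2 = rng.uniform(size=r_idx.size)
                frac_pe = pe_here[r_idx] / mu_here[r_idx]
                frac_inc = inc_here[r_idx] / mu_here[r_idx]
                is_pe = u2 < frac_pe
                is_inc = (~is_pe) & (u2 < frac_pe + frac_inc)
                is_coh = ~(is_pe | is_inc)
                # photoelectric: full local deposition
                np.add.at(dose_b, flat_idx[r_idx[is_pe]], energy[r_idx[is_pe]])
                # incoherent: KN scatter, electron energy deposited locally
                ii = r_idx[is_inc]
                if ii.size:
                    cos_t = _sample_kn_costheta(rng, energy[ii])
                    e_prime = energy[ii] / (
                        1.0 + energy[ii] / 510.99895 * (1.0 - cos_t)
                    )
                    np.add.at(dose_b, flat_idx[ii], energy[ii] - e_prime)
                    phi_az = rng.uniform(0.0, 2.0 * np.pi, ii.size)
                    direc[ii] = _rotate_directions(direc[ii], cos_t, phi_az)
                    energy[ii] = e_prime
                # coherent: direction change only (Thomson-like)
                ic = r_idx[is_coh]
                if ic.size:
                    cos_t = _sample_thomson_costheta(rng, ic.size)
                    phi_az = rng.uniform(0.0, 2.0 * np.pi, ic.size)
                    direc[ic] = _rotate_directions(direc[ic], cos_t, phi_az)
                # terminate absorbed / cutoff photons
                killed = np.zeros(energy.size, dtype=bool)
                killed[r_idx[is_pe]] = True
                low = energy < config.energy_cutoff
                low &= ~killed
                if np.any(low):
                    np.add.at(dose_b, flat_idx[low], energy[low])
                    killed |= low
                keep = ~killed
                pos, direc, energy = pos[keep], direc[keep], energy[keep]

        dose += dose_b
        dose_sq += dose_b**2
        for lab in range(4):
            sel = lab_flat == lab
            batch_label[b, lab] = dose_b[sel].sum()
            batch_label_band[b, lab] = dose_b[sel & band_vox].sum()

    mean_b = dose / n_batches
    var_b = dose_sq / n_batches - mean_b**2
    err = np.sqrt(np.clip(var_b, 0.0, None) * n_batches)  # error of the sum
    fluence = config.n_photons / (w0 * (band_m[1] - band_m[0]))
    return DoseMap(
        deposited_kev=dose.reshape(labels.shape),
        mass_kg=mass,
        error_kev=err.reshape(labels.shape),
        n_photons=config.n_photons,
        energy_kev=config.energy,
        escaped_kev=float(escaped),
        illuminated_rows=tuple(rows),
        fluence_per_m2=fluence,
        batch_label_kev=batch_label,
        batch_label_kev_band=batch_label_band,
        batch_total_kev=batch_label.sum(axis=1),
        batch_band_kev=batch_label_band.sum(axis=1),
    )


def _sample_thomson_costheta(rng, n):
    """cos(theta) ~ (1 + cos^2) / (8/3), by rejection."""
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        cand = rng.uniform(-1.0, 1.0, todo.size)
        acc = rng.uniform(0.0, 2.0, todo.size) < 1.0 + cand**2
        out[todo[acc]] = cand[acc]
        todo = todo[~acc]
    return out


def transport_photon(phantom: VoxelPhantom, config: MCConfig, seed: int = 0):
    """Single-photon transport: list of (voxel index, deposited keV).

    Convenience wrapper over :func:`run_mc` with one photon; mainly for
    inspection and unit tests of the contract (vacuum -> no deposition).
    """
    dm = run_mc(phantom, replace(config, n_photons=1, batch_size=1), seed=seed)
    idx = np.argwhere(dm.deposited_kev > 0)
    return [(tuple(i), float(dm.deposited_kev[tuple(i)])) for i in idx]


# ---------------------------------------------------------------------------
# kerma and conversion coefficients

def incident_air_kerma(fluence_per_m2: float, energy_kev: float) -> float:
    """Air kerma [mGy] of a planar mono-energetic fluence [photons/m^2]."""
    if fluence_per_m2 < 0:
        raise ValueError("fluence must be >= 0")
    mu_en = xraydata.air_mu_en_rho(energy_kev) * 0.1  # m^2/kg
    return fluence_per_m2 * energy_kev * KEV_TO_J * mu_en * 1e3


@dataclass
class DKRTable:
    """Mean-absorbed-dose to incident-air-kerma ratios per tissue."""

    energy_kev: float
    scope: str  # 'whole' | 'subvolume'
    values: dict[str, tuple[float, float]]  # tissue -> (DKR, MC error)

    def to_csv(self) -> str:
        lines = ["energy_keV,scope,tissue,dkr,mc_error"]
        for t, (v, e) in self.values.items():
            lines.append(f"{self.energy_kev:g},{self.scope},{t},{v:.6g},{e:.3g}")
        return "\n".join(lines) + "\n"


_TISSUE_NAMES = {1: "lung", 2: "soft", 3: "bone"}


def dkr_table(
    dosemap: DoseMap,
    phantom: VoxelPhantom,
    kerma_mgy: float | None = None,
    scope: str = "whole",
    tissues: dict[int, str] = _TISSUE_NAMES,
) -> DKRTable:
    """MAD / K_a,i per tissue with Monte Carlo standard errors.

    ``scope='whole'`` averages over all voxels of each tissue;
    ``scope='subvolume'`` restricts both energy and mass to the illuminated
    band.  If ``kerma_mgy`` is omitted it is computed from the simulated
    fluence.
    """
    if kerma_mgy is None:
        kerma_mgy = incident_air_kerma(dosemap.fluence_per_m2, dosemap.energy_kev)
    if scope not in ("whole", "subvolume"):
        raise ValueError("scope must be 'whole' or 'subvolume'")
    rows = dosemap.illuminated_rows
    band = np.zeros(phantom.labels.shape, dtype=bool)
    band[rows[0]:rows[1]] = True
    batches = dosemap.batch_label_kev if scope == "whole" else dosemap.batch_label_kev_band
    out = {}
    for lab, name in tissues.items():
        sel = phantom.labels == lab
        if scope == "subvolume":
            sel = sel & band
        m = dosemap.mass_kg[sel].sum()
        if m == 0 or not np.any(sel):
            continue
        per_batch_mad = batches[:, lab] * KEV_TO_J / m  # Gy per batch
        nb = per_batch_mad.size
        mad = per_batch_mad.sum() * 1e3  # mGy
        err = np.std(per_batch_mad, ddof=1) * np.sqrt(nb) * 1e3 if nb > 1 else 0.0
        out[name] = (mad / kerma_mgy, err / kerma_mgy)
    return DKRTable(dosemap.energy_kev, scope, out)


def illuminated_fraction(dosemap: DoseMap, region: np.ndarray | None = None) -> float:
    """Fraction of all deposited energy inside ``region`` (default: the
    illuminated band)."""
    total = dosemap.deposited_kev.sum()
    if total == 0:
        raise ValueError("no energy deposited; fraction undefined")
    if region is None:
        region = np.zeros(dosemap.deposited_kev.shape, dtype=bool)
        rows = dosemap.illuminated_rows
        region[rows[0]:rows[1]] = True
    return float(dosemap.deposited_kev[region].sum() / total)


def rebin_phantom(phantom: VoxelPhantom, factor: int = 8) -> VoxelPhantom:
    """Down-sample by ``factor``: majority-vote labels, mean air fraction."""
    if factor == 1:
        return VoxelPhantom(
            phantom.labels.copy(), phantom.voxel_size, dict(phantom.label_materials),
            phantom.air_fraction.copy(), phantom.ground_truth,
        )
    labels = phantom.labels
    pads = [(0, (-s) % factor) for s in labels.shape]
    if any(p[1] for p in pads):
        import logging

        logging.getLogger("pbilung").info("padding phantom with air to a multiple of %d", factor)
        labels = np.pad(labels, pads, constant_values=0)
        af = np.pad(phantom.air_fraction, pads, constant_values=0.0)
    else:
        af = phantom.air_fraction
    nz, ny, nx = (s // factor for s in labels.shape)
    blocks = labels.reshape(nz, factor, ny, factor, nx, factor).transpose(0, 2, 4, 1, 3, 5)
    blocks = blocks.reshape(nz, ny, nx, -1)
    counts = (blocks[..., None] == np.arange(4)).sum(axis=3)
    maj = counts.argmax(axis=-1).astype(np.uint8)
    af_blocks = af.reshape(nz, factor, ny, factor, nx, factor).mean(axis=(1, 3, 5))
    return VoxelPhantom(
        maj, phantom.voxel_size * factor, dict(phantom.label_materials),
        af_blocks.astype(np.float32), phantom.ground_truth,
    )


def per_slice_kerma(flat_profile: np.ndarray, scan_kerma_mgy: float) -> np.ndarray:
    """Row-wise incident air kerma from the (peak-normalised) beam profile."""
    profile = np.asarray(flat_profile, dtype=np.float64)
    if profile.max() <= 0:
        raise ValueError("profile must have a positive peak")
    return scan_kerma_mgy * profile / profile.max()
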
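"""Parallel-beam propagation-based imaging simulator.

Models the synchrotron acquisition end to end: line integrals of delta and
beta through the voxel phantom (projection approximation, one contact
plane), free-space Fresnel propagation over the sample-detector distance by
the angular-spectrum method, horizontal source-size blur scaled by the
geometric magnification of the source, a vertically rolling-off flat field
and a photon-counting detector with tiled-module gaps, hot pixels and
Poisson noise.

The beam is monochromatic and fully coherent apart from the single Gaussian
source blur.  Intensity fringes at tissue-air interfaces live on the
``sqrt(lambda * z)`` scale (about 10 um here), well below the detector
pixel, so projections are upsampled transversely before propagation and the
propagated intensity is re-binned onto detector pixels (``supersample``).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
from scipy import ndimage

from ._constants import wavelength_m
from .materials import optical_constants
from .phantom import LABEL_LUNG, VoxelPhantom

log = logging.getLogger("pbilung")


@dataclass(frozen=True)
class BeamModel:
    """Monochromatic parallel beam with a vertical Gaussian roll-off."""

    energy: float = 70.0  # keV
    distances: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0)  # m, sample-to-detector
    source_distance: float = 138.5  # m
    source_width_h: float = 800.0  # um FWHM, horizontal
    beam_height: float = 25.0  # mm
    center_fluence: float = 2.0e4  # photons / mm^2 per projection at the peak row
    profile_peak_frac: float = 0.35  # peak position as a fraction of the rows
    profile_edge_ratio: float = 1.0 / 30.0  # roll-off at the far detector edge

    def __post_init__(self):
        if self.energy <= 0 or self.center_fluence <= 0 or any(d < 0 for d in self.distances):
            raise ValueError("energy, fluence and distances must be positive")

    def vertical_profile(self, n_rows: int) -> np.ndarray:
        """Relative beam intensity per detector row, peak normalised to 1.

        Gaussian in the row index, calibrated so the detector edge farthest
        from the peak receives ``profile_edge_ratio`` of the peak fluence
        (emulating the measured scan-kerma span of a rolled-off wiggler
        beam).
        """
        if n_rows == 1:
            return np.ones(1)
        rows = np.arange(n_rows, dtype=float)
        peak = self.profile_peak_frac * (n_rows - 1)
        edge = max(peak, (n_rows - 1) - peak)
        width = edge / np.sqrt(np.log(1.0 / self.profile_edge_ratio))
        return np.exp(-(((rows - peak) / width) ** 2))


@dataclass(frozen=True)
class DetectorModel:
    """Photon-counting detector tiled from chips with inter-module gaps."""

    pixel_size: float = 75.0  # um
    chip_px: int = 256  # pixels per chip edge
    gap_h: int = 10  # px, gap between horizontally adjacent modules
    gap_v: int = 36  # px, gap between vertically adjacent modules
    hot_pixel_rate: float = 0.0  # fraction of pixels
    counter_max: int = 65535
    threshold: float | None = None  # keV; metadata only (ideal counter)

    def gap_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of INVALID (gap) pixels for a frame of ``shape``."""
        rows, cols = shape
        mask = np.zeros(shape, dtype=bool)
        for c in range(self.chip_px, cols, self.chip_px):
            lo = c - self.gap_h // 2
            mask[:, max(lo, 0) : min(lo + self.gap_h, cols)] = True
        for r in range(self.chip_px, rows, self.chip_px):
            lo = r - self.gap_v // 2
            mask[max(lo, 0) : min(lo + self.gap_v, rows), :] = True
        return mask

    def hot_mask(self, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        n = int(round(self.hot_pixel_rate * mask.size))
        if n:
            idx = rng.choice(mask.size, size=n, replace=False)
            mask.flat[idx] = True
        return mask


@dataclass(frozen=True)
class ScanGeometry:
    """Rotation scan parameters."""

    n_projections: int = 3600
    angular_range: float = 360.0  # degrees
    rotation_center_offset: float = 0.0  # px, axis shift for off-center scans
    exposure: float = 0.1  # s
    vertical_step: float = 25.0  # mm
    vertical_overlap: float = 12.0  # mm
    n_flats: int = 10

    def __post_init__(self):
        if self.n_projections < 2:
            raise ValueError("need at least 2 projections")
        if self.angular_range not in (180.0, 360.0):
            raise ValueError("angular_range must be 180 or 360 degrees")

    @property
    def scan_time_s(self) -> float:
        return self.n_projections * self.exposure

    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_projections) * (self.angular_range / self.n_projections)


@dataclass
class ProjectionStack:
    """Raw detector frames of one scan plus flats, darks and pixel masks."""

    counts: np.ndarray  # (n_angles, rows, cols)
    flats: np.ndarray  # (n_flats, rows, cols)
    darks: np.ndarray  # (n_darks, rows, cols)
    gap_mask: np.ndarray  # (rows, cols) True = invalid
    hot_mask: np.ndarray
    angles: np.ndarray  # degrees
    beam: BeamModel
    detector: DetectorModel
    geometry: ScanGeometry
    pixel_size: float = 75.0  # um of the simulated frames

    def save_h5(self, path):
        import json

        with h5py.File(path, "w") as f:
            for name in ("counts", "flats", "darks"):
                f.create_dataset(name, data=getattr(self, name), compression="gzip")
            f.create_dataset("gap_mask", data=self.gap_mask)
            f.create_dataset("hot_mask", data=self.hot_mask)
            f.create_dataset("angles", data=self.angles)
            f.attrs["pixel_size_um"] = self.pixel_size
            for name in ("beam", "detector", "geometry"):
                f.attrs[name] = json.dumps(asdict(getattr(self, name)))

    @classmethod
    def load_h5(cls, path) -> "ProjectionStack":
        import json

        with h5py.File(path, "r") as f:
            kw = {n: f[n][...] for n in ("counts", "flats", "darks", "gap_mask", "hot_mask", "angles")}
            beam_d = json.loads(f.attrs["beam"])
            beam_d["distances"] = tuple(beam_d["distances"])
            geo = json.loads(f.attrs["geometry"])
            return cls(
                beam=BeamModel(**beam_d),
                detector=DetectorModel(**json.loads(f.attrs["detector"])),
                geometry=ScanGeometry(**geo),
                pixel_size=float(f.attrs["pixel_size_um"]),
                **kw,
            )


# ---------------------------------------------------------------------------
# optical volumes and projections

def optical_volumes(phantom: VoxelPhantom, energy_kev: float):
    """Per-voxel (delta, mu [1/m]) maps; lung voxels mix tissue and air."""
    delta = np.zeros(phantom.shape, dtype=np.float64)
    mu = np.zeros(phantom.shape, dtype=np.float64)
    for lab in np.unique(phantom.labels):
        m = phantom.label_materials[int(lab)]
        oc = optical_constants(m, energy_kev)
        sel = phantom.labels == lab
        delta[sel] = oc.delta
        mu[sel] = oc.mu
    lung = phantom.labels == LABEL_LUNG
    if np.any(lung):
        af = phantom.air_fraction[lung].astype(np.float64)
        oc_l = optical_constants(phantom.label_materials[LABEL_LUNG], energy_kev)
        oc_a = optical_constants(phantom.label_materials[0], energy_kev)
        delta[lung] = (1.0 - af) * oc_l.delta + af * oc_a.delta
        mu[lung] = (1.0 - af) * oc_l.mu + af * oc_a.mu
    return delta, mu


def project_line_integrals(
    phantom: VoxelPhantom, angles_deg, energy_kev: float
) -> tuple[np.ndarray, np.ndarray]:
    """Parallel-beam projections: attenuation A = int mu dl and phase phi.

    Rays travel along +y of the rotated phantom; detector rows are the
    phantom z axis and columns its x axis.  Rotation uses in-plane linear
    resampling.  Returns (phi, A) with shape (n_angles, nz, nx); phi is the
    physical (negative) phase shift ``-k * int delta dl``.
    """
    delta, mu = optical_volumes(phantom, energy_kev)
    voxel_m = phantom.voxel_size * 1e-3
    k = 2.0 * np.pi / wavelength_m(energy_kev)
    both = np.concatenate([mu, delta], axis=0)  # rotate once per angle
    nz = phantom.shape[0]
    angles_deg = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    A = np.empty((angles_deg.size, nz, phantom.shape[2]))
    phi = np.empty_like(A)
    for i, ang in enumerate(angles_deg):
        if ang % 360.0 == 0.0:
            rot = both
        else:
            rot = ndimage.rotate(
                both, ang, axes=(1, 2), reshape=False, order=1, mode="constant", cval=0.0
            )
        proj = rot.sum(axis=1) * voxel_m
        A[i] = proj[:nz]
        phi[i] = -k * proj[nz:]
    return phi, A


# ---------------------------------------------------------------------------
# wave optics

def fresnel_propagate(
    intensity: np.ndarray,
    phase: np.ndarray,
    z_m: float,
    energy_kev: float,
    pixel_um,
    pad: bool = True,
) -> np.ndarray:
    """Free-space propagation of ``sqrt(I) * exp(i*phi)`` over ``z_m``.

    Exact angular-spectrum transfer function (non-paraxial); ``pixel_um``
    may be a scalar or (row, col) pair for anisotropic sampling.  With
    ``pad=False`` the propagation is unitary (total intensity conserved to
    rounding); with ``pad=True`` frames are edge-padded to suppress
    wrap-around at the borders.  ``z_m = 0`` returns the input bitwise.
    """
    if z_m < 0:
        raise ValueError("propagation distance must be >= 0")
    intensity = np.asarray(intensity, dtype=np.float64)
    if np.ndim(pixel_um) == 0:
        dy = dx = float(pixel_um) * 1e-6
    else:
        dy, dx = (float(p) * 1e-6 for p in pixel_um)
    if z_m == 0.0:
        return intensity.copy()
    lam = wavelength_m(energy_kev)
    rows, cols = intensity.shape
    if lam * z_m > (cols * dx) * dx:
        log.warning(
            "angular-spectrum sampling bound exceeded (lambda*z=%.3g m^2 > N*dx^2=%.3g m^2)",
            lam * z_m, cols * dx * dx,
        )
    py = rows // 2 if pad else 0
    px = cols // 2 if pad else 0
    field_ = np.sqrt(intensity) * np.exp(1j * np.asarray(phase, dtype=np.float64))
    if pad:
        field_ = np.pad(field_, ((py, py), (px, px)), mode="edge")
    fy = np.fft.fftfreq(field_.shape[0], d=dy)[:, None]
    fx = np.fft.fftfreq(field_.shape[1], d=dx)[None, :]
    arg = 1.0 - lam**2 * (fy**2 + fx**2)
    kz = 2.0 * np.pi / lam * np.sqrt(np.clip(arg, 0.0, None))
    h = np.where(arg >= 0.0, np.exp(1j * kz * z_m), 0.0)  # evanescent cut
    out = np.fft.ifft2(np.fft.fft2(field_) * h)
    inten = np.abs(out) ** 2
    if pad:
        inten = inten[py : py + rows, px : px + cols]
    return inten


def apply_source_blur(image: np.ndarray, z_m: float, beam: BeamModel, pixel_um: float) -> np.ndarray:
    """Horizontal Gaussian blur from the finite source size.

    Penumbra FWHM = source_width_h * z / source_distance, projected onto the
    detector; the kernel is normalised so the image mean is preserved.
    """
    if z_m < 0:
        raise ValueError("z must be >= 0")
    fwhm_um = beam.source_width_h * z_m / beam.source_distance
    sigma_px = fwhm_um / 2.3548200450309493 / pixel_um
    if sigma_px < 1e-6:
        return np.asarray(image, dtype=np.float64).copy()
    return ndimage.gaussian_filter1d(np.asarray(image, dtype=np.float64), sigma_px, axis=-1, mode="nearest")


def detect(
    intensity: np.ndarray,
    beam: BeamModel,
    detector: DetectorModel,
    rng: np.random.Generator,
    gap_mask: np.ndarray | None = None,
    hot_mask: np.ndarray | None = None,
) -> np.ndarray:
    """One Poisson-sampled counts frame.

    Expected counts = intensity * peak fluence * vertical profile * pixel
    area; gap pixels read zero (flagged invalid elsewhere), hot pixels read
    above the 16-bit counter limit.
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    if np.any(intensity < 0):
        raise ValueError("intensity must be non-negative")
    rows = intensity.shape[0]
    area_mm2 = (detector.pixel_size * 1e-3) ** 2
    lam = intensity * beam.center_fluence * area_mm2 * beam.vertical_profile(rows)[:, None]
    frame = rng.poisson(lam).astype(np.int64)
    frame = np.minimum(frame, detector.counter_max)
    if gap_mask is not None:
        frame[gap_mask] = 0
    if hot_mask is not None:
        frame[hot_mask] = detector.counter_max
    return frame.astype(np.uint16)


def _bin_columns(arr: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return arr
    r, c = arr.shape
    return arr[:, : c - c % factor].reshape(r, -1, factor).mean(axis=2)


def simulate_projection(
    phi: np.ndarray,
    A: np.ndarray,
    z_m: float,
    energy_kev: float,
    beam: BeamModel,
    pixel_um: float,
    supersample: int = 4,
) -> np.ndarray:
    """Detector-plane intensity for one projection (before counting).

    Upsamples columns by ``supersample`` (cubic), propagates at the fine
    pitch, applies source blur and re-bins onto detector pixels.
    """
    if supersample > 1:
        zoom = (1.0, float(supersample))
        A_f = ndimage.zoom(A, zoom, order=3, mode="nearest", grid_mode=True)
        phi_f = ndimage.zoom(phi, zoom, order=3, mode="nearest", grid_mode=True)
        dx = pixel_um / supersample
    else:
        A_f, phi_f, dx = A, phi, pixel_um
    inten = fresnel_propagate(np.exp(-A_f), phi_f, z_m, energy_kev, (pixel_um, dx))
    inten = apply_source_blur(inten, z_m, beam, dx)
    return _bin_columns(inten, supersample)


def simulate_scan(
    phantom: VoxelPhantom,
    beam: BeamModel,
    detector: DetectorModel,
    geometry: ScanGeometry,
    z_m: float,
    seed: int = 0,
    supersample: int = 4,
) -> ProjectionStack:
    """Full rotation scan -> ProjectionStack (counts + flats + darks + masks).

    The detector pixel pitch is taken equal to the phantom voxel size (the
    grids must be commensurate); ``detector.pixel_size`` is retained as
    metadata for physical-unit conversions of real-detector setups.
    """
    pixel_um = phantom.voxel_size * 1e3
    det = DetectorModel(**{**asdict(detector), "pixel_size": pixel_um})
    angles = geometry.angles_deg()
    phi, A = project_line_integrals(phantom, angles, beam.energy)
    if geometry.rotation_center_offset:
        off = geometry.rotation_center_offset
        A = ndimage.shift(A, (0, 0, off), order=1, mode="constant", cval=0.0)
        phi = ndimage.shift(phi, (0, 0, off), order=1, mode="constant", cval=0.0)
    shape = A.shape[1:]
    ss = np.random.SeedSequence(seed)
    rng_scan, rng_flat, rng_hot = (np.random.default_rng(s) for s in ss.spawn(3))
    gap_mask = det.gap_mask(shape)
    hot_mask = det.hot_mask(shape, rng_hot)
    counts = np.empty((angles.size,) + shape, dtype=np.uint16)
    for i in range(angles.size):
        inten = simulate_projection(phi[i], A[i], z_m, beam.energy, beam, pixel_um, supersample)
        counts[i] = detect(inten, beam, det, rng_scan, gap_mask, hot_mask)
    flat_int = np.ones(shape)
    flats = np.stack(
        [detect(flat_int, beam, det, rng_flat, gap_mask, hot_mask) for _ in range(geometry.n_flats)]
    )
    darks = np.zeros((1,) + shape, dtype=np.uint16)
    return ProjectionStack(counts, flats, darks, gap_mask, hot_mask, angles, beam, det, geometry, pixel_um)
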
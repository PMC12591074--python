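"""Voxelised phantoms: a four-tissue chest surrogate and calibration objects.

The chest phantom emulates a segmented thorax: an elliptic-cylinder of soft
tissue containing two lung lobes, rib cross-sections of cortical bone and a
branching airway of air.  Lung texture follows a Boolean model: the inflated
part of each lobe is filled with overlapping spherical air voids (alveolar
air at the working resolution is represented by a per-voxel air fraction),
the collapsed part is solid lung tissue.  All geometry is parametric, so
label volumes have closed-form expectations, and generation is a pure
function of (spec, seed).

Conventions: labels 0=air, 1=lung, 2=soft tissue, 3=bone; arrays are indexed
(z, y, x) with isotropic voxels; the physical origin is the grid corner and
all geometry is in millimetres; axial slices are indexed along z.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import h5py
import numpy as np
import tifffile

from . import materials as mats
from .materials import Material

LABEL_AIR, LABEL_LUNG, LABEL_SOFT, LABEL_BONE = 0, 1, 2, 3

DEFAULT_LABEL_MATERIALS = {
    LABEL_AIR: mats.AIR,
    LABEL_LUNG: mats.LUNG_ICRU44,
    LABEL_SOFT: mats.SOFT_TISSUE,
    LABEL_BONE: mats.BONE_CORTICAL,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of the chest phantom.

    Default desk-scale grid: 256 x 256 x 32 voxels of 0.2 mm.  ``thorax_rx``
    and ``thorax_ry`` are the elliptic semi-axes of the soft-tissue cylinder
    (``thorax_radius`` of the effective-depth formula is their mean).
    """

    nx: int = 256
    ny: int = 256
    nz: int = 32
    voxel_size: float = 0.2  # mm
    thorax_rx: float = 23.0  # mm
    thorax_ry: float = 18.0  # mm
    lung_offset_x: float = 10.0  # lobe centre offset from midline, mm
    lung_rx: float = 7.5  # mm
    lung_ry: float = 10.5  # mm
    rib_count: int = 8
    rib_radius: float = 1.2  # mm
    airway_radius: float = 1.5  # mm
    branch_radius: float = 0.8  # mm
    alveolar_void_radius_range: tuple[float, float] = (0.3, 1.0)  # mm
    void_volume_density: float = 1.2  # expected sphere volume per unit volume
    inflated_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if min(self.nx, self.ny, self.nz) <= 0 or self.voxel_size <= 0:
            raise ValueError("grid dimensions and voxel size must be positive")
        if not (0.0 <= self.inflated_fraction <= 1.0):
            raise ValueError("inflated_fraction must lie in [0, 1]")
        if self.thorax_rx <= 0 or self.thorax_ry <= 0:
            raise ValueError("thorax semi-axes must be positive")

    @classmethod
    def fitted(cls, nx=256, ny=256, nz=32, voxel_size=0.2, seed=0, **overrides) -> "PhantomSpec":
        """Default anatomy proportionally scaled to the requested field of
        view (the class defaults assume a 51.2 mm FOV)."""
        f = min(nx, ny) * voxel_size / 51.2
        scaled = dict(
            thorax_rx=23.0 * f, thorax_ry=18.0 * f, lung_offset_x=10.0 * f,
            lung_rx=7.5 * f, lung_ry=10.5 * f, rib_radius=max(1.2 * f, 2.5 * voxel_size),
            airway_radius=max(1.5 * f, 2.0 * voxel_size),
            branch_radius=max(0.8 * f, 1.5 * voxel_size),
            alveolar_void_radius_range=(max(0.3 * f, 1.5 * voxel_size), max(1.0 * f, 3.0 * voxel_size)),
        )
        scaled.update(overrides)
        return cls(nx=nx, ny=ny, nz=nz, voxel_size=voxel_size, seed=seed, **scaled)

    @property
    def thorax_radius(self) -> float:
        """Effective cylinder radius R_c [mm] (mean semi-axis)."""
        return 0.5 * (self.thorax_rx + self.thorax_ry)

    @property
    def height(self) -> float:
        """Cylinder height H [mm]."""
        return self.nz * self.voxel_size


@dataclass
class VoxelPhantom:
    """Labelled voxel grid with per-voxel lung air fraction."""

    labels: np.ndarray  # (nz, ny, nx) uint8
    voxel_size: float  # mm, isotropic
    label_materials: dict[int, Material] = field(default_factory=lambda: dict(DEFAULT_LABEL_MATERIALS))
    air_fraction: np.ndarray | None = None  # in [0,1] where labels == LABEL_LUNG
    ground_truth: PhantomSpec | None = None

    def __post_init__(self):
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3 or 0 in self.labels.shape:
            raise ValueError("labels must be a non-empty 3-D grid")
        if not set(np.unique(self.labels)) <= {0, 1, 2, 3}:
            raise ValueError("labels must be in {0, 1, 2, 3}")
        if self.air_fraction is None:
            self.air_fraction = np.zeros_like(self.labels, dtype=np.float32)

    @property
    def shape(self):
        return self.labels.shape

    def density_map(self) -> np.ndarray:
        """Mass density [g/cm^3]; lung voxels mix tissue and air by air fraction."""
        rho = np.empty(self.labels.shape, dtype=np.float64)
        present = np.unique(self.labels)
        for lab in present:
            if lab not in self.label_materials:
                raise KeyError(f"no material registered for present label {lab}")
            rho[self.labels == lab] = self.label_materials[int(lab)].density
        lung = self.labels == LABEL_LUNG
        if np.any(lung):
            af = self.air_fraction[lung].astype(np.float64)
            rho_l = self.label_materials[LABEL_LUNG].density
            rho_a = self.label_materials[LABEL_AIR].density
            rho[lung] = (1.0 - af) * rho_l + af * rho_a
        return rho

    def total_mass_g(self) -> float:
        """Total phantom mass [g]."""
        return float(self.density_map().sum() * (self.voxel_size / 10.0) ** 3)

    # -- persistence --------------------------------------------------------
    def save_h5(self, path):
        with h5py.File(path, "w") as f:
            f.create_dataset("labels", data=self.labels, compression="gzip")
            f.create_dataset("air_fraction", data=self.air_fraction, compression="gzip")
            f.attrs["voxel_size_mm"] = self.voxel_size
            f.attrs["label_materials"] = json.dumps(
                {str(k): m.name for k, m in self.label_materials.items()}
            )
            if self.ground_truth is not None:
                f.attrs["spec_json"] = json.dumps(asdict(self.ground_truth))

    @classmethod
    def load_h5(cls, path) -> "VoxelPhantom":
        with h5py.File(path, "r") as f:
            labels = f["labels"][...]
            af = f["air_fraction"][...]
            vs = float(f.attrs["voxel_size_mm"])
            lm = {
                int(k): mats.REGISTRY[v]
                for k, v in json.loads(f.attrs["label_materials"]).items()
            }
            spec = None
            if "spec_json" in f.attrs:
                d = json.loads(f.attrs["spec_json"])
                d["alveolar_void_radius_range"] = tuple(d["alveolar_void_radius_range"])
                spec = PhantomSpec(**d)
        return cls(labels, vs, lm, af, spec)

    def labels_to_tiff(self, path):
        tifffile.imwrite(path, self.labels)


# ---------------------------------------------------------------------------
# generators

def _grid_mm(spec_or_shape, voxel):
    nz, ny, nx = spec_or_shape
    z = (np.arange(nz) + 0.5) * voxel
    y = (np.arange(ny) + 0.5) * voxel
    x = (np.arange(nx) + 0.5) * voxel
    return np.meshgrid(z, y, x, indexing="ij", sparse=True)


def make_chest_phantom(spec: PhantomSpec, seed: int | None = None) -> VoxelPhantom:
    """Build the four-tissue chest phantom; bitwise deterministic in (spec, seed)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    nz, ny, nx = spec.nz, spec.ny, spec.nx
    vs = spec.voxel_size
    cx, cy = nx * vs / 2.0, ny * vs / 2.0
    if spec.thorax_rx * 2 >= nx * vs or spec.thorax_ry * 2 >= ny * vs:
        raise ValueError("thorax does not fit inside the grid")
    if spec.lung_offset_x + spec.lung_rx >= spec.thorax_rx:
        raise ValueError("lung lobes extend outside the thorax")

    zz, yy, xx = _grid_mm((nz, ny, nx), vs)
    labels = np.zeros((nz, ny, nx), dtype=np.uint8)

    thorax = ((xx - cx) / spec.thorax_rx) ** 2 + ((yy - cy) / spec.thorax_ry) ** 2 <= 1.0
    labels[np.broadcast_to(thorax, labels.shape)] = LABEL_SOFT

    lung_mask = np.zeros_like(labels, dtype=bool)
    for sx in (-1.0, 1.0):
        lobe = (
            ((xx - (cx + sx * spec.lung_offset_x)) / spec.lung_rx) ** 2
            + ((yy - cy) / spec.lung_ry) ** 2
            <= 1.0
        )
        lung_mask |= np.broadcast_to(lobe, labels.shape)
    labels[lung_mask] = LABEL_LUNG

    # rib cross-sections: spheres on an elliptical ring, clear of the lungs
    ring_rx, ring_ry = 0.93 * spec.thorax_rx, 0.93 * spec.thorax_ry
    zmid = nz * vs / 2.0
    for k in range(spec.rib_count):
        ang = 2.0 * np.pi * (k + 0.5) / spec.rib_count
        px, py = cx + ring_rx * np.cos(ang), cy + ring_ry * np.sin(ang)
        sphere = (xx - px) ** 2 + (yy - py) ** 2 + (zz - zmid) ** 2 <= spec.rib_radius**2
        labels[sphere & (labels == LABEL_SOFT)] = LABEL_BONE

    # airway: central z-cylinder plus two lateral branches at mid-height
    airway = (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.airway_radius**2
    airway = np.broadcast_to(airway, labels.shape).copy()
    branch = ((yy - cy) ** 2 + (zz - zmid) ** 2 <= spec.branch_radius**2) & (
        np.abs(xx - cx) <= spec.lung_offset_x
    )
    airway |= branch
    labels[airway] = LABEL_AIR

    # alveolar texture: Boolean model of spherical voids in the inflated part
    air_fraction = np.zeros_like(labels, dtype=np.float32)
    lung_mask = labels == LABEL_LUNG
    # inflated = upper fraction of each lobe in y
    y_top, y_bot = cy - spec.lung_ry, cy + spec.lung_ry
    y_split = y_top + spec.inflated_fraction * (y_bot - y_top)
    inflated = lung_mask & np.broadcast_to(yy < y_split, labels.shape)
    if spec.inflated_fraction > 0 and np.any(inflated):
        r_lo, r_hi = spec.alveolar_void_radius_range
        mean_vol = 4.0 / 3.0 * np.pi * (r_hi**4 - r_lo**4) / (4.0 * (r_hi - r_lo)) if r_hi > r_lo \
            else 4.0 / 3.0 * np.pi * r_lo**3
        region_vol = inflated.sum() * vs**3
        n_voids = rng.poisson(spec.void_volume_density * region_vol / mean_vol)
        idx = np.flatnonzero(inflated)
        picks = rng.integers(0, idx.size, size=n_voids)
        zi, yi, xi = np.unravel_index(idx[picks], labels.shape)
        radii = rng.uniform(r_lo, r_hi, size=n_voids)
        void = np.zeros_like(labels, dtype=bool)
        zc, yc, xc = (zi + 0.5) * vs, (yi + 0.5) * vs, (xi + 0.5) * vs
        for j in range(n_voids):
            r = radii[j]
            # local bounding box to keep the loop cheap
            lo = [max(int((c - r) / vs), 0) for c in (zc[j], yc[j], xc[j])]
            hi = [
                min(int((c + r) / vs) + 2, s)
                for c, s in zip((zc[j], yc[j], xc[j]), labels.shape)
            ]
            sl = tuple(slice(a, b) for a, b in zip(lo, hi))
            d2 = (
                (zz[sl[0], :, :] - zc[j]) ** 2
                + (yy[:, sl[1], :] - yc[j]) ** 2
                + (xx[:, :, sl[2]] - xc[j]) ** 2
            )
            void[sl] |= d2 <= r**2
        air_fraction[void & inflated] = 1.0

    phantom = VoxelPhantom(labels, vs, dict(DEFAULT_LABEL_MATERIALS), air_fraction, spec)
    for lab in (LABEL_AIR, LABEL_LUNG, LABEL_SOFT, LABEL_BONE):
        if not np.any(labels == lab):
            raise RuntimeError(f"degenerate phantom: label {lab} has zero volume")
    return phantom


def make_cylinder_phantom(
    radius_mm: float,
    material: Material,
    grid: tuple[int, int, int] = (8, 256, 256),
    voxel_size: float = 0.2,
    label: int = LABEL_SOFT,
) -> VoxelPhantom:
    """Homogeneous z-axis cylinder of ``material`` in an air background."""
    nz, ny, nx = grid
    if 2 * radius_mm > min(nx, ny) * voxel_size:
        raise ValueError("cylinder radius does not fit in the grid")
    _, yy, xx = _grid_mm(grid, voxel_size)
    cx, cy = nx * voxel_size / 2.0, ny * voxel_size / 2.0
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_mm**2
    labels = np.where(np.broadcast_to(inside, grid), np.uint8(label), np.uint8(LABEL_AIR))
    lm = dict(DEFAULT_LABEL_MATERIALS)
    lm[label] = material
    return VoxelPhantom(labels, voxel_size, lm)


def make_edge_phantom(
    orientation: str,
    pair: tuple[Material, Material],
    grid: tuple[int, int, int] = (8, 128, 128),
    voxel_size: float = 0.2,
) -> VoxelPhantom:
    """Half-space interface between two materials, normal to ``orientation``.

    ``orientation`` is the axis normal to the interface plane ('x' or 'y');
    the first material fills the low-coordinate side.
    """
    m1, m2 = pair
    if m1.name == m2.name and m1.density == m2.density:
        raise ValueError("edge phantom needs two distinct materials (no contrast)")
    nz, ny, nx = grid
    labels = np.zeros(grid, dtype=np.uint8)
    axis = {"x": 2, "y": 1}[orientation]
    half = grid[axis] // 2
    sl = [slice(None)] * 3
    sl[axis] = slice(half, None)
    labels[tuple(sl)] = LABEL_SOFT
    lm = dict(DEFAULT_LABEL_MATERIALS)
    lm[LABEL_AIR] = m1
    lm[LABEL_SOFT] = m2
    return VoxelPhantom(labels, voxel_size, lm)


def density_map(phantom: VoxelPhantom) -> np.ndarray:
    """Module-level alias of :meth:`VoxelPhantom.density_map`."""
    return phantom.density_map()
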
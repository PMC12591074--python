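# Methods

`pbilung` rebuilds, fully in silico, an imaging-protocol optimisation study
for propagation-based phase-contrast (PBI) lung CT at a wiggler beamline:
simulate the acquisition of a four-tissue chest phantom with a
photon-counting detector, run the standard pre-processing chain, retrieve
and reconstruct, score image quality per unit dose, and convert incident
air kerma to per-tissue mean absorbed dose by Monte Carlo. This note
records the models, the parameter choices and their reasons, and the known
limits of each part.

## X-ray data and materials

Elemental mass attenuation (total, coherent included) and mass
energy-absorption coefficients are tabulated in-package on the standard
grid 10–150 keV for H, C, N, O, Na, Mg, P, S, Cl, Ar, K, Ca, typed from
the standard NIST/Hubbell–Seltzer tabulations; interpolation is log–log
linear (no absorption edges exist above 10 keV for these elements). The
dry-air, water and cortical-bone compound tables are carried verbatim and
double as validation targets: the element mixtures rebuilt from the
package's tables reproduce them to <0.2% (water, air; exact for Ar, which
is derived from the air table) and ~0.3% (bone). Trace-element
energy-absorption values are modelled from the channel decomposition
described under *Monte Carlo* below; they carry ≤0.3% of soft-tissue mass,
so their accuracy is noncritical.

Optical constants use the forward-scattering approximation `f1 ≈ Z`
(anomalous corrections are <0.1% for Z ≤ 20 above 10 keV):

    delta = r_e λ² n_e / 2π,   beta = μ λ / 4π,

with `n_e` the electron density and `μ` from the total attenuation. The
ratio `delta/beta` is independent of mass density.

**Two readings of the ICRU-44 lung composition.** The package ships the
lung material in the standard mass-fraction reading (`LUNG_ICRU44`) and in
a stoichiometric reading (`LUNG_ICRU44_STOICH`) in which the ICRU-44
percentage figures are parsed as atoms per formula unit — the convention a
chemical-formula parser applies to a string like
`H10.3C10.5N3.1O74.9Na0.2P0.2S0.3Cl0.3K0.2`. The published lung
`delta/beta` values used for single-distance TIE-Hom retrieval at
beamlines of this class (1.91/1.80/1.67/1.55 ×10³ at 50/60/70/80 keV)
follow the stoichiometric reading exactly (this package reproduces all
four to <0.7%); the mass-fraction reading gives ratios ~7% higher. Both
are exposed; the stoichiometric material is the default for the retrieval
filter, for compatibility with the published ratios, and the mass-fraction
material is used wherever dose or attenuation is computed. For retrieval
the distinction is mild: the ratio only sets the strength of a low-pass
filter.

## Chest phantom (synthetic-data generator)

Labels 0=air, 1=lung, 2=soft tissue, 3=cortical bone on an isotropic voxel
grid (default 256×256×32 at 0.2 mm; every geometric parameter is in mm).
The thorax is an elliptic cylinder of soft tissue; two elliptic-cylinder
lung lobes; rib cross-sections as bone spheres on a ring; a central airway
cylinder with two lateral branches. Alveolar texture is a Boolean model:
the inflated fraction of each lobe (default 0.7) is filled with
overlapping spherical voids, radius 0.3–1.0 mm (resolvable at the
simulated pixel size; the real acinar microstructure is unresolved at
75 µm anyway), at an expected sphere-volume density of 1.2, so the
expected void fraction is `1 − exp(−1.2) ≈ 0.70`. Voids are carried as a
per-voxel air fraction; lung voxel density interpolates between lung
tissue (1.050 g/cm³, the ICRU-44 non-inflated value) and air. Every solid
has a closed-form volume, which the tests compare against the voxelised
counts, and generation is a pure function of (spec, seed).

Not modelled: diaphragm/heart, motion, pathology, anatomical realism
beyond four tissue classes.

## Forward simulation

Parallel, monochromatic, fully coherent beam apart from one horizontal
Gaussian source blur with penumbra FWHM = source width × z / source
distance (800 µm, 138.5 m defaults). Projections are line integrals of
`delta` and `mu` through the phantom (projection approximation: a single
contact plane; valid in the thin-object, paraxial regime at 50–80 keV);
rotation is by in-plane linear resampling. Free-space propagation uses the
exact angular-spectrum transfer function; without padding it is unitary to
rounding (Parseval), with edge padding it suppresses wrap-around.

Edge fringes live on the `sqrt(λz)` ≈ 10 µm scale, below the 75 µm pixel,
so projections are upsampled transversely (cubic, factor 4–8), propagated
at the fine pitch, source-blurred, and re-binned onto detector pixels.
Factor 8 is used where fringe amplitudes are asserted quantitatively;
factor 4 where only orderings matter.

The detector is an idealised photon counter: expected counts = intensity ×
fluence × pixel area × a vertical beam profile, Poisson sampled, 16-bit
counter clip, tiled-chip gap masks (10 px horizontal / 36 px vertical
between modules) flagged invalid, configurable hot pixels pinned above
65000. The threshold setting (half the beam energy) is carried as metadata
only — no charge sharing or spectral response is modelled. The vertical
roll-off is a Gaussian in detector row calibrated so the far edge of the
field receives 1/30 of the peak fluence, emulating the ~29× span of
per-slice incident kerma (290 → 10 mGy) that a rolled-off wiggler beam
produces across one field height.

## Pre-processing

Order: hot-pixel repair on raw frames → flat-field normalisation →
sinogram-space gap in-painting and ring removal → (for 360° off-center
scans) extension to a centred 180° sinogram → reconstruction → vertical
stitching of height steps.

* **Hot pixels**: counts above 65000 in an 8-connected cluster of fewer
  than 10 pixels; replaced by the nearest valid pixel (Euclidean distance
  transform). Larger saturated blobs are treated as signal.
* **Gap in-painting**: harmonic (Laplace) fill of the masked region with
  the surrounding valid pixels as Dirichlet data — the steady state of
  isotropic diffusion; exact for data linear across the gap. Valid pixels
  are returned bitwise unchanged.
* **Ring removal**: ring artifacts are column-coherent gain errors, so the
  correction is an explicit per-column renormalisation, applied only to
  columns the data support as miscalibrated. Detection compares each
  column's angle-averaged mean with a 5-column local median (which equals
  the central value wherever the profile is monotone, so sharp but
  monotone object edges never trigger) against `snr × 4σ` of the counting
  noise, estimated from successive angle differences. Flagged columns are
  renormalised onto the profile interpolated across median-smoothed clean
  columns; runs wider than `la_size` are left alone (indistinguishable
  from signal). The 4σ gate is set so that a stripe-free scan with
  realistic flat statistics yields an expected false-positive count well
  below one column per sinogram — this is what makes the chain provably
  harmless on clean data while still catching sub-percent gain errors.
  This detection-gated design replaces the sorting-based rank filter of
  the classic combined algorithm: on noisy data the rank filter carries a
  ~1% per-column bias near sharp cross-column structure, which a ramp
  filter amplifies into visible rings on perfectly clean scans. The
  `snr/la_size/sm_size` parameters keep their conventional meanings
  (detection scale, maximum stripe run, local window).
* **Off-center conversion**: the second half-turn is mirrored about the
  rotation axis (estimated by cross-correlation of angle-averaged
  profiles, sub-pixel by parabolic refinement) and blended linearly with
  the first across their overlap into a wider, centred 180° sinogram.
* **Stitching**: the nominal overlap (step 25 mm, overlap ~12 mm) seeds a
  windowed search maximising the normalised correlation of candidate
  overlap segments; overlapping slices are blended linearly.

## Phase retrieval and reconstruction

Single-distance TIE-Hom: the Fourier filter
`1 / (1 + π λ z (δ/β) (u² + v²))` applied to the flat-corrected intensity
(edge-padded), then `−ln`, giving the attenuation line integral. At z=0
the filter is unity. FBP is delegated to `skimage.transform.iradon` (ramp
filter, no apodisation by default, linear back-projection), scaled to 1/m
by the pixel size; a rotation-axis column can be given and is shifted to
the detector centre first. Note `iradon` places the axis at column `n//2`;
for even widths this is half a pixel from the array centre — quantitative
tests that compare against rotations use odd grids, where all conventions
coincide.

The retrieval/FBP pair is validated on its own forward model: a simulated
lung-material cylinder at 70 keV / 7 m reconstructs its interior µ to
0.2% and suppresses the rim overshoot from ~58–85% (attenuation-only
reconstruction) to ~0.2–2%; halving the ratio leaves residual edge
enhancement, doubling it over-smooths — the behaviour used in practice to
sanity-check the ratio choice.

## Image quality

* **CNR** between soft tissue and air ROIs: `|G_t − G_a| / sqrt(σ_t² +
  σ_a²)`, averaged over four ROI pairs placed automatically from the
  ground-truth labels (largest inscribed squares, greedily spread);
  reported with its standard deviation. The quadrature-sum denominator
  makes the metric invariant under global affine rescaling.
* **Spatial resolution** R: profiles across a tissue–air interface
  (perpendicular to the structure-tensor edge direction, or row-wise),
  averaged to an ESF, differentiated by central differences, and the LSF
  fitted with a Gaussian initialised from moments. The central-difference
  kernel convolves the LSF with a 2-px boxcar, so 1/3 px² is subtracted
  from the fitted variance before `R = 2.3548 σ` (2√(2 ln 2), the exact
  Gaussian FWHM factor). Fits with σ at the sampling floor are flagged
  resolution-limited. On noisy synthetic edges with known σ = 100 µm the
  estimator recovers R within 10% in ≥95/100 trials.
* **Q_c**: the printed forms of the CNR and Q_c equations were not
  recoverable from the source text, so the package fixes them from their
  stated structure and dimensional closure:

      R_ab,air = E_ph (μ_en/ρ)_air        [J·m²/kg]
      L        = V/Ω = π R_c / 2          (cylinder volume / entrance area)
      Q_c      = CNR · sqrt( R_ab,air · L / (D · R³) )

  `D / R_ab,air` is the photon fluence that would deliver the dose D as
  air kerma, `(D/R_ab,air)/L` the corresponding volumetric photon density,
  and `Q_c = CNR / sqrt(n_V R³)` is the contrast extracted per photon per
  resolution volume — dimensionless, linear in CNR, ∝ D^(−1/2), with R
  cubed because the measurement is volumetric. Uncertainty is first-order
  propagation of the CNR spread and the fit error of R.

## Monte Carlo dosimetry

Photons enter through the illuminated band of slices from uniformly random
(or fixed) horizontal projection angles, over a virtual entrance plane
wide enough to cover the grid at any angle; the planar fluence over that
band normalises the incident air kerma `K = Φ E (μ_en/ρ)_air`. Tracking
is Woodcock (delta) tracking against a per-energy majorant over the
materials present.

**Channel decomposition.** Published partial cross sections are not
tabulated in-package; instead the channels are constructed from the two
coefficients that are: incoherent = electrons/kg × Klein–Nishina σ (free
electron, no binding/Doppler); photoelectric = μ_en/ρ − f_tr × incoherent
(clipped ≥0), where f_tr is the KN mean energy-transfer fraction (64-point
Gauss–Legendre quadrature); coherent = total − incoherent − photoelectric
(clipped ≥0). The three channels sum to the tabulated total, and the
thin-medium expected deposition coefficient equals the tabulated μ_en/ρ by
construction — so the thin-air dose-to-kerma check (DKR → 1) genuinely
tests the transport rather than table round-trips. Photoelectric events
deposit the photon energy locally; Compton events sample the KN angular
density (vectorised rejection; χ² p > 0.01 at 10⁶ samples per energy) and
deposit the electron energy locally (kerma approximation — CSDA electron
ranges at ≤80 keV are below the 0.57 mm working voxel); Rayleigh is off by
default (a few-percent, direction-only channel; when enabled it deflects
with a Thomson-like density); photons below the 10 keV cutoff deposit
locally. The energy ledger (deposited + escaped = injected) holds to
accumulation precision on every run.

Runs are batch-deterministic: fixed-size batches with seeds spawned from
(seed, batch index); per-batch sums per tissue (whole volume and
illuminated band) provide the statistical errors of every DKR. The
mean absorbed dose of a tissue is Σε/Σm over its voxels; DKR = MAD/K,
reported for the whole volume and for the illuminated sub-volume
(necessarily ≥ the whole-volume value). Lung voxels keep the lung
composition with the air-fraction-reduced density (the composition error
of treating alveolar air as tissue is negligible for transport at these
energies). Phantoms can be re-binned by majority vote (factor 8 maps
0.071 mm voxels to the 0.568 mm working scale); DKRs are stable under
re-binning within MC error on smooth phantoms.

Validation against a deterministic oracle: in a beam-aligned narrow water
cylinder, the cross-section-averaged depth dose matches primary
attenuation plus a quadrature first-scatter build-up within 5%. Not
modelled: electron transport, bremsstrahlung, binding/Doppler corrections,
ionisation-chamber response.

## Experiment orchestration and problem sizes

One cell of the (energy × distance) grid = simulate → pre-process →
retrieve/reconstruct → select the matched-MAD slice → score. The per-slice
lung MAD is the per-row incident kerma (scan kerma × vertical profile)
times the Monte Carlo lung DKR; the slice closest to the configured target
is scored, ties broken toward the beam peak — making explicit the fact
that the matched-dose slice sits at different heights in different cells.
Every output carries a configuration hash and the seeds; reruns are
bit-identical.

Desk-scale defaults keep a full 4×4 grid around ten minutes on one CPU:
160²×16 phantom voxels at 0.25 mm, 240 projections over 180°, 3×10⁵
photons/mm² per projection at the profile peak (≈2×10⁴ counts/pixel, safely
inside the 16-bit counter), 10⁵ Monte Carlo photons per energy, matched
lung MAD 0.8 mGy (mid-range of the per-slice span the 1/30 roll-off
produces at this fluence). The experiment cells use centred 180° scans;
the off-center 360° mode and vertical stitching are exercised separately.
The acceptance checks run the two extreme-corner cells, where the
protocol-ordering claims (CNR maximal at 50 keV / 7 m, minimal at
80 keV / 1 m at matched lung MAD; R growing with z at fixed energy) are
asserted.

## What the synthetic study does and does not show

The generator reproduces the *structure* of the real experiment — four
tissue classes, alveolar air–tissue interfaces, beam roll-off, detector
tiling — not its scale or its exact beam. Absolute CNR, R, Q_c and DKR
values depend on the real specimen, the measured kerma and the true beam
profile and are not reproducible at desk scale; orderings, scaling laws
and conversion identities are. Accordingly the tests pin Table-level
physics (delta/beta ratios), metric identities, transport conservation and
qualitative protocol orderings, and treat published absolute DKR and Q_c
values as context only.
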
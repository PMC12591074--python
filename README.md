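# pbilung

Propagation-based phase-contrast (PBI) lung CT, end to end in silico:
protocol optimisation and dosimetry for synchrotron imaging of large
(human-scale) lungs, of the kind performed at wiggler beamlines with
photon-counting detectors.

The lung is hard to image because it is mostly air: millions of air-tissue
interfaces scatter and refract X-rays. PBI turns this problem into signal —
free-space propagation between sample and detector converts the strong
phase gradients at air-tissue interfaces into measurable intensity fringes,
boosting contrast-to-noise by orders of magnitude over attenuation CT.
The price is a protocol-design problem: photon energy and propagation
distance trade contrast against resolution and dose. This package rebuilds
that design study synthetically, so every step can be tested against ground
truth.

## What it contains

* `pbilung.materials` — elemental X-ray data (10–150 keV), tissue
  compositions (ICRU-44), optical constants `n = 1 − δ + iβ`, the lung
  δ/β ratios used for phase retrieval, and the kerma normalisation factor
  `R_ab,air = E_ph (μ_en/ρ)_air`.
* `pbilung.phantom` — a parametric four-tissue chest phantom (air / lung
  with alveolar air-fraction texture / soft tissue / cortical bone) with
  closed-form ground truth, plus cylinder and edge calibration phantoms.
* `pbilung.forward_sim` — parallel-beam projections, angular-spectrum
  Fresnel propagation, source-size blur, a vertically rolling-off flat
  field and a tiled photon-counting detector (gaps, hot pixels, Poisson
  noise, 16-bit counter).
* `pbilung.preprocess` — hot-pixel repair, flat-field correction, harmonic
  gap in-painting, noise-gated ring removal, 360° off-center to 180°
  sinogram conversion, vertical stitching.
* `pbilung.recon` — single-distance TIE-Hom (Paganin) phase retrieval

      T(u,v) filter:  1 / (1 + π λ z (δ/β) (u² + v²)),  then −ln(·),

  followed by filtered back-projection, scaled to linear attenuation.
* `pbilung.quality` — CNR = |G_t − G_a| / √(σ_t² + σ_a²) over four ROI
  pairs; edge-spread resolution R = 2.35 σ of the Gaussian-fitted line
  spread; and the dose-normalised biomedical image-quality characteristic

      Q_c = CNR · √( R_ab,air · L / (D · R³) ),  L = π R_c / 2,

  with D the lung mean absorbed dose of the scored slice.
* `pbilung.dose_mc` — voxel Monte Carlo photon transport (Woodcock
  tracking, Klein–Nishina Compton, kerma approximation) producing
  per-tissue mean-absorbed-dose-to-air-kerma ratios (DKR), whole-volume and
  illuminated-sub-volume, with batch-wise statistical errors, plus
  per-slice kerma from the beam profile.
* `pbilung.pipeline` — the (energy × distance) optimisation experiment:
  simulate → pre-process → reconstruct → select the slice at matched lung
  dose → score, with deterministic seeding and a config-hashed summary.
* `pbilung` CLI — thin subcommands (`phantom`, `simulate`, `preprocess`,
  `reconstruct`, `dose`, `experiment`) over the library.

## Worked example

Tabulated lung δ/β for the retrieval filter, then the four corner cells of
the protocol grid at matched lung dose:

```python
import pbilung as P
from pbilung import pipeline as pl
from pbilung.phantom import PhantomSpec

for e in (50, 60, 70, 80):
    print(f"{e} keV: delta/beta(lung) = {P.delta_beta_ratio(P.LUNG_ICRU44_STOICH, e):.0f}")

cfg = pl.ExperimentConfig(
    energies=(50.0, 80.0), distances=(1.0, 7.0),
    phantom=PhantomSpec(nx=160, ny=160, nz=16, voxel_size=0.25,
                        thorax_rx=17.0, thorax_ry=13.5, lung_offset_x=7.5,
                        lung_rx=5.5, lung_ry=8.0, rib_radius=0.9,
                        airway_radius=1.1, branch_radius=0.6,
                        alveolar_void_radius_range=(0.4, 1.0), seed=11),
    n_projections=240, roi_size=20, matched_mad_mgy=0.8,
    mc_photons=100_000, mc_rebin=2, seed=1,
)
summary, dkr = pl.run_experiment(cfg)
print(summary[["energy_keV", "dist_m", "cnr", "cnr_sd", "R_um", "mad_mGy", "q_c"]]
      .round(3).to_string(index=False))
```

prints (about 45 s on one CPU):

```
50 keV: delta/beta(lung) = 1906
60 keV: delta/beta(lung) = 1793
70 keV: delta/beta(lung) = 1659
80 keV: delta/beta(lung) = 1549
 energy_keV  dist_m    cnr  cnr_sd    R_um  mad_mGy   q_c
       50.0     1.0  8.761   0.213 527.868    0.804 0.023
       50.0     7.0 15.837   1.091 709.391    0.804 0.026
       80.0     1.0  6.475   0.223 272.074    0.797 0.044
       80.0     7.0 10.977   0.507 443.827    0.797 0.036
```

Reading the table: each row is one acquisition protocol, scored on the
reconstructed slice whose lung mean absorbed dose is closest to 0.8 mGy.
CNR is highest at the lowest energy and longest propagation distance
(50 keV, 7 m) — phase contrast grows with distance, and soft-tissue/air
attenuation contrast with softer X-rays — and lowest at (80 keV, 1 m).
The measured resolution R worsens with distance at fixed energy, the
low-pass cost of TIE-Hom retrieval. Q_c folds dose and resolution back in,
which is why its optimum does not sit at the maximum-CNR corner: on this
desk-scale phantom the resolution term dominates and favours the
short-distance, high-energy cell. Absolute values of all metrics are
specific to the phantom, fluence and geometry; the orderings and scaling
laws are the transferable content.

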
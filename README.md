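# pxct — quantitative phase-tomography densitometry for silicified microfossils

Ptychographic X-ray computed tomography (PXCT) maps the refractive-index
decrement δ(**r**) of a specimen in 3D at tens-of-nanometre resolution.
Because δ is proportional to electron density, a phase tomogram is a
quantitative densitometer: each voxel's value converts to electrons per unit
volume, and — under a composition hypothesis — to mass density. For
microfossils silicified in chert this allows the matrix, kerogenous cell
remains, and accessory minerals to be identified *in situ* and
non-destructively, down to discriminating iron-oxide polymorphs (maghemite
4.87 g/cm³ vs magnetite 5.18 vs hematite 5.24) that optical microscopy and
bulk diffraction cannot separate within a single filament.

This package implements that analysis chain as a tested pipeline, together
with a synthetic phantom generator so every stage is verifiable without
beamline data:

- **physics** — δ ↔ electron density ↔ mass density:
  `n_e = 2πδ/(λ²r₀)` and `ρ = n_e·A/(N_A·Z)`, with composition bookkeeping
  (A/Z = 2.00 for SiO₂, 2.10 for Fe₂O₃/Fe₃O₄, 1.92 for a mature-kerogen
  composition C₁₇₅H₁₀₂O₉N₄S₂), mineral-candidate matching, and a
  kerogen-vs-graphite density classifier.
- **phantom** — labeled 3D volumes emulating a FIB-milled chert pillar:
  quartz matrix, ~1 µm tubular kerogen filaments (periodic constrictions,
  discontinuous walls), octahedral/cubic maghemite crystals, cracks/voids,
  Gaussian PSF (partial-volume effect), additive noise; full ground truth.
- **tomo** — parallel-beam forward projection, per-projection
  constant+linear phase-ramp simulation/removal, filtered back projection
  (ram-lak or hann), even/odd angular splitting.
- **resolution** — Fourier shell correlation between half-dataset
  reconstructions with the van Heel–Schatz ½-bit threshold; half-period
  resolution at the crossing.
- **quantify** — intensity segmentation, partial-volume-safe mask erosion
  (default 3 voxels, from requiring a sphere to hold more volume than
  surface voxels: (4π/3)R³ > 4πR²·l ⇒ R > 3l), per-phase histograms,
  Gaussian decomposition with air normalization, and filament-diameter
  morphometrics (a biogenicity cue).
- **pipeline** — configuration, orchestration, TIFF/NRRD/CSV/JSON/YAML I/O,
  and a deterministic per-run report.

## Worked example

The numbered drivers under `analysis/` run the canonical in-silico
experiment: a 128³ phantom at 28.53 nm voxels and 6.2 keV with a
2-voxel-FWHM PSF and 2% noise.

```sh
python analysis/01_build_phantom.py          # phantom + ground truth
python analysis/02_tomography_resolution.py  # FBP + even/odd FSC
python analysis/03_quantify_densities.py     # the densitometry chain
python analysis/04_filament_morphometrics.py # diameter homogeneity
```

`03_quantify_densities.py` prints the phase-identification table
(abridged):

```
    phase  mass_density_g_cm3  sigma_g_cm3  true_density_g_cm3  best_candidate  carbonaceous_class
  kerogen               1.500      0.0508                1.50   mature_kerogen  mature_kerogen
   quartz               2.660      0.0531                2.66   quartz
maghemite               4.870      0.0563                4.87   maghemite

iron-oxide phase candidate ranking: maghemite > magnetite > hematite
```

Every recovered density sits within 0.1% of the generator's truth; the
fitted widths (~0.05 g/cm³) reflect the injected 2% noise; and the
iron-oxide phase is correctly matched to maghemite over magnetite and
hematite — the density-based mineral discrimination the pipeline exists
for. `02_tomography_resolution.py` reports half-period resolutions of
42.3 nm and 56.8 nm at 5% and 10% projection noise (the estimate degrades
monotonically with noise), and `04_filament_morphometrics.py` measures
filament envelope diameters of ~0.9–0.95 µm with a coefficient of variation
of 0.01 for the smooth filament and 0.11 for the periodically constricted
one.

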
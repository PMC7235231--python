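# Methods

## Physical model

A phase tomogram stores the real refractive-index decrement δ(**r**) of the
specimen, n(**r**) = 1 − δ(**r**) + iβ(**r**). Away from absorption edges,

    n_e(r) = 2π δ(r) / (λ² r₀),

with λ the wavelength and r₀ the classical electron radius, so δ is a
direct electron-density probe. Mass density follows under a composition
hypothesis through the molar-mass-per-electron ratio,

    ρ = n_e · A / (N_A · Z).

A/Z is insensitive to the exact mineral formula for light minerals (2.00
for SiO₂, 2.10 for both Fe₂O₃ and Fe₃O₄ — so the conversion cannot itself
bias the iron-oxide identification) and markedly lower for hydrogen-rich
organics (1.92 for the mature-kerogen model composition C₁₇₅H₁₀₂O₉N₄S₂).
Atomic masses come from a bundled IUPAC standard-atomic-weight table;
electron counts are sums of atomic numbers. All conversions are linear, so
1σ Gaussian widths propagate by the same factors as the centers, and the
ρ → n_e → δ → n_e → ρ round trip is exact to floating-point precision.

Default beam geometry: 6.2 keV photons (λ ≈ 2.000 Å) and 28.53 nm isotropic
voxels, matching a typical ptychographic tomography acquisition of chert
pillars; both are configurable.

## Synthetic phantoms

The generator emulates a FIB-milled cylindrical chert pillar in air:

- a uniform quartz matrix (2.66 g/cm³) inside a pillar radius, air outside;
- solid tubular kerogen filaments (1.50 g/cm³), diameter ≈ 35 voxels
  (≈1 µm), optionally hollow with seeded random angular wall gaps
  (emulating discontinuous "saw-tooth" sheath walls) and sinusoidal radius
  modulation for septation-like periodic constrictions. The modulation is
  symmetric about the nominal radius so the mean diameter is preserved.
  The micron-scale irregularity of real silicified kerogen has no
  quantitative generative model in the literature, and this
  gap-fraction/constriction parameterization is a stand-in;
- euhedral maghemite crystals (4.87 g/cm³): octahedra as L1 balls and cubes
  as L∞ balls in voxel space, axis-aligned by default;
- low-density ellipsoidal cracks/voids carved into the kerogen (thermal
  cracking analogue).

Voxels are labeled in painter's order (later inclusions overwrite earlier;
voids overwrite their host), mapped to piecewise-constant δ, blurred with
an isotropic Gaussian PSF (FWHM in voxels; edge mode: constant extension
with the air value, matching a pillar surrounded by air), and degraded with
i.i.d. Gaussian noise specified as a fraction of the matrix δ. One integer
seed determines everything; identical spec+seed is bit-identical.

Defaults mirror the study conditions used by the tests and the acceptance
script: 128³ voxels, PSF FWHM 2 voxels, noise 2% of the matrix δ.

What the phantom does *not* model: photon statistics propagated through
ptychographic phase retrieval (noise is additive white Gaussian),
reconstruction streaks/ring artifacts, sub-voxel crystal habits, kerogen
density heterogeneity, or misalignment between projections. Passing the
recovery tests therefore demonstrates the correctness of the quantification
chain under controlled partial-volume and noise conditions, not robustness
to every artifact of real beamline data.

## Tomography

Forward projection is the discrete parallel-beam Radon transform about the
z axis (skimage's `radon`, slice by slice; rotation centre at pixel N//2),
scaled by the voxel size so projections are line integrals in δ·nm.
Per-projection constant and linear phase components — the residue phase
retrieval leaves in each projection — are simulated by `add_ramp` and
removed by least-squares plane fits over air-only detector margins.
Reconstruction is textbook filtered back projection (skimage `iradon`)
with ram-lak or hann apodization; the "modified" FBP used on beamlines is
unpublished, so fidelity is checked by self-consistency (cylinder NRMSE
≤ 5% at 180 angles on a 128² grid) rather than against beamline output.
On small grids the rim-discretization floor dominates the NRMSE budget,
which is why the consistency tests use ≥128² slices and treat the floor
as the convergence limit of the angle-count sweep.

## Resolution estimation

The projections are split into even- and odd-indexed angular subsets (each
with doubled spacing), reconstructed independently, and compared by
Fourier shell correlation over one-frequency-voxel shells:

    FSC(s) = Re Σ F_A·conj(F_B) / sqrt(Σ|F_A|² · Σ|F_B|²).

A raised-cosine spherical mask (on by default) suppresses box-edge
correlation; shell voxel counts are raw (unadjusted for masking). The
½-bit information threshold T(n) = (0.2071 + 1.9102/√n)/(1.2071 + 0.9102/√n)
is evaluated per shell; the first FSC/threshold crossing f* (linear
interpolation between bracketing shells) gives the half-period resolution
1/(2 f*). Under this convention the Nyquist floor is one voxel width
(28.53 nm at the default geometry); published PXCT half-period
resolutions routinely fall between one and two voxel widths, so values
below two voxels are legitimate, not artifacts. No crossing ⇒ the result is
flagged Nyquist-limited; an FSC that starts below the threshold ⇒ flagged
degenerate, not an exception.

## Densitometry

Segmentation is by ordered intensity cut points only (half-open intervals,
exact partition, no filtering). Boundary voxels mix the δ of adjacent
materials (partial-volume effect), biasing per-phase statistics, so each
mask is eroded before histogram extraction. The default depth comes from
requiring a spherical particle to hold more volume voxels than surface
voxels, (4π/3)R³ > 4πR²·l ⇒ R > 3l: a 3-voxel shrink. A brute-force count
over digitized spheres (ball voxels vs a one-voxel shell centred on the
surface) crosses at R = 3, confirming the continuum answer on the lattice.
Erosion uses Euclidean-distance-transform thresholding (a true isotropic
ball, not a cubic element); an empty eroded mask is flagged, not raised.

Per-phase electron-density histograms (Freedman–Diaconis bins by default)
are fitted with sums of Gaussians by least squares on the binned counts —
a deliberate match to the curve-fitting-on-histograms workflow
practitioners use with commercial plotting software, rather than an EM
mixture fit on voxels. Initialization
takes the highest local maxima; the fit must not worsen its
initialization's residual; overlapping redundant components are flagged
with a warning. A noiseless piecewise-constant phase concentrates in fewer
bins than a fit needs, in which case the sample mean/std of the masked
voxels are used directly. The air peak (lowest center by default,
overridable) calibrates the electron-density zero: its center is
subtracted from all components, absorbing any residual reconstruction
offset. Centers and widths then convert to ρ ± σ per the composition
hypothesis of each phase; candidates are ranked by |ρ_est − ρ_ref| with a
configurable k·σ consistency annotation (default 1σ), ties broken by name.
A carbonaceous phase is classified mature kerogen for ρ ∈ [1.19, 1.77]
g/cm³ (boundaries inclusive), graphitic/amorphous above 2 g/cm³,
indeterminate otherwise; the candidate table separately records the
1.25–1.40 g/cm³ literature reference range for mature kerogen — the two
ranges come from different sources and are deliberately not reconciled.

Filament morphometrics: local diameter = 2 × the Euclidean distance
transform along the medial axis, reported as mean and coefficient of
variation. The medial axis is extracted by a distance-ridge method: voxels
are projected on the mask's principal axis (PCA) and the maximal-EDT voxel
per one-voxel axial slab is the medial point, with slabs within one
maximal radius of either end dropped so end caps do not depress the
profile. This is the package's own implementation, chosen because it is
robust and exact for the elongated tubular masks this operation targets;
blob-like masks (axial extent < 2 diameters) are flagged degenerate.
Diameter means carry a ~3% negative digitization bias (the EDT measures to
background voxel centers), and deep constrictions shadow adjacent bulges,
so CV is the homogeneity statistic to interpret, not sub-5% mean shifts.

## Numerical choices

- Thresholds: strictly increasing, half-open `[t_i, t_{i+1})`; "auto" uses
  midpoints of the true phase electron densities for phantoms (multi-Otsu
  for loaded volumes).
- Gaussian fit bounds: σ > 0, amplitude ≥ 0; convergence failure raises
  with the initial residual attached.
- PSF sum conservation holds to 1e-6 for interior-supported phantoms;
  pillars that touch the z faces lose flux to the constant-extension
  boundary there, a real edge effect excluded from core statistics.
- Determinism: the phantom seed drives geometry (wall gaps) and, offset by
  one, the noise stream; reports serialize with sorted keys and no
  timestamps, so identical config+seed gives byte-identical JSON.
- Volume I/O refuses to invent a physical scale: a TIFF without its JSON
  sidecar (or an NRRD without spacings) is an error.

## Study conditions and problem sizes

The canonical experiments run a 128³ phantom for densitometry (every
eroded phase keeps ≥10³ voxels, the smallest being the crystal cores) and
64³ with 96 angles for the tomography/FSC chain, where reconstruction cost
grows as slices × angles × N² and the smaller grid already exercises every
code path. The matrix-width experiment averages ten seeds.

## Known limitations

- The additive-Gaussian noise model understates the structured noise of
  real ptychographic reconstructions; recovered-width numbers are
  optimistic in that respect.
- Projection alignment is out of scope; synthetic projections are
  generated aligned.
- Gaussian decomposition assumes roughly symmetric unimodal phase
  histograms; strongly skewed phases (severe partial volume on thin
  structures) should be eroded deeper or reported as flagged.
- The filament profiler assumes one connected tubular body per mask;
  branching networks are out of scope.
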
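"""Synthetic phantoms emulating silicified microfossil specimens.

The generator builds labeled 3D volumes of a cylindrical rock pillar in air:
a uniform quartz matrix hosting irregular tubular kerogen bodies (optionally
hollow, with periodic constrictions and discontinuous walls), euhedral
iron-oxide crystals (octahedra and cubes), and low-density voids/cracks.
Labels are converted to refractive-index-decrement (delta) volumes through
the physics module, blurred with an isotropic Gaussian point-spread function
to emulate the partial-volume effect, and degraded with additive Gaussian
noise emulating reconstruction noise.  Everything downstream of the seed is
deterministic, and full ground truth (masks, true densities, volume
fractions) is returned alongside the volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .physics import (
    BeamGeometry,
    Composition,
    delta_from_mass_density,
    electron_density_from_mass_density,
    parse_formula,
)
from .volume import Volume3D

__all__ = [
    "Material",
    "AIR",
    "Tube",
    "Octahedron",
    "Cube",
    "Sphere",
    "EllipsoidVoid",
    "PhantomSpec",
    "GroundTruth",
    "build_phantom",
    "assign_densities",
    "apply_psf",
    "add_noise",
    "mink_mountain_spec",
    "render_phantom",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class Material:
    """A named material with mass density and (for non-air) a composition."""

    name: str
    density_g_cm3: float
    composition: Composition | None = None

    def delta(self, beam: BeamGeometry) -> float:
        if self.density_g_cm3 == 0 or self.composition is None:
            return 0.0
        return float(delta_from_mass_density(self.density_g_cm3, self.composition, beam))

    def electron_density(self) -> float:
        if self.density_g_cm3 == 0 or self.composition is None:
            return 0.0
        return float(
            electron_density_from_mass_density(self.density_g_cm3, self.composition)
        )


AIR = Material("air", 0.0, None)
VOID = Material("void", 0.0, None)


@dataclass(frozen=True)
class Tube:
    """A (possibly hollow) cylindrical filament.

    ``constriction_amplitude`` modulates the local radius sinusoidally about
    its nominal value (mean radius preserved); ``wall_gap_fraction`` knocks
    out random angular/axial wall sectors to emulate the discontinuous
    "saw-tooth" walls of silicified sheaths (seeded draw).
    """

    center: tuple[float, float, float]      # (z, y, x) voxels
    axis: tuple[float, float, float]        # direction, need not be unit
    length: float                           # voxels
    radius: float                           # voxels
    material: Material
    wall_thickness: float | None = None     # None -> solid
    constriction_period: float = 0.0        # voxels along axis, 0 -> none
    constriction_amplitude: float = 0.0     # fraction of radius, in [0, 1)
    wall_gap_fraction: float = 0.0          # in [0, 1)

    def __post_init__(self) -> None:
        if not 0.0 <= self.constriction_amplitude < 1.0:
            raise ValueError("constriction amplitude must be a fraction in [0, 1)")
        if not 0.0 <= self.wall_gap_fraction < 1.0:
            raise ValueError("wall gap fraction must be in [0, 1)")

    def rasterize(self, shape, rng: np.random.Generator) -> np.ndarray:
        u = np.asarray(self.axis, dtype=float)
        u = u / np.linalg.norm(u)
        zz, yy, xx = np.indices(shape, dtype=float)
        p = np.stack(
            [zz - self.center[0], yy - self.center[1], xx - self.center[2]]
        )
        t = np.einsum("i,izyx->zyx", u, p)
        radial = p - t[None] * u[:, None, None, None]
        d = np.sqrt(np.einsum("izyx,izyx->zyx", radial, radial))
        if self.constriction_period > 0 and self.constriction_amplitude > 0:
            r_local = self.radius * (
                1.0
                + self.constriction_amplitude
                * np.sin(2.0 * np.pi * t / self.constriction_period)
            )
        else:
            r_local = np.full_like(t, self.radius)
        inside = (np.abs(t) <= self.length / 2.0) & (d <= r_local)
        if self.wall_thickness is not None:
            inside &= d >= (r_local - self.wall_thickness)
        if self.wall_gap_fraction > 0:
            # perpendicular frame for the angular coordinate around the axis
            a = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(a, u)) > 0.9:
                a = np.array([0.0, 1.0, 0.0])
            e1 = np.cross(u, a)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(u, e1)
            phi = np.arctan2(
                np.einsum("i,izyx->zyx", e2, radial),
                np.einsum("i,izyx->zyx", e1, radial),
            )
            n_sectors, band = 24, max(self.radius, 4.0)
            sector = np.floor((phi + np.pi) / (2 * np.pi) * n_sectors).astype(int)
            sector = np.clip(sector, 0, n_sectors - 1)
            bands = np.floor((t + self.length / 2.0) / band).astype(int)
            n_bands = int(np.ceil(self.length / band)) + 2
            bands = np.clip(bands, 0, n_bands - 1)
            keep = rng.random((n_bands, n_sectors)) >= self.wall_gap_fraction
            inside &= keep[bands, sector]
        return inside


@dataclass(frozen=True)
class Octahedron:
    """Euhedral octahedral crystal: an L1 ball in voxel space (axis-aligned)."""

    center: tuple[float, float, float]
    half_diagonal: float
    material: Material

    def rasterize(self, shape, rng) -> np.ndarray:
        zz, yy, xx = np.indices(shape, dtype=float)
        d = (
            np.abs(zz - self.center[0])
            + np.abs(yy - self.center[1])
            + np.abs(xx - self.center[2])
        )
        return d <= self.half_diagonal


@dataclass(frozen=True)
class Cube:
    """Euhedral cubic crystal: an L-infinity ball in voxel space (axis-aligned)."""

    center: tuple[float, float, float]
    half_edge: float
    material: Material

    def rasterize(self, shape, rng) -> np.ndarray:
        zz, yy, xx = np.indices(shape, dtype=float)
        d = np.maximum(
            np.abs(zz - self.center[0]),
            np.maximum(np.abs(yy - self.center[1]), np.abs(xx - self.center[2])),
        )
        return d <= self.half_edge


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float
    material: Material

    def rasterize(self, shape, rng) -> np.ndarray:
        zz, yy, xx = np.indices(shape, dtype=float)
        r2 = (
            (zz - self.center[0]) ** 2
            + (yy - self.center[1]) ** 2
            + (xx - self.center[2]) ** 2
        )
        return r2 <= self.radius**2


@dataclass(frozen=True)
class EllipsoidVoid:
    """A low-density crack/void; overwrites its host in painter's order."""

    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]    # (z, y, x) voxels
    material: Material = VOID

    def rasterize(self, shape, rng) -> np.ndarray:
        zz, yy, xx = np.indices(shape, dtype=float)
        q = (
            ((zz - self.center[0]) / self.semiaxes[0]) ** 2
            + ((yy - self.center[1]) / self.semiaxes[1]) ** 2
            + ((xx - self.center[2]) / self.semiaxes[2]) ** 2
        )
        return q <= 1.0


Inclusion = Tube | Octahedron | Cube | Sphere | EllipsoidVoid


@dataclass
class PhantomSpec:
    """Declarative phantom description; ``seed`` fully determines the output."""

    shape: tuple[int, int, int]
    beam: BeamGeometry
    matrix_material: Material
    inclusions: Sequence[Inclusion] = field(default_factory=list)
    psf_fwhm_voxels: float = 0.0
    noise_sigma_frac: float = 0.0           # fraction of the matrix delta
    pillar_radius_voxels: float | None = None  # None -> 0.46 * min(ny, nx)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError("shape must be three positive integers")
        self.shape = tuple(int(s) for s in self.shape)
        if self.psf_fwhm_voxels < 0:
            raise ValueError("PSF FWHM must be >= 0")
        if self.noise_sigma_frac < 0:
            raise ValueError("noise sigma must be >= 0")

    @property
    def pillar_radius(self) -> float:
        if self.pillar_radius_voxels is not None:
            return float(self.pillar_radius_voxels)
        return 0.46 * min(self.shape[1], self.shape[2])

    def materials_by_label(self) -> dict[int, Material]:
        out = {0: AIR, 1: self.matrix_material}
        for i, inc in enumerate(self.inclusions):
            out[2 + i] = inc.material
        return out


@dataclass
class GroundTruth:
    """Per-label masks and per-material true densities for a built phantom."""

    masks: dict[int, np.ndarray]                 # label -> boolean mask
    material_for_label: dict[int, Material]
    true_density: dict[str, float]               # material name -> g/cm^3
    true_electron_density: dict[str, float]      # e/A^3
    true_delta: dict[str, float]
    volume_fractions: dict[str, float]           # material name -> fraction

    def material_mask(self, name: str) -> np.ndarray:
        """Union of the masks of every label carrying the named material."""
        out = None
        for label, mat in self.material_for_label.items():
            if mat.name == name:
                m = self.masks[label]
                out = m.copy() if out is None else (out | m)
        if out is None:
            raise KeyError(f"no label carries material {name!r}")
        return out


def build_phantom(spec: PhantomSpec) -> tuple[Volume3D, GroundTruth]:
    """Rasterize the spec into a label volume in painter's order.

    Later inclusions overwrite earlier ones (so voids listed after their host
    carve into it); everything outside the pillar radius is air (label 0), the
    matrix is label 1, inclusion ``i`` is label ``2 + i``.  Seeded draws (wall
    gaps) come from a single generator, so identical spec+seed gives
    bit-identical output.
    """
    shape = spec.shape
    rng = np.random.default_rng(spec.seed)
    labels = np.zeros(shape, dtype=np.uint8)

    zz, yy, xx = np.indices(shape, dtype=float)
    cy, cx = (shape[1] - 1) / 2.0, (shape[2] - 1) / 2.0
    pillar = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.pillar_radius**2
    labels[pillar] = 1

    for i, inc in enumerate(spec.inclusions):
        mask = inc.rasterize(shape, rng)
        mask &= pillar  # inclusions live inside the pillar
        if not mask.any():
            raise ValueError(f"inclusion {i} ({type(inc).__name__}) lies outside the volume")
        labels[mask] = 2 + i

    mats = spec.materials_by_label()
    masks = {lbl: labels == lbl for lbl in mats}
    n_total = labels.size
    fractions: dict[str, float] = {}
    for lbl, mat in mats.items():
        fractions[mat.name] = fractions.get(mat.name, 0.0) + masks[lbl].sum() / n_total
    gt = GroundTruth(
        masks=masks,
        material_for_label=mats,
        true_density={m.name: m.density_g_cm3 for m in mats.values()},
        true_electron_density={m.name: m.electron_density() for m in mats.values()},
        true_delta={m.name: m.delta(spec.beam) for m in mats.values()},
        volume_fractions=fractions,
    )
    vol = Volume3D(grid=labels, channel="label", voxel_size_nm=spec.beam.voxel_size_nm)
    return vol, gt


def assign_densities(
    labels: Volume3D, materials: Mapping[int, Material], beam: BeamGeometry
) -> Volume3D:
    """Map phase labels to a piecewise-constant delta volume."""
    if labels.channel != "label":
        raise ValueError("assign_densities expects a label volume")
    present = np.unique(labels.grid)
    missing = [int(l) for l in present if int(l) not in materials]
    if missing:
        raise KeyError(f"no material assigned to labels {missing}")
    delta = np.zeros(labels.shape, dtype=np.float64)
    for lbl in present:
        delta[labels.grid == lbl] = materials[int(lbl)].delta(beam)
    return Volume3D(grid=delta, channel="delta", voxel_size_nm=labels.voxel_size_nm)


def apply_psf(vol: Volume3D, fwhm_voxels: float, air_value: float = 0.0) -> Volume3D:
    """Isotropic Gaussian blur emulating the finite point-spread function.

    Edge handling is constant extension with the air value, matching a pillar
    surrounded by air.  ``fwhm = 0`` is the identity.
    """
    if fwhm_voxels < 0:
        raise ValueError("PSF FWHM must be >= 0")
    if fwhm_voxels == 0:
        return vol.copy()
    sigma = fwhm_voxels / _FWHM_TO_SIGMA
    blurred = ndimage.gaussian_filter(
        vol.grid.astype(np.float64), sigma=sigma, mode="constant", cval=air_value
    )
    return vol.with_grid(blurred)


def add_noise(vol: Volume3D, sigma: float, seed: int) -> Volume3D:
    """Additive i.i.d. Gaussian noise in absolute delta units, seeded."""
    if sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    if sigma == 0:
        return vol.copy()
    rng = np.random.default_rng(seed)
    return vol.with_grid(vol.grid + rng.normal(0.0, sigma, size=vol.shape))


def render_phantom(spec: PhantomSpec) -> tuple[Volume3D, GroundTruth]:
    """Full forward chain: labels -> delta -> PSF -> noise.

    The noise standard deviation is ``spec.noise_sigma_frac`` times the
    matrix delta (absolute units), drawn with ``spec.seed + 1`` so geometry
    and noise streams are independent.
    """
    labels, gt = build_phantom(spec)
    delta = assign_densities(labels, spec.materials_by_label(), spec.beam)
    delta = apply_psf(delta, spec.psf_fwhm_voxels, air_value=0.0)
    sigma_abs = spec.noise_sigma_frac * spec.matrix_material.delta(spec.beam)
    delta = add_noise(delta, sigma_abs, seed=spec.seed + 1)
    return delta, gt


QUARTZ = Material("quartz", 2.66, parse_formula("SiO2"))
KEROGEN = Material("kerogen", 1.50, parse_formula("C175H102O9N4S2"))
MAGHEMITE = Material("maghemite", 4.87, parse_formula("Fe2O3"))

DEFAULT_BEAM = BeamGeometry(photon_energy_keV=6.2, voxel_size_nm=28.53)


def mink_mountain_spec(
    shape: tuple[int, int, int] = (128, 128, 128),
    seed: int = 0,
    psf_fwhm_voxels: float = 2.0,
    noise_sigma_frac: float = 0.02,
    beam: BeamGeometry = DEFAULT_BEAM,
) -> PhantomSpec:
    """The canonical scene: quartz matrix, two ~1 um kerogen filaments with
    internal cracks, and maghemite octahedral/cubic crystals.

    Filament diameters are ~35 voxels (1.0 um at 28.53 nm voxels); crystal
    sizes are chosen so every phase keeps a sizeable core after the 3-voxel
    partial-volume erosion.
    """
    nz, ny, nx = shape
    s = min(shape) / 128.0  # scale geometry with the grid
    cz, cy, cx = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2
    inclusions: list[Inclusion] = [
        Tube(
            center=(cz, cy - 18 * s, cx - 14 * s),
            axis=(1.0, 0.08, -0.05),
            length=0.92 * nz,
            radius=17.5 * s,
            material=KEROGEN,
            constriction_period=44.0 * s,
            constriction_amplitude=0.15,
        ),
        Tube(
            center=(cz, cy + 22 * s, cx + 18 * s),
            axis=(1.0, -0.06, 0.10),
            length=0.85 * nz,
            radius=16.0 * s,
            material=KEROGEN,
        ),
        Octahedron(
            center=(cz - 24 * s, cy - 18 * s, cx - 14 * s),
            half_diagonal=16.0 * s,
            material=MAGHEMITE,
        ),
        Cube(
            center=(cz + 30 * s, cy + 22 * s, cx + 18 * s),
            half_edge=10.0 * s,
            material=MAGHEMITE,
        ),
        EllipsoidVoid(
            center=(cz + 20 * s, cy - 16 * s, cx - 15 * s),
            semiaxes=(9.0 * s, 5.0 * s, 5.0 * s),
        ),
        EllipsoidVoid(
            center=(cz - 18 * s, cy + 21 * s, cx + 19 * s),
            semiaxes=(7.0 * s, 4.5 * s, 4.5 * s),
        ),
    ]
    return PhantomSpec(
        shape=shape,
        beam=beam,
        matrix_material=QUARTZ,
        inclusions=inclusions,
        psf_fwhm_voxels=psf_fwhm_voxels,
        noise_sigma_frac=noise_sigma_frac,
        seed=seed,
    )
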
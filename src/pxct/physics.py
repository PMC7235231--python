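"""Unit-safe conversions between phase contrast, electron density, and mass density.

Quantitative phase tomography measures the refractive-index decrement
``delta`` of a specimen, ``n(r) = 1 - delta(r) + i*beta(r)``.  For hard
X-rays away from absorption edges ``delta`` is proportional to electron
density,

    n_e(r) = 2*pi*delta(r) / (lambda^2 * r_0),

with ``lambda`` the wavelength and ``r_0`` the classical electron radius.
Electron density converts to mass density through the molar-mass-per-electron
ratio of a hypothesised composition,

    rho = n_e * A / (N_A * Z),

where ``A`` is the molar mass and ``Z`` the electron count per formula unit.
``A/Z`` is close to 2 for light minerals (quartz 2.00, iron oxides 2.10) and
lower for hydrogen-rich organics (mature kerogen 1.92), which is what makes
density-based mineral and kerogen identification possible.

Internal canonical units: wavelength in Angstrom, electron density in e/A^3,
mass density in g/cm^3, voxel size in nm.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources

import numpy as np
from typing import Mapping, Sequence

__all__ = [
    "CONSTANTS",
    "BeamGeometry",
    "Composition",
    "MineralCandidate",
    "DensityEstimate",
    "CandidateMatch",
    "CarbonaceousClass",
    "parse_formula",
    "a_over_z",
    "electron_density_from_delta",
    "delta_from_electron_density",
    "mass_density_from_electron_density",
    "electron_density_from_mass_density",
    "delta_from_mass_density",
    "mass_density_from_delta",
    "load_mineral_candidates",
    "match_candidates",
    "classify_carbonaceous",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA values used throughout; immutable by construction."""

    r0_m: float = 2.8179403262e-15        # classical electron radius, m
    avogadro: float = 6.02214076e23       # 1/mol
    hc_keV_A: float = 12.398420           # photon energy * wavelength, keV*Angstrom

    @property
    def r0_angstrom(self) -> float:
        return self.r0_m * 1e10


CONSTANTS = PhysicalConstants()

_E_PER_A3_TO_E_PER_CM3 = 1e24  # (1 cm / 1 A)^3


@dataclass(frozen=True)
class BeamGeometry:
    """Photon energy and sampling of the reconstruction.

    Parameters
    ----------
    photon_energy_keV : float
        X-ray photon energy in keV (> 0).
    voxel_size_nm : float
        Isotropic voxel width of the reconstructed volume in nm (> 0).
    """

    photon_energy_keV: float
    voxel_size_nm: float

    def __post_init__(self) -> None:
        if self.photon_energy_keV <= 0:
            raise ValueError("photon energy must be positive")
        if self.voxel_size_nm <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def wavelength_angstrom(self) -> float:
        return CONSTANTS.hc_keV_A / self.photon_energy_keV


def _load_atomic_table() -> dict[str, tuple[int, float]]:
    table: dict[str, tuple[int, float]] = {}
    ref = resources.files("pxct.data").joinpath("atomic_weights.csv")
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            table[row["symbol"]] = (
                int(row["atomic_number"]),
                float(row["standard_atomic_weight"]),
            )
    return table


_ATOMIC_TABLE = _load_atomic_table()


@dataclass(frozen=True)
class Composition:
    """A chemical formula with derived molar mass and electron count.

    Attributes
    ----------
    formula : mapping of element symbol to positive integer count
    molar_mass : float, g/mol (``A``)
    electrons : int, electrons per formula unit (``Z``)
    """

    formula: Mapping[str, int]
    molar_mass: float
    electrons: int

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError("molar mass must be positive")
        if self.electrons < 1:
            raise ValueError("electron count must be >= 1")


class FormulaError(ValueError):
    """Raised for malformed or unknown-element chemical formulas."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Composition:
    """Parse ``"C175H102O9N4S2"``-style formulas into a :class:`Composition`.

    Molar mass uses the bundled IUPAC standard-atomic-weight table; the
    electron count is the sum of atomic numbers.  Repeated element symbols
    accumulate (``"CHC"`` counts two carbons).
    """
    if not formula or not formula.strip():
        raise FormulaError("empty formula")
    s = formula.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
        sym, digits = m.group(1), m.group(2)
        if sym not in _ATOMIC_TABLE:
            raise FormulaError(f"unknown element symbol {sym!r} in {formula!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"non-positive count for element {sym!r} in {formula!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    A = sum(n * _ATOMIC_TABLE[sym][1] for sym, n in counts.items())
    Z = sum(n * _ATOMIC_TABLE[sym][0] for sym, n in counts.items())
    return Composition(formula=dict(counts), molar_mass=A, electrons=Z)


def a_over_z(c: Composition, decimals: int | None = None) -> float:
    """Molar mass per electron, optionally rounded to ``decimals`` places."""
    ratio = c.molar_mass / c.electrons
    return round(ratio, decimals) if decimals is not None else ratio


def electron_density_from_delta(delta, beam: BeamGeometry):
    """Electron density (e/A^3) from the refractive-index decrement.

    Accepts scalars or arrays.  Negative ``delta`` (noise or voids) maps to
    negative electron density rather than raising.
    """
    lam = beam.wavelength_angstrom
    return 2.0 * np.pi * np.asarray(delta) / (lam * lam * CONSTANTS.r0_angstrom)


def delta_from_electron_density(n_e, beam: BeamGeometry):
    """Inverse of :func:`electron_density_from_delta` (exact algebraic inverse)."""
    lam = beam.wavelength_angstrom
    return np.asarray(n_e) * lam * lam * CONSTANTS.r0_angstrom / (2.0 * np.pi)


def mass_density_from_electron_density(n_e, c: Composition):
    """Mass density in g/cm^3 from electron density in e/A^3 via rho = n_e*A/(N_A*Z)."""
    return np.asarray(n_e) * _E_PER_A3_TO_E_PER_CM3 * (c.molar_mass / c.electrons) / CONSTANTS.avogadro


def electron_density_from_mass_density(rho, c: Composition):
    """Electron density in e/A^3 from mass density in g/cm^3 (inverse map)."""
    return np.asarray(rho) * CONSTANTS.avogadro / ((c.molar_mass / c.electrons) * _E_PER_A3_TO_E_PER_CM3)


def delta_from_mass_density(rho, c: Composition, beam: BeamGeometry):
    """Refractive-index decrement of a material of density ``rho`` (phantom forward map)."""
    return delta_from_electron_density(electron_density_from_mass_density(rho, c), beam)


def mass_density_from_delta(delta, c: Composition, beam: BeamGeometry):
    """Mass density straight from ``delta`` (composition hypothesis applied)."""
    return mass_density_from_electron_density(electron_density_from_delta(delta, beam), c)


@dataclass(frozen=True)
class MineralCandidate:
    """A named reference material for density matching."""

    name: str
    reference_density: float  # g/cm^3
    composition: Composition
    density_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.reference_density <= 0:
            raise ValueError("reference density must be positive")


@dataclass(frozen=True)
class DensityEstimate:
    """An electron-density measurement and its mass-density conversion.

    Uncertainties are 1-sigma Gaussian widths; the mass-density map is linear,
    so sigma_rho = sigma_ne * (A/Z)/N_A exactly.
    """

    electron_density: float          # e/A^3
    electron_density_sigma: float
    mass_density: float              # g/cm^3
    mass_density_sigma: float
    composition_used: Composition

    def __post_init__(self) -> None:
        if self.electron_density_sigma < 0 or self.mass_density_sigma < 0:
            raise ValueError("uncertainties must be non-negative")

    @classmethod
    def from_electron_density(
        cls, n_e: float, sigma: float, composition: Composition
    ) -> "DensityEstimate":
        rho = float(mass_density_from_electron_density(n_e, composition))
        rho_sigma = float(mass_density_from_electron_density(sigma, composition))
        return cls(
            electron_density=float(n_e),
            electron_density_sigma=float(sigma),
            mass_density=rho,
            mass_density_sigma=abs(rho_sigma),
            composition_used=composition,
        )


@dataclass(frozen=True)
class CandidateMatch:
    candidate: MineralCandidate
    abs_difference: float      # |rho_est - rho_ref|, g/cm^3
    n_sigma: float             # |difference| / sigma (inf when sigma == 0)
    consistent: bool           # |difference| <= k * sigma


def load_mineral_candidates(path=None) -> list[MineralCandidate]:
    """Load the candidate table (bundled Gunflint set by default).

    CSV columns: name, formula, reference_density_g_cm3, range_low_g_cm3,
    range_high_g_cm3.  The bundled table carries quartz, hematite, magnetite,
    maghemite, and a mature-kerogen entry whose literature density range is
    kept alongside its midpoint reference value.
    """
    if path is None:
        ref = resources.files("pxct.data").joinpath("mineral_candidates.csv")
        fh = ref.open("r", encoding="utf-8")
    else:
        fh = open(path, "r", encoding="utf-8")
    out = []
    with fh:
        for row in csv.DictReader(fh):
            lo, hi = row.get("range_low_g_cm3"), row.get("range_high_g_cm3")
            rng = (float(lo), float(hi)) if lo and hi else None
            out.append(
                MineralCandidate(
                    name=row["name"],
                    reference_density=float(row["reference_density_g_cm3"]),
                    composition=parse_formula(row["formula"]),
                    density_range=rng,
                )
            )
    return out


def match_candidates(
    est: DensityEstimate,
    candidates: Sequence[MineralCandidate],
    k_sigma: float = 1.0,
) -> list[CandidateMatch]:
    """Rank candidates by closeness of reference density to the estimate.

    Sorted ascending by ``|rho_est - rho_ref|``; ties broken by candidate name
    so the ranking is a deterministic total order regardless of input order.
    Each match is annotated with whether it lies within ``k_sigma`` standard
    deviations of the estimate.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    sigma = est.mass_density_sigma
    matches = []
    for cand in candidates:
        diff = abs(est.mass_density - cand.reference_density)
        n_sig = diff / sigma if sigma > 0 else float("inf") if diff > 0 else 0.0
        matches.append(
            CandidateMatch(
                candidate=cand,
                abs_difference=diff,
                n_sigma=n_sig,
                consistent=diff <= k_sigma * sigma,
            )
        )
    matches.sort(key=lambda m: (m.abs_difference, m.candidate.name))
    return matches


class CarbonaceousClass(str, Enum):
    """Interpretation of a carbonaceous-phase density.

    Thermally mature kerogen spans 1.19-1.77 g/cm^3; graphite and amorphous
    carbon exceed 2 g/cm^3, so a low measured density argues against an
    abiotic graphitic interpretation.
    """

    MATURE_KEROGEN = "mature_kerogen"
    GRAPHITIC_OR_AMORPHOUS = "graphitic_or_amorphous"
    INDETERMINATE = "indeterminate"


MATURE_KEROGEN_RANGE = (1.19, 1.77)  # g/cm^3, inclusive
GRAPHITIC_CUTOFF = 2.0               # g/cm^3, exclusive lower bound


def classify_carbonaceous(est: DensityEstimate) -> CarbonaceousClass:
    """Classify a carbonaceous phase from its mass-density center (boundaries inclusive)."""
    rho = est.mass_density
    if not np.isfinite(rho):
        raise ValueError("density center must be finite")
    lo, hi = MATURE_KEROGEN_RANGE
    if lo <= rho <= hi:
        return CarbonaceousClass.MATURE_KEROGEN
    if rho > GRAPHITIC_CUTOFF:
        return CarbonaceousClass.GRAPHITIC_OR_AMORPHOUS
    return CarbonaceousClass.INDETERMINATE
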
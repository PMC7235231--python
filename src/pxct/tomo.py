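"""Parallel-beam tomography: forward projection, phase ramps, FBP, splits.

Projections are line integrals of delta through the volume (units delta*nm),
taken slice-by-slice about the z axis.  Conventions follow
``skimage.transform.radon``: rotation centre at pixel ``n // 2``, angle 0
projecting along the +y axis of each (y, x) slice.  Reconstruction is
textbook filtered back projection with a selectable apodization window; the
beamline reconstruction this emulates additionally removes per-projection
constant and linear phase offsets left over from phase retrieval, modeled
here by :func:`add_ramp` / :func:`remove_ramp`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import iradon, radon

from .volume import Volume3D

__all__ = [
    "ProjectionSet",
    "RampModel",
    "forward_project",
    "add_ramp",
    "remove_ramp",
    "air_margin_mask",
    "fbp_reconstruct",
    "split_even_odd",
]

_FILTERS = {"ram-lak": "ramp", "hann": "hann"}


@dataclass
class ProjectionSet:
    """Angle-ordered stack of 2D phase projections.

    ``images`` has shape (n_angles, n_rows, n_cols): rows are the tomographic
    z slices, columns the detector coordinate in the rotation plane.  Pixel
    values are line integrals of delta in units of delta*nm.
    """

    angles_deg: np.ndarray
    images: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.images = np.asarray(self.images)
        if self.angles_deg.ndim != 1:
            raise ValueError("angles must be a 1D sequence")
        if np.any(self.angles_deg < 0) or np.any(self.angles_deg >= 180):
            raise ValueError("angles must lie in [0, 180) degrees")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.images.ndim != 3 or self.images.shape[0] != self.angles_deg.size:
            raise ValueError("images must be (n_angles, n_rows, n_cols)")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def n_angles(self) -> int:
        return int(self.angles_deg.size)


@dataclass
class RampModel:
    """Per-projection plane: offset + slope_x * x + slope_y * y (pixel coords)."""

    offset: np.ndarray   # (n_angles,)
    slope_x: np.ndarray  # per detector column
    slope_y: np.ndarray  # per detector row

    def __post_init__(self) -> None:
        for name in ("offset", "slope_x", "slope_y"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
            setattr(self, name, arr)


def equispaced_angles(n: int) -> np.ndarray:
    """n angles equally spaced over [0, 180) degrees."""
    return np.linspace(0.0, 180.0, n, endpoint=False)


def forward_project(vol: Volume3D, angles_deg) -> ProjectionSet:
    """Discrete Radon transform of a delta volume about the z axis.

    Linear in the input; each projection value is the line integral of delta
    scaled by the voxel size (delta*nm).
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size == 0:
        raise ValueError("angle list is empty")
    nz, ny, nx = vol.shape
    if ny != nx:
        raise ValueError("volume must be square in the rotation plane (pad first)")
    images = np.empty((angles.size, nz, nx), dtype=np.float64)
    with warnings.catch_warnings():
        # noise voxels outside the inscribed circle trip a harmless skimage note
        warnings.filterwarnings(
            "ignore", message="Radon transform: image must be zero outside"
        )
        for z in range(nz):
            sino = radon(vol.grid[z].astype(np.float64), theta=angles)  # (nx, n_angles)
            images[:, z, :] = sino.T * vol.voxel_size_nm
    return ProjectionSet(
        angles_deg=angles, images=images, pixel_size_nm=vol.voxel_size_nm
    )


def add_ramp(p: ProjectionSet, model: RampModel) -> ProjectionSet:
    """Add per-projection constant + linear phase components (simulation aid)."""
    n, rows, cols = p.images.shape
    x = np.arange(cols, dtype=float)
    y = np.arange(rows, dtype=float)
    ramp = (
        np.asarray(model.offset)[:, None, None]
        + np.asarray(model.slope_x)[:, None, None] * x[None, None, :]
        + np.asarray(model.slope_y)[:, None, None] * y[None, :, None]
    )
    return ProjectionSet(p.angles_deg.copy(), p.images + ramp, p.pixel_size_nm)


def air_margin_mask(shape: tuple[int, int], margin: int) -> np.ndarray:
    """Air-only detector mask: the outermost ``margin`` columns on each side."""
    rows, cols = shape
    if margin < 1 or 2 * margin >= cols:
        raise ValueError("margin must be >= 1 and leave interior columns")
    mask = np.zeros(shape, dtype=bool)
    mask[:, :margin] = True
    mask[:, -margin:] = True
    return mask


def remove_ramp(p: ProjectionSet, air_mask: np.ndarray) -> tuple[ProjectionSet, RampModel]:
    """Fit and subtract a plane a + b*x + c*y per projection over air pixels.

    The least-squares fit uses only the air-only mask (regions never shadowed
    by the pillar), so object signal does not bias the fitted plane.  Returns
    the corrected projections and the fitted model.
    """
    air_mask = np.asarray(air_mask, dtype=bool)
    if air_mask.shape != p.images.shape[1:]:
        raise ValueError("air mask shape must match projection shape")
    if not air_mask.any():
        raise ValueError("air mask is empty")
    rows, cols = air_mask.shape
    yy, xx = np.indices((rows, cols), dtype=float)
    A = np.stack(
        [np.ones(air_mask.sum()), xx[air_mask], yy[air_mask]], axis=1
    )
    out = np.empty_like(p.images, dtype=np.float64)
    offs = np.empty(p.n_angles)
    bx = np.empty(p.n_angles)
    by = np.empty(p.n_angles)
    full = np.stack([np.ones(rows * cols), xx.ravel(), yy.ravel()], axis=1)
    for i in range(p.n_angles):
        coef, *_ = np.linalg.lstsq(A, p.images[i][air_mask], rcond=None)
        offs[i], bx[i], by[i] = coef
        out[i] = p.images[i] - (full @ coef).reshape(rows, cols)
    model = RampModel(offset=offs, slope_x=bx, slope_y=by)
    return ProjectionSet(p.angles_deg.copy(), out, p.pixel_size_nm), model


def fbp_reconstruct(p: ProjectionSet, filter_name: str = "ram-lak") -> Volume3D:
    """Slice-by-slice filtered back projection of ramp-corrected projections.

    ``filter_name`` selects the apodization: "ram-lak" (pure ramp) or "hann"
    (ramp * Hann window, trading resolution for noise suppression).  Output
    voxel size equals the detector pixel size.
    """
    if p.n_angles < 2:
        raise ValueError("FBP needs at least 2 projection angles")
    if filter_name not in _FILTERS:
        raise ValueError(f"unknown filter {filter_name!r}; choose from {sorted(_FILTERS)}")
    n_angles, nz, nx = p.images.shape
    grid = np.empty((nz, nx, nx), dtype=np.float64)
    for z in range(nz):
        sino = p.images[:, z, :].T / p.pixel_size_nm  # line integrals in pixel units
        grid[z] = iradon(
            sino,
            theta=p.angles_deg,
            filter_name=_FILTERS[filter_name],
            circle=True,
            output_size=nx,
        )
    return Volume3D(grid=grid, channel="delta", voxel_size_nm=p.pixel_size_nm)


def split_even_odd(p: ProjectionSet) -> tuple[ProjectionSet, ProjectionSet]:
    """Split into even- and odd-indexed angular subsets (double spacing each).

    The two halves are disjoint, their union is the original set, and each is
    an independent measurement of the same object, which is what makes the
    Fourier shell correlation between their reconstructions a resolution
    estimate.
    """
    if p.n_angles < 4:
        raise ValueError("need at least 4 angles to split")
    even = ProjectionSet(p.angles_deg[0::2], p.images[0::2], p.pixel_size_nm)
    odd = ProjectionSet(p.angles_deg[1::2], p.images[1::2], p.pixel_size_nm)
    return even, odd
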
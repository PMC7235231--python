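"""Fourier shell correlation and half-period resolution estimation.

Two independent reconstructions of the same object (here: tomograms from the
even- and odd-angle projection subsets) share signal but not noise, so their
normalized cross-correlation per Fourier shell decays from ~1 at low spatial
frequency toward 0 where noise dominates.  The spatial frequency at which
the FSC curve first drops below the 1/2-bit information threshold of
van Heel & Schatz defines the resolution; we report the half-period length
1 / (2 f*), the convention used for quantitative phase tomograms.

A real-space raised-cosine spherical mask (on by default) suppresses the
spurious correlation contributed by the shared box edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume3D

__all__ = [
    "FSCResult",
    "fsc",
    "half_bit_threshold",
    "resolution_estimate",
    "soft_spherical_mask",
]


@dataclass
class FSCResult:
    """FSC curve, per-shell threshold, and (after estimation) the resolution."""

    frequencies: np.ndarray        # shell centers, cycles/nm, increasing
    correlation: np.ndarray        # real FSC per shell
    n_voxels: np.ndarray           # voxels per shell
    threshold: np.ndarray          # 1/2-bit threshold per shell
    voxel_size_nm: float
    crossing_frequency: float | None = None   # cycles/nm
    resolution_nm: float | None = None        # half-period, 1/(2 f*)
    nyquist_limited: bool = False
    degenerate: bool = False       # FSC below threshold from the first shell

    @property
    def nyquist_frequency(self) -> float:
        return 1.0 / (2.0 * self.voxel_size_nm)


def soft_spherical_mask(
    shape: tuple[int, int, int], radius_frac: float = 0.9, soft_width_frac: float = 0.1
) -> np.ndarray:
    """Raised-cosine sphere: 1 inside, smooth roll-off to 0 at the edge.

    ``radius_frac`` is the outer mask radius as a fraction of the inscribed
    sphere radius; the cosine roll-off occupies the outer ``soft_width_frac``
    of that radius.
    """
    r_max = min(shape) / 2.0
    r_outer = radius_frac * r_max
    r_inner = r_outer * (1.0 - soft_width_frac)
    center = [(s - 1) / 2.0 for s in shape]
    zz, yy, xx = np.indices(shape, dtype=float)
    r = np.sqrt(
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    )
    mask = np.zeros(shape, dtype=np.float64)
    mask[r <= r_inner] = 1.0
    band = (r > r_inner) & (r < r_outer)
    mask[band] = 0.5 * (1.0 + np.cos(np.pi * (r[band] - r_inner) / (r_outer - r_inner)))
    return mask


def half_bit_threshold(n_per_shell) -> np.ndarray:
    """Van Heel-Schatz 1/2-bit information threshold per shell.

    T(n) = (0.2071 + 1.9102/sqrt(n)) / (1.2071 + 0.9102/sqrt(n)); strictly
    decreasing in the shell voxel count, approaching 0.2071/1.2071 ~ 0.1716
    for large shells and ~1 for a single-voxel shell.
    """
    n = np.asarray(n_per_shell, dtype=float)
    if np.any(n < 1):
        raise ValueError("shell voxel counts must be >= 1")
    rt = np.sqrt(n)
    return (0.2071 + 1.9102 / rt) / (1.2071 + 0.9102 / rt)


def fsc(
    volA: Volume3D,
    volB: Volume3D,
    apply_mask: bool = True,
    mask: np.ndarray | None = None,
) -> FSCResult:
    """Fourier shell correlation between two volumes on identical grids.

    Per concentric shell s of one frequency-voxel width,
    FSC(s) = Re sum(F_A conj(F_B)) / sqrt(sum|F_A|^2 sum|F_B|^2).
    """
    if volA.shape != volB.shape:
        raise ValueError("volumes must have identical shapes")
    if not np.isclose(volA.voxel_size_nm, volB.voxel_size_nm):
        raise ValueError("volumes must have identical voxel sizes")
    a = volA.grid.astype(np.float64)
    b = volB.grid.astype(np.float64)
    if apply_mask:
        m = soft_spherical_mask(volA.shape) if mask is None else np.asarray(mask)
        a = a * m
        b = b * m
    elif mask is not None:
        a = a * np.asarray(mask)
        b = b * np.asarray(mask)

    FA = np.fft.fftshift(np.fft.fftn(a))
    FB = np.fft.fftshift(np.fft.fftn(b))

    shape = volA.shape
    coords = [np.arange(s, dtype=float) - s // 2 for s in shape]
    # radius in units of the smallest-axis frequency step so shells are isotropic
    zz, yy, xx = np.meshgrid(
        *[c / s for c, s in zip(coords, shape)], indexing="ij"
    )
    n_shells = min(shape) // 2 + 1
    r = np.sqrt(zz**2 + yy**2 + xx**2) * min(shape)  # shell index units
    shell_idx = np.rint(r).astype(np.intp)
    keep = shell_idx < n_shells
    idx = shell_idx[keep]

    cross = np.bincount(idx, weights=(FA * np.conj(FB)).real[keep], minlength=n_shells)
    pa = np.bincount(idx, weights=(np.abs(FA) ** 2)[keep], minlength=n_shells)
    pb = np.bincount(idx, weights=(np.abs(FB) ** 2)[keep], minlength=n_shells)
    n_vox = np.bincount(idx, minlength=n_shells)

    denom = np.sqrt(pa * pb)
    corr = np.divide(cross, denom, out=np.zeros(n_shells), where=denom > 0)
    freqs = np.arange(n_shells) / (min(shape) * volA.voxel_size_nm)  # cycles/nm
    nonempty = n_vox > 0
    return FSCResult(
        frequencies=freqs[nonempty],
        correlation=corr[nonempty],
        n_voxels=n_vox[nonempty],
        threshold=half_bit_threshold(n_vox[nonempty]),
        voxel_size_nm=volA.voxel_size_nm,
    )


def resolution_estimate(result: FSCResult) -> FSCResult:
    """Locate the first FSC / half-bit-threshold crossing and set the resolution.

    The crossing frequency f* is linearly interpolated between the bracketing
    shells; the half-period resolution is 1 / (2 f*).  If the FSC never drops
    below the threshold the result is flagged Nyquist-limited and the
    resolution is the half period at Nyquist (one voxel width).  If the FSC
    starts below the threshold the result is flagged degenerate (not an
    exception: it is a legitimate outcome for uncorrelated inputs).
    """
    f = result.frequencies
    diff = result.correlation - result.threshold
    # ignore the DC shell when looking for the initial state
    below = np.where(diff < 0)[0]
    below = below[below > 0]
    if below.size == 0:
        f_star = result.nyquist_frequency
        return FSCResult(
            **{
                **result.__dict__,
                "crossing_frequency": f_star,
                "resolution_nm": 1.0 / (2.0 * f_star),
                "nyquist_limited": True,
            }
        )
    i = int(below[0])
    if i == 1 and diff[0] < 0:
        # below threshold from the start: no meaningful crossing
        return FSCResult(**{**result.__dict__, "degenerate": True})
    # linear interpolation of the sign change between shells i-1 and i
    d0, d1 = diff[i - 1], diff[i]
    t = d0 / (d0 - d1)
    f_star = float(f[i - 1] + t * (f[i] - f[i - 1]))
    return FSCResult(
        **{
            **result.__dict__,
            "crossing_frequency": f_star,
            "resolution_nm": 1.0 / (2.0 * f_star),
        }
    )


def fsc_to_table(result: FSCResult):
    """FSC curve as a pandas DataFrame (frequency, fsc, threshold, n_eff)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "frequency_per_nm": result.frequencies,
            "fsc": result.correlation,
            "half_bit_threshold": result.threshold,
            "n_eff": result.n_voxels,
        }
    )
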
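"""Canonical in-silico experiments over the pipeline.

These functions define the study conditions used throughout the project:
128^3 phantoms at 28.53 nm voxels and 6.2 keV, a 2-voxel-FWHM PSF, and
additive Gaussian noise at 2% of the matrix delta.  Analysis drivers, the
test suite, and the acceptance script all call these so the experiments are
defined once.
"""

from __future__ import annotations

import numpy as np

from . import quantify as q
from .phantom import (
    DEFAULT_BEAM,
    QUARTZ,
    PhantomSpec,
    mink_mountain_spec,
    render_phantom,
)
from .physics import (
    DensityEstimate,
    electron_density_from_delta,
    load_mineral_candidates,
    match_candidates,
    parse_formula,
)
from .pipeline import RunConfig, run
from .resolution import fsc, resolution_estimate
from .tomo import equispaced_angles, fbp_reconstruct, forward_project, split_even_odd
from .volume import Volume3D

__all__ = [
    "PHASE_HYPOTHESES",
    "recover_phase_densities",
    "matrix_width_g_cm3",
    "mean_matrix_width_g_cm3",
    "even_odd_resolution_nm",
]

PHASE_HYPOTHESES = {
    "kerogen": "C175H102O9N4S2",
    "quartz": "SiO2",
    "maghemite": "Fe2O3",
}


def recover_phase_densities(
    shape=(128, 128, 128),
    seed: int = 0,
    psf_fwhm_voxels: float = 2.0,
    noise_sigma_frac: float = 0.02,
    output_dir="pxct_recovery",
):
    """Full parameter-recovery experiment on the canonical four-phase phantom.

    Returns the pipeline report plus the phantom's ground truth, so callers
    can compare recovered mass densities against the true values.
    """
    spec = mink_mountain_spec(
        shape=shape,
        seed=seed,
        psf_fwhm_voxels=psf_fwhm_voxels,
        noise_sigma_frac=noise_sigma_frac,
    )
    cfg = RunConfig(
        phantom=spec,
        thresholds="auto",
        phase_labels=["air", "kerogen", "quartz", "maghemite"],
        hypotheses=dict(PHASE_HYPOTHESES),
        output_dir=output_dir,
        seed=seed,
        log_level="WARNING",
    )
    report = run(cfg)
    _, gt = render_phantom(spec)
    return report, gt


def matrix_width_g_cm3(
    seed: int,
    shape=(128, 128, 128),
    psf_fwhm_voxels: float = 2.0,
    noise_sigma_frac: float = 0.02,
) -> float:
    """Fitted 1-sigma width of the matrix-phase histogram in mass-density units.

    A quartz-density pillar in air (no inclusions) is rendered with the PSF
    and noise of the study conditions; the matrix is segmented at the
    air/quartz midpoint, eroded by the partial-volume shrink, and a single
    Gaussian is fitted to its electron-density histogram.  The width converts
    to g/cm^3 through the quartz composition.
    """
    spec = PhantomSpec(
        shape=shape,
        beam=DEFAULT_BEAM,
        matrix_material=QUARTZ,
        inclusions=[],
        psf_fwhm_voxels=psf_fwhm_voxels,
        noise_sigma_frac=noise_sigma_frac,
        seed=seed,
    )
    vol, gt = render_phantom(spec)
    ne = Volume3D(
        grid=np.asarray(electron_density_from_delta(vol.grid, spec.beam)),
        channel="electron_density",
        voxel_size_nm=vol.voxel_size_nm,
    )
    cut = 0.5 * gt.true_electron_density["quartz"]
    _, matrix = q.threshold_segment(ne, [cut], labels=["air", "matrix"])
    eroded = q.erode_mask(matrix, q.min_shrink_voxels())
    hist = q.extract_histogram(ne, eroded)
    fitted = q.fit_gaussians(hist, n_components=1)
    comp = fitted.components[0]
    est = q.estimate_phase_density(comp, parse_formula("SiO2"))
    return est.mass_density_sigma


def mean_matrix_width_g_cm3(base_seed: int = 0, n_seeds: int = 10, **kwargs) -> float:
    """Matrix-width experiment averaged over ``n_seeds`` consecutive seeds."""
    widths = [matrix_width_g_cm3(base_seed + i, **kwargs) for i in range(n_seeds)]
    return float(np.mean(widths))


def even_odd_resolution_nm(
    shape=(64, 64, 64),
    seed: int = 0,
    n_angles: int = 96,
    projection_noise_frac: float = 0.05,
    fbp_filter: str = "hann",
):
    """Even/odd-split FSC resolution of a noisy reconstructed phantom.

    The clean phantom (PSF applied, no volume noise) is forward projected;
    independent Gaussian noise is added to the projections at
    ``projection_noise_frac`` of the maximum projection value; the even- and
    odd-angle subsets are reconstructed separately and their FSC crossing of
    the half-bit threshold gives the half-period resolution in nm.
    """
    spec = mink_mountain_spec(
        shape=shape, seed=seed, psf_fwhm_voxels=2.0, noise_sigma_frac=0.0
    )
    vol, _ = render_phantom(spec)
    proj = forward_project(vol, equispaced_angles(n_angles))
    rng = np.random.default_rng(seed + 101)
    sigma = projection_noise_frac * np.abs(proj.images).max()
    noisy = type(proj)(
        proj.angles_deg, proj.images + rng.normal(0.0, sigma, proj.images.shape),
        proj.pixel_size_nm,
    )
    even, odd = split_even_odd(noisy)
    rec_even = fbp_reconstruct(even, filter_name=fbp_filter)
    rec_odd = fbp_reconstruct(odd, filter_name=fbp_filter)
    return resolution_estimate(fsc(rec_even, rec_odd))
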
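"""Phantom construction: geometry, densities, PSF, noise, determinism."""

import numpy as np
import pytest

from pxct import io as pio
from pxct import phantom as ph
from pxct.phantom import (
    AIR,
    DEFAULT_BEAM,
    KEROGEN,
    MAGHEMITE,
    QUARTZ,
    EllipsoidVoid,
    Octahedron,
    PhantomSpec,
    Tube,
    add_noise,
    apply_psf,
    assign_densities,
    build_phantom,
    mink_mountain_spec,
    render_phantom,
)


def tube_spec(radius=17.5, **tube_kwargs):
    return PhantomSpec(
        shape=(64, 64, 64),
        beam=DEFAULT_BEAM,
        matrix_material=QUARTZ,
        inclusions=[
            Tube(
                center=(31.5, 31.5, 31.5),
                axis=(1, 0, 0),
                length=58,
                radius=radius,
                material=KEROGEN,
                **tube_kwargs,
            )
        ],
        seed=0,
    )


class TestBuildPhantom:
    def test_no_inclusions_pillar_is_matrix(self, small_matrix_spec):
        labels, gt = build_phantom(small_matrix_spec)
        inside = gt.masks[1]
        outside = gt.masks[0]
        assert np.array_equal(labels.grid == 1, inside)
        assert np.array_equal(labels.grid == 0, outside)
        assert inside.sum() + outside.sum() == labels.grid.size

    def test_masks_partition_volume(self):
        _, gt = build_phantom(mink_mountain_spec(shape=(48, 48, 48)))
        total = np.zeros((48, 48, 48), dtype=int)
        for m in gt.masks.values():
            total += m.astype(int)
        assert np.all(total == 1)  # pairwise disjoint and covering
        assert sum(gt.volume_fractions.values()) == pytest.approx(1.0)

    def test_tube_diameter_one_micron(self):
        """35-voxel diameter at 28.53 nm/voxel is the ~1 um filament width."""
        labels, gt = build_phantom(tube_spec(radius=17.5))
        mid = gt.masks[2][32]  # (y, x) cross-section at mid-height
        widths = mid.sum(axis=0).max(), mid.sum(axis=1).max()
        assert max(widths) == pytest.approx(35, abs=1)
        assert 35 * DEFAULT_BEAM.voxel_size_nm == pytest.approx(1000.0, rel=0.02)

    def test_painters_order_void_overwrites_tube(self):
        spec = tube_spec()
        spec.inclusions = list(spec.inclusions) + [
            EllipsoidVoid(center=(31.5, 31.5, 31.5), semiaxes=(5, 4, 4))
        ]
        labels, gt = build_phantom(spec)
        assert gt.masks[3].sum() > 0
        assert not np.any(gt.masks[2] & gt.masks[3])

    def test_inclusion_outside_volume_error_names_index(self):
        spec = tube_spec()
        spec.inclusions = list(spec.inclusions) + [
            Octahedron(center=(500, 500, 500), half_diagonal=4, material=MAGHEMITE)
        ]
        with pytest.raises(ValueError, match="inclusion 1"):
            build_phantom(spec)

    def test_deterministic_given_seed(self):
        spec = mink_mountain_spec(shape=(32, 32, 32), seed=7)
        a, _ = build_phantom(spec)
        b, _ = build_phantom(mink_mountain_spec(shape=(32, 32, 32), seed=7))
        assert np.array_equal(a.grid, b.grid)

    def test_seed_changes_only_wall_gaps(self):
        gapped = dict(wall_thickness=6.0, wall_gap_fraction=0.3)
        s1, s2 = tube_spec(**gapped), tube_spec(**gapped)
        s2.seed = 99
        a, _ = build_phantom(s1)
        b, _ = build_phantom(s2)
        assert not np.array_equal(a.grid, b.grid)  # gaps are seeded
        solid1, solid2 = tube_spec(), tube_spec()
        solid2.seed = 99
        c, _ = build_phantom(solid1)
        d, _ = build_phantom(solid2)
        assert np.array_equal(c.grid, d.grid)  # geometry itself is seed-free

    def test_end_to_end_determinism(self):
        spec = mink_mountain_spec(shape=(32, 32, 32), seed=3)
        v1, _ = render_phantom(spec)
        v2, _ = render_phantom(mink_mountain_spec(shape=(32, 32, 32), seed=3))
        assert np.array_equal(v1.grid, v2.grid)


class TestAssignDensities:
    def test_air_is_zero_and_quartz_delta(self, small_matrix_spec):
        labels, gt = build_phantom(small_matrix_spec)
        vol = assign_densities(labels, small_matrix_spec.materials_by_label(), DEFAULT_BEAM)
        assert np.all(vol.grid[gt.masks[0]] == 0.0)
        assert vol.grid[gt.masks[1]].mean() == pytest.approx(1.43e-5, rel=0.01)

    def test_delta_ratio_maghemite_over_quartz(self):
        """delta is linear in n_e, so the ratio follows (rho/(A/Z)) ratios."""
        ratio = MAGHEMITE.delta(DEFAULT_BEAM) / QUARTZ.delta(DEFAULT_BEAM)
        from pxct.physics import a_over_z

        expected = (4.87 / a_over_z(MAGHEMITE.composition)) / (
            2.66 / a_over_z(QUARTZ.composition)
        )
        assert ratio == pytest.approx(expected, rel=1e-10)

    def test_unmapped_label_raises(self, small_matrix_spec):
        labels, _ = build_phantom(small_matrix_spec)
        with pytest.raises(KeyError, match="1"):
            assign_densities(labels, {0: AIR}, DEFAULT_BEAM)


class TestPSF:
    def test_zero_fwhm_is_identity(self, small_matrix_spec):
        labels, _ = build_phantom(small_matrix_spec)
        vol = assign_densities(labels, small_matrix_spec.materials_by_label(), DEFAULT_BEAM)
        out = apply_psf(vol, 0.0)
        assert np.array_equal(out.grid, vol.grid)

    def test_negative_fwhm_rejected(self, small_matrix_spec):
        labels, _ = build_phantom(small_matrix_spec)
        vol = assign_densities(labels, small_matrix_spec.materials_by_label(), DEFAULT_BEAM)
        with pytest.raises(ValueError):
            apply_psf(vol, -1.0)

    def test_interior_support_conserves_total(self, rng):
        grid = np.zeros((48, 48, 48))
        grid[16:32, 16:32, 16:32] = rng.random((16, 16, 16))
        from tests.conftest import make_volume

        vol = make_volume(grid)
        out = apply_psf(vol, 2.0)
        assert out.grid.sum() == pytest.approx(grid.sum(), rel=1e-6)

    def test_step_interface_takes_intermediate_values(self):
        grid = np.zeros((16, 16, 48))
        grid[:, :, 24:] = 1.0
        from tests.conftest import make_volume

        out = apply_psf(make_volume(grid), 3.0)
        line = out.grid[8, 8, :]
        assert np.all(line >= -1e-12) and np.all(line <= 1 + 1e-12)
        assert np.any((line > 0.1) & (line < 0.9))
        # monotone across the step away from the constant-extension edges
        assert np.all(np.diff(line[12:36]) >= -1e-12)


class TestNoise:
    def test_zero_sigma_identity_and_seed_determinism(self, small_matrix_spec):
        labels, _ = build_phantom(small_matrix_spec)
        vol = assign_densities(labels, small_matrix_spec.materials_by_label(), DEFAULT_BEAM)
        assert np.array_equal(add_noise(vol, 0.0, seed=1).grid, vol.grid)
        n1 = add_noise(vol, 1e-6, seed=5)
        n2 = add_noise(vol, 1e-6, seed=5)
        assert np.array_equal(n1.grid, n2.grid)
        assert not np.array_equal(n1.grid, add_noise(vol, 1e-6, seed=6).grid)

    def test_noise_variance_matches_sigma(self, small_matrix_spec):
        labels, _ = build_phantom(small_matrix_spec)
        vol = assign_densities(labels, small_matrix_spec.materials_by_label(), DEFAULT_BEAM)
        sigma = 2.5e-6
        noisy = add_noise(vol, sigma, seed=11)
        sample_var = (noisy.grid - vol.grid).var()
        assert sample_var == pytest.approx(sigma**2, rel=0.05)


class TestMixtureCenters:
    def test_phase_means_match_truth_after_psf_and_noise(self):
        """Component means stay within 1% of true delta for thick phases."""
        spec = mink_mountain_spec(
            shape=(64, 64, 64), seed=2, psf_fwhm_voxels=1.0, noise_sigma_frac=0.01
        )
        vol, gt = render_phantom(spec)
        from scipy import ndimage

        for name in ("quartz", "kerogen"):
            mask = gt.material_mask(name)
            core = ndimage.distance_transform_edt(mask) > 4  # >= 4x FWHM from edges
            assert vol.grid[core].mean() == pytest.approx(
                gt.true_delta[name], rel=0.01
            )


class TestSpecYaml:
    def test_round_trip_preserves_rendered_volume(self, tmp_path):
        spec = mink_mountain_spec(shape=(32, 32, 32), seed=5)
        path = tmp_path / "spec.yaml"
        pio.spec_to_yaml(spec, path)
        spec2 = pio.spec_from_yaml(path)
        v1, _ = render_phantom(spec)
        v2, _ = render_phantom(spec2)
        assert np.array_equal(v1.grid, v2.grid)

    @pytest.mark.parametrize("bad", [-0.1])
    def test_invalid_psf_or_noise_rejected(self, bad):
        with pytest.raises(ValueError):
            PhantomSpec(
                shape=(8, 8, 8),
                beam=DEFAULT_BEAM,
                matrix_material=QUARTZ,
                psf_fwhm_voxels=bad,
            )
        with pytest.raises(ValueError):
            Tube(
                center=(0, 0, 0),
                axis=(1, 0, 0),
                length=5,
                radius=2,
                material=KEROGEN,
                constriction_amplitude=1.5,
            )
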
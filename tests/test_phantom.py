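import numpy as np
import pytest

from embolimetry import (
    CONTINUOUS,
    PULSED,
    ParticleSet,
    PhantomSpec,
    RegimeSpec,
    add_ct_noise,
    ellipsoid_volume_ml,
    generate_kidney_mask,
    rasterize_particles,
    sample_particles,
    simulate_kidney,
)
from embolimetry.phantom import (
    grid_shape_for,
    sample_truncated_exponential,
    truncated_exponential_cdf,
    truncated_exponential_mean,
)
from embolimetry.stratify import surface_distance_field


class TestEllipsoidVolume:
    def test_sphere_special_case(self):
        assert ellipsoid_volume_ml(10, 10, 10) == pytest.approx(0.5236, abs=5e-5)

    def test_degenerate_axis(self):
        assert ellipsoid_volume_ml(0, 50, 60) == 0.0

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            ellipsoid_volume_ml(-1, 10, 10)

    def test_matches_fine_grid_integration(self):
        # count voxel centers of a 0.05 mm grid inside the ellipsoid;
        # per-slice searchsorted keeps the full 1.2e9-point count tractable
        L, W, H = 66.4, 50.0, 45.0
        h = 0.05
        a, b, c = L / 2, W / 2, H / 2
        ys = np.arange(-b + h / 2, b, h)
        xs = np.arange(-c + h / 2, c, h)
        plane = np.sort(((ys[:, None] / b) ** 2 + (xs[None, :] / c) ** 2).ravel())
        count = 0
        for z in np.arange(-a + h / 2, a, h):
            count += np.searchsorted(plane, 1.0 - (z / a) ** 2, side="right")
        oracle_ml = count * h**3 / 1000.0
        assert ellipsoid_volume_ml(L, W, H) == pytest.approx(oracle_ml, rel=5e-3)


class TestKidneyMask:
    def test_unit_semi_axis_gives_center_plus_face_neighbors(self):
        spec = PhantomSpec(semi_axes_mm=(1.0, 1.0, 1.0), spacing_mm=1.0)
        mask = generate_kidney_mask(spec, (5, 5, 5))
        # brute-force enumeration of voxel centers against the inequality
        oracle = np.zeros((5, 5, 5), bool)
        for z in range(5):
            for y in range(5):
                for x in range(5):
                    cz, cy, cx = z + 0.5 - 2.5, y + 0.5 - 2.5, x + 0.5 - 2.5
                    oracle[z, y, x] = cz**2 + cy**2 + cx**2 <= 1.0
        assert np.array_equal(mask.data, oracle)
        assert mask.voxel_count() == 7

    @pytest.mark.parametrize("semi_axes", [(2.4, 2.2, 2.0), (3.1, 2.0, 2.8)])
    def test_volume_matches_closed_form(self, semi_axes):
        spec = PhantomSpec(semi_axes_mm=semi_axes, spacing_mm=0.1)
        mask = generate_kidney_mask(spec)
        a, b, c = semi_axes
        analytic_ml = 4.0 / 3.0 * np.pi * a * b * c / 1000.0
        measured = mask.voxel_count() * spec.spacing_mm**3 / 1000.0
        assert measured == pytest.approx(analytic_ml, rel=0.02)

    def test_ellipsoid_exceeding_grid_rejected(self):
        spec = PhantomSpec(semi_axes_mm=(3.0, 3.0, 3.0), spacing_mm=1.0)
        with pytest.raises(ValueError, match="grid"):
            generate_kidney_mask(spec, (6, 6, 6))


class TestDepthDistribution:
    def test_empirical_mean_matches_closed_form(self, rng):
        scale, upper, n = 40.0, 120.0, 100_000
        draws = sample_truncated_exponential(rng, scale, upper, n)
        assert np.all((draws >= 0) & (draws <= upper))
        assert draws.mean() == pytest.approx(
            truncated_exponential_mean(scale, upper), rel=0.02
        )

    def test_regime_cdf_ordering_at_50px(self):
        upper = 120.0
        p_cont = truncated_exponential_cdf(50.0, CONTINUOUS.depth_scale_px, upper)
        p_puls = truncated_exponential_cdf(50.0, PULSED.depth_scale_px, upper)
        assert p_cont > p_puls

    def test_vanishing_scale_puts_all_mass_in_outermost_bin(self, rng):
        spec = PhantomSpec(semi_axes_mm=(2.0, 1.8, 1.6), spacing_mm=0.1)
        mask = generate_kidney_mask(spec)
        regime = RegimeSpec("surface", 1e-6, 100.0, (1.0, 2.0))
        particles = sample_particles(regime, spec, mask, rng, n_particles=200)
        assert np.all(particles.depths_px <= 1.0)

    def test_sampled_depth_fraction_monotone_in_scale(self, rng):
        spec = PhantomSpec(semi_axes_mm=(8.0, 7.0, 6.5), spacing_mm=0.1)
        mask = generate_kidney_mask(spec)
        dist = surface_distance_field(mask)
        shallow = sample_particles(CONTINUOUS, spec, mask, rng,
                                   distance_field=dist, n_particles=4000)
        deep = sample_particles(PULSED, spec, mask, rng,
                                distance_field=dist, n_particles=4000)
        upper = dist.max()
        for d in (20.0, 50.0):
            frac_c = np.mean(shallow.depths_px <= d)
            frac_p = np.mean(deep.depths_px <= d)
            assert frac_c > frac_p
            # both track the closed-form truncated-exponential CDF
            assert frac_c == pytest.approx(
                truncated_exponential_cdf(d, 40.0, upper), abs=0.05
            )


class TestSampleParticles:
    def test_ground_truth_bookkeeping(self, rng):
        spec = PhantomSpec(semi_axes_mm=(3.0, 2.6, 2.2), spacing_mm=0.1)
        mask = generate_kidney_mask(spec)
        dist = surface_distance_field(mask)
        ps = sample_particles(CONTINUOUS, spec, mask, rng,
                              distance_field=dist, n_particles=500)
        assert len(ps) == 500
        idx = np.floor(ps.centers_mm / spec.spacing_mm).astype(int)
        assert np.all(mask.data[idx[:, 0], idx[:, 1], idx[:, 2]])
        assert np.all((ps.radii_um >= 75) & (ps.radii_um <= 100))
        assert np.all(ps.depths_px > 0)
        # recorded depths are the surface distances of the chosen voxels
        assert np.allclose(ps.depths_px, dist[idx[:, 0], idx[:, 1], idx[:, 2]])

    def test_poisson_count_and_empty_mask_error(self, rng):
        spec = PhantomSpec(semi_axes_mm=(2.0, 1.8, 1.6), spacing_mm=0.1)
        mask = generate_kidney_mask(spec)
        regime = RegimeSpec("r", 10.0, 300.0, (1.0, 2.0))
        n = len(sample_particles(regime, spec, mask, rng))
        assert 150 < n < 450  # Poisson(300), > 8 sigma guard band
        from embolimetry import BinaryMask

        empty = BinaryMask(np.zeros((5, 5, 5), bool), 0.1)
        with pytest.raises(ValueError, match="empty"):
            sample_particles(regime, spec, empty, rng)

    def test_min_separation_prevents_adjacent_centers(self, rng):
        spec = PhantomSpec(semi_axes_mm=(3.0, 2.6, 2.2), spacing_mm=0.1)
        mask = generate_kidney_mask(spec)
        ps = sample_particles(CONTINUOUS, spec, mask, rng, n_particles=300,
                              min_center_separation_px=2)
        idx = np.floor(ps.centers_mm / spec.spacing_mm).astype(int)
        cheb = np.abs(idx[:, None, :] - idx[None, :, :]).max(axis=2)
        np.fill_diagonal(cheb, 99)
        assert cheb.min() >= 2


class TestRasterize:
    SPEC = PhantomSpec(semi_axes_mm=(2.0, 2.0, 2.0), spacing_mm=0.1)

    def test_subvoxel_bead_elevates_exactly_one_voxel(self):
        ps = ParticleSet([[1.23, 0.87, 1.51]], [40.0], [5.0])
        vol = rasterize_particles(ps, (30, 30, 30), 0.1, self.SPEC)
        assert np.count_nonzero(vol.data > self.SPEC.background_intensity) == 1

    def test_disjoint_beads_are_additive(self):
        one = ParticleSet([[1.0, 1.0, 1.0]], [90.0], [5.0])
        other = ParticleSet([[2.0, 2.0, 2.0]], [90.0], [5.0])
        both = ParticleSet([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]], [90.0, 90.0], [5.0, 5.0])
        count = lambda p: np.count_nonzero(
            rasterize_particles(p, (30, 30, 30), 0.1, self.SPEC).data > 100
        )
        assert count(both) == count(one) + count(other)

    def test_five_voxel_radius_sphere_volume(self):
        ps = ParticleSet([[1.53, 1.48, 1.52]], [500.0], [5.0])
        vol = rasterize_particles(ps, (31, 31, 31), 0.1, self.SPEC)
        n = np.count_nonzero(vol.data > 100)
        assert n == pytest.approx(4.0 / 3.0 * np.pi * 125, rel=0.05)

    def test_center_outside_grid_rejected(self):
        ps = ParticleSet([[5.0, 1.0, 1.0]], [90.0], [5.0])
        with pytest.raises(ValueError, match="outside"):
            rasterize_particles(ps, (10, 30, 30), 0.1, self.SPEC)


class TestNoise:
    def test_sigma_zero_is_identity(self, rng):
        from embolimetry import Volume3D

        vol = Volume3D(np.full((10, 10, 10), 42.0))
        out = add_ct_noise(vol, 0.0, rng)
        assert np.array_equal(out.data, vol.data)

    def test_same_seed_same_noise(self):
        from embolimetry import Volume3D

        vol = Volume3D(np.full((20, 20, 20), 100.0))
        a = add_ct_noise(vol, 10.0, np.random.default_rng(7))
        b = add_ct_noise(vol, 10.0, np.random.default_rng(7))
        assert np.array_equal(a.data, b.data)

    def test_mean_preserved_within_standard_error(self, rng):
        from embolimetry import Volume3D

        vol = Volume3D(np.full((100, 100, 100), 100.0))
        noisy = add_ct_noise(vol, 10.0, rng)
        se = 10.0 / np.sqrt(1e6)
        assert abs(noisy.data.mean() - 100.0) < 3 * se
        assert noisy.data.min() >= 0.0

    def test_negative_sigma_rejected(self, rng):
        from embolimetry import Volume3D

        with pytest.raises(ValueError):
            add_ct_noise(Volume3D(np.ones((3, 3, 3))), -1.0, rng)


def test_phantom_fully_reproducible_from_seed():
    spec = PhantomSpec(semi_axes_mm=(2.5, 2.2, 2.0), spacing_mm=0.1)
    a = simulate_kidney(spec, CONTINUOUS, np.random.default_rng(11), n_particles=200)
    b = simulate_kidney(spec, CONTINUOUS, np.random.default_rng(11), n_particles=200)
    assert np.array_equal(a.particles.centers_mm, b.particles.centers_mm)
    assert np.array_equal(a.volume.data, b.volume.data)
    assert a.embolic_volume_ml == b.embolic_volume_ml


def test_grid_shape_leaves_background_margin():
    spec = PhantomSpec(semi_axes_mm=(2.0, 1.5, 1.2), spacing_mm=0.1)
    mask = generate_kidney_mask(spec, grid_shape_for(spec))
    for face in (mask.data[0], mask.data[-1], mask.data[:, 0], mask.data[:, -1],
                 mask.data[:, :, 0], mask.data[:, :, -1]):
        assert not face.any()
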
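import numpy as np
import pytest

from myoseg import ContourCollapseError, LocalChanVese, OneSidedWindowError, dice, gaussian_regularize
from myoseg.chanvese import dirac, heaviside, region_means
from myoseg.hough import Circle, levelset_from_circle
from myoseg.local import adaptive_window, curve_band, local_force, local_means, run_smlv, smlv_data_force, smlv_step
from myoseg.phantom import disk_mask

from _oracles import brute_force_local_force, brute_force_window_means


class TestCurveBand:
    def test_band_points_lie_near_the_circle(self):
        phi = levelset_from_circle(Circle(32, 32, 10), (64, 64))
        pts = curve_band(phi, band_width=1.5)
        assert len(pts) > 0
        assert np.all(np.abs(phi[pts[:, 0], pts[:, 1]]) < 1.5)

    def test_huge_band_returns_every_pixel(self):
        phi = levelset_from_circle(Circle(16, 16, 5), (32, 32))
        assert len(curve_band(phi, band_width=1e9)) == 32 * 32

    def test_matches_threshold_scan_on_signed_distance_field(self, rng):
        phi = levelset_from_circle(
            Circle(rng.uniform(20, 40), rng.uniform(20, 40), rng.uniform(5, 15)), (64, 64)
        )
        pts = curve_band(phi, band_width=3.0)
        expected = np.argwhere(np.abs(phi) < 3.0)
        assert np.array_equal(pts, expected)

    def test_one_sided_field_raises(self):
        with pytest.raises(ContourCollapseError):
            curve_band(np.ones((8, 8)), 1.0)

    def test_steepened_field_keeps_interface_collar(self):
        # a near-binary field whose interface pixels all have |phi| > band:
        # the sign-change collar still yields a nonempty band
        phi = np.full((16, 16), -30.0)
        phi[4:12, 4:12] = 30.0
        pts = curve_band(phi, band_width=3.0)
        assert len(pts) > 0


class TestAdaptiveWindow:
    CFG = dict(win_init=3, win_max=10, win_entropy_threshold=0.5, n_bins=32)

    def test_constant_image_grows_to_cap(self):
        assert adaptive_window(np.full((40, 40), 9.0), (20, 20), **self.CFG) == 10

    def test_informative_initial_window_not_grown(self, rng):
        img = rng.uniform(0, 255, (40, 40))
        assert adaptive_window(img, (20, 20), **self.CFG) == 3

    def test_matches_exhaustive_size_scan_on_ramp(self):
        img = np.tile(np.arange(60, dtype=float) * 2.0, (60, 1))
        center = (30, 30)
        got = adaptive_window(img, center, **self.CFG)
        expected = None
        for half in range(3, 11):
            sl = (slice(30 - half, 30 + half + 1), slice(30 - half, 30 + half + 1))
            counts, _ = np.histogram(np.clip(img[sl], 0, 255), bins=32, range=(0, 255))
            p = counts[counts > 0] / counts.sum()
            if -(p * np.log(p)).sum() >= 0.5 or half == 10:
                expected = half
                break
        assert got == expected


class TestLocalMeans:
    def test_vertical_step_window(self):
        image = np.full((20, 20), 40.0)
        image[:, 10:] = 160.0
        phi = np.where(np.arange(20) < 10, 1000.0, -1000.0)[np.newaxis, :] * np.ones((20, 1))
        u, v = local_means(image, phi, ((10, 10), 5), heaviside_eps=1.5)
        assert u == pytest.approx(40.0, abs=0.5)
        assert v == pytest.approx(160.0, abs=0.5)

    def test_whole_image_window_equals_global_region_means(self, rng):
        image = rng.uniform(0, 255, (16, 16))
        phi = rng.uniform(-5, 5, (16, 16))
        u, v = local_means(image, phi, (slice(0, 16), slice(0, 16)), heaviside_eps=1.5)
        c_i, c_o = region_means(image, phi, eps=1.5)
        assert u == pytest.approx(c_i, abs=1e-12)
        assert v == pytest.approx(c_o, abs=1e-12)

    def test_matches_brute_force_over_hundred_random_windows(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            image = rng.uniform(0, 255, (9, 9))
            phi = rng.uniform(-4, 4, (9, 9))
            u, v = local_means(image, phi, (slice(0, 9), slice(0, 9)), heaviside_eps=1.5)
            eu, ev = brute_force_window_means(image, phi, range(9), range(9), 1.5)
            assert u == pytest.approx(eu, abs=1e-10)
            assert v == pytest.approx(ev, abs=1e-10)

    def test_one_sided_window_raises_signal(self):
        image = np.zeros((10, 10))
        phi = np.ones((10, 10))
        with pytest.raises(OneSidedWindowError):
            local_means(image, phi, ((5, 5), 2), heaviside_eps=1.5)


class TestLocalForce:
    def test_constant_window_has_zero_force(self):
        image = np.full((20, 20), 77.0)
        phi = levelset_from_circle(Circle(10, 10, 5), (20, 20))
        f = local_force(image, phi, (10, 5), win_init=3, win_max=3)
        assert f == 0.0

    def test_matches_straight_line_oracle_on_fixture(self):
        rng = np.random.default_rng(11)
        image = rng.uniform(0, 255, (7, 7))
        phi = rng.uniform(-4, 4, (7, 7))
        got = local_force(
            image, phi, (3, 3), heaviside_eps=1.5, win_init=3, win_max=3,
            adaptive=False, entropy_weighting=True,
        )
        # win_max=3 centered at (3,3) covers the whole 7x7 fixture
        expected = brute_force_local_force(
            image, phi, range(7), range(7), 1.5, 32, 0.0, 255.0, 0.05
        )
        assert got == pytest.approx(expected, abs=1e-10)


class TestGaussianRegularize:
    def test_constant_field_unchanged(self):
        phi = np.full((33, 33), 3.0)
        np.testing.assert_allclose(gaussian_regularize(phi, 2.0), phi, atol=1e-12)

    def test_impulse_center_equals_kernel_central_weight(self):
        phi = np.zeros((33, 33))
        phi[16, 16] = 1.0
        out = gaussian_regularize(phi, 2.0)
        # normalized 1-D kernel weight at offset 0, truncated at 4*xi
        x = np.arange(-8, 9)
        w = np.exp(-0.5 * (x / 2.0) ** 2)
        w /= w.sum()
        assert out[16, 16] == pytest.approx(w[8] ** 2, abs=1e-12)

    def test_linear_ramp_interior_unchanged(self):
        phi = np.tile(np.arange(40, dtype=float), (40, 1))
        out = gaussian_regularize(phi, 1.0)
        np.testing.assert_allclose(out[4:-4, 4:-4], phi[4:-4, 4:-4], atol=1e-9)

    def test_dirichlet_energy_strictly_decreases(self, rng):
        phi = rng.normal(0, 5, (32, 32))

        def dirichlet(f):
            return float((np.diff(f, axis=0) ** 2).sum() + (np.diff(f, axis=1) ** 2).sum())

        assert dirichlet(gaussian_regularize(phi, 1.0)) < dirichlet(phi)

    def test_nonpositive_xi_rejected(self):
        with pytest.raises(ValueError):
            gaussian_regularize(np.zeros((8, 8)), 0.0)


class TestSmlvStep:
    def test_constant_image_step_is_area_shrink_plus_smoothing(self):
        phi = levelset_from_circle(Circle(16, 16, 8), (32, 32))
        image = np.full((32, 32), 100.0)
        # every window is one-sided in intensity terms but straddles phi, so
        # u = v and the data force vanishes; only -nu and smoothing act
        new = smlv_step(image, phi, nu=0.5, xi=0.3, dt=0.05)
        assert heaviside(new, 1.5).sum() < heaviside(phi, 1.5).sum()

    def test_matched_two_constant_image_changes_only_by_smoothing(self):
        phi = np.where(disk_mask((32, 32), (16, 16), 8).astype(bool), 50.0, -50.0)
        image = np.where(phi > 0, 200.0, 50.0)
        new = smlv_step(image, phi, nu=0.0, xi=1.0, dt=0.05)
        np.testing.assert_allclose(new, gaussian_regularize(phi, 1.0), atol=1e-3)

    def test_limit_case_equals_global_cv_data_force(self):
        rng = np.random.default_rng(5)
        image = rng.uniform(0, 255, (16, 16))
        phi = rng.uniform(-6, 6, (16, 16))
        a = smlv_data_force(
            image, phi, heaviside_eps=1.5, band_width=1e9, win_init=16, win_max=16,
            adaptive=False, entropy_weighting=False,
        )
        n_band = phi.size
        c_i, c_o = region_means(image, phi, eps=1.5)
        cv_force = dirac(phi, 1.5) * (-(image - c_i) ** 2 + (image - c_o) ** 2)
        assert np.abs(a + n_band * cv_force).max() <= 1e-8 * np.abs(a).max()

    def test_zero_iterations_returns_initialization(self):
        image = np.full((32, 32), 10.0)
        phi0 = levelset_from_circle(Circle(16, 16, 8), (32, 32))
        phi, diag = run_smlv(image, phi0, max_iters=0)
        assert np.array_equal(phi, phi0)
        assert len(diag) == 0


class TestLocalChanVeseEstimator:
    def test_recovers_ring_phantom_epicardium(self, small_phantom):
        image, endo, epi, myo = small_phantom
        phi0 = levelset_from_circle(Circle(40, 40, 21), (80, 80))
        model = LocalChanVese(max_iters=80).fit(image, phi_init=phi0)
        assert dice(epi, model.mask_) >= 0.99

    def test_phi_stays_finite_and_bounded(self, small_phantom):
        image, _, _, _ = small_phantom
        phi0 = levelset_from_circle(Circle(40, 40, 12), (80, 80))
        model = LocalChanVese(max_iters=40).fit(image, phi_init=phi0)
        bound = np.abs(phi0).max() + model.n_iter_ * model.step_cap
        assert np.isfinite(model.phi_).all()
        assert np.abs(model.phi_).max() <= bound + 1e-9

    def test_xi_must_exceed_sqrt_dt(self):
        with pytest.raises(ValueError, match="sqrt"):
            LocalChanVese(dt=0.5, xi=0.5).fit(np.zeros((16, 16)))

    def test_ncv_mode_uses_fixed_window(self):
        from myoseg import ncv_model

        model = ncv_model((64, 64))
        assert model.win_init == model.win_max == 8
        assert not model.adaptive and not model.entropy_weighting
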
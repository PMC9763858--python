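"""Segmentation, object analysis and Ripley K/L/H spatial statistics."""

import numpy as np
import pytest

from patchstoich import (ImageStack, PatternSpec, PointPattern, RectRegion,
                         analyze_objects, binarize_puncta,
                         bleach_correct_zstack, clustering_gradient,
                         density_map, nearest_neighbor_distance, ripley_h,
                         simulate_point_pattern)
from patchstoich.cluster import MaskRegion, RipleyCurve
from patchstoich.errors import ParameterError, SegmentationError

from conftest import gaussian_spot_frame


def brute_force_K(points, area_um2, r_grid_nm):
    """Independent double-loop Ripley K (no edge correction)."""
    n = len(points)
    K = np.zeros(len(r_grid_nm))
    for k, r in enumerate(r_grid_nm):
        count = 0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = np.hypot(points[i, 0] - points[j, 0],
                             points[i, 1] - points[j, 1])
                if d <= r:
                    count += 1
        K[k] = (area_um2 * 1e6) / (n * n) * count
    return K / 1e6    # um^2


class TestBleachCorrection:
    def test_exponential_decay_is_undone(self):
        tau = 30.0
        k = np.arange(12)
        base = np.full((16, 16), 100.0)
        frames = np.stack([base * np.exp(-kk / tau) for kk in k])
        ref = frames.mean(axis=(1, 2))
        stack = ImageStack(frames, pixel_size_nm=40.0)
        corrected, tau_fit = bleach_correct_zstack(stack, ref)
        means = corrected.frames.mean(axis=(1, 2))
        assert np.all(np.abs(means - 100.0) < 1.0)
        assert tau_fit == pytest.approx(tau, rel=1e-6)

    def test_tau_recovered_from_noisy_reference(self, rng):
        tau = 25.0
        k = np.arange(20)
        ref = 100.0 * np.exp(-k / tau) * rng.normal(1.0, 0.01, 20)
        stack = ImageStack(np.ones((20, 8, 8)), pixel_size_nm=40.0)
        _, tau_fit = bleach_correct_zstack(stack, ref)
        assert tau_fit == pytest.approx(tau, rel=0.05)

    def test_zero_decay_reference_is_identity(self):
        stack = ImageStack(np.random.default_rng(0).uniform(size=(5, 8, 8)),
                           pixel_size_nm=40.0)
        corrected, tau = bleach_correct_zstack(stack, np.full(6, 50.0))
        np.testing.assert_array_equal(corrected.frames, stack.frames)
        assert np.isinf(tau)

    def test_increasing_reference_rejected(self):
        stack = ImageStack(np.ones((3, 8, 8)), pixel_size_nm=40.0)
        with pytest.raises(ParameterError):
            bleach_correct_zstack(stack, np.array([50.0, 60.0, 75.0]))


class TestBinarization:
    def test_two_valued_image_recovers_bright_patches_exactly(self, rng):
        image = np.full((128, 128), 50.0)
        truth = np.zeros((128, 128), dtype=bool)
        for cx, cy in [(20, 30), (64, 64), (100, 40), (40, 100)]:
            truth[cy - 2:cy + 3, cx - 2:cx + 3] = True
        image[truth] = 200.0
        mask = binarize_puncta(image, local_radius=25, min_size=4)
        np.testing.assert_array_equal(mask, truth)

    def test_constant_image_is_a_segmentation_error(self):
        with pytest.raises(SegmentationError):
            binarize_puncta(np.full((64, 64), 10.0))

    def test_global_threshold_matches_exhaustive_oracle(self, rng):
        # brute-force maximization of between-class variance over 8-bit levels
        from skimage.filters import threshold_otsu

        img = np.clip(rng.normal(40, 10, (96, 96)), 0, 255)
        img[30:36, 30:36] = 220
        img[60:66, 70:76] = 200
        img8 = np.round((img - img.min()) / (img.max() - img.min()) * 255
                        ).astype(np.uint8)
        best_t, best_var = 0, -1.0
        for t in range(256):
            lo, hi = img8[img8 <= t], img8[img8 > t]
            if lo.size == 0 or hi.size == 0:
                continue
            w0, w1 = lo.size, hi.size
            var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
            if var > best_var:
                best_var, best_t = var, t
        assert threshold_otsu(img8) == best_t

    def test_synthetic_puncta_yield_one_object_each(self, rng):
        # SIM-like field: bright diffraction-limited puncta on noisy background
        image = rng.normal(20.0, 2.0, (256, 256))
        spots, sigma = [], 1.5
        while len(spots) < 25:
            p = rng.uniform(15, 240, 2)
            if all(np.hypot(*(p - q)) > 12 for q in spots):
                spots.append(p)
        for x0, y0 in spots:
            image += gaussian_spot_frame((256, 256), x0, y0, 2000.0, sigma)
        mask = binarize_puncta(image, local_radius=25, min_size=4)
        objs = analyze_objects(mask, image)
        matched = 0
        centers = np.array([[o.x_px, o.y_px] for o in objs])
        for x0, y0 in spots:
            d = np.hypot(centers[:, 0] - x0, centers[:, 1] - y0)
            matched += np.sum(d < 4) == 1
        assert matched >= 0.9 * len(spots)


class TestObjects:
    def test_square_area_and_centroid(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[10:15, 20:25] = True
        (obj,) = analyze_objects(mask, pixel_size_nm=100.0)
        assert obj.area_px == 25
        assert obj.area_um2 == pytest.approx(25 * 0.01 * 0.01 * 100)  # 0.25 um2
        assert (obj.x_px, obj.y_px) == (22.0, 12.0)

    def test_large_disk_circularity_near_one(self):
        yy, xx = np.mgrid[0:101, 0:101]
        mask = (xx - 50) ** 2 + (yy - 50) ** 2 <= 40 ** 2
        (obj,) = analyze_objects(mask)
        assert 0.9 <= obj.circularity <= 1.1

    def test_diagonal_touch_is_one_object_under_8_connectivity(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[2:5, 2:5] = True
        mask[5:8, 5:8] = True
        assert len(analyze_objects(mask)) == 1

    def test_intensity_weighted_centroid(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[5, 5:7] = True
        intensity = np.zeros((16, 16))
        intensity[5, 5], intensity[5, 6] = 10.0, 30.0
        (obj,) = analyze_objects(mask, intensity)
        assert obj.x_px == pytest.approx(5.75)

    def test_empty_mask_gives_empty_list(self):
        assert analyze_objects(np.zeros((8, 8), dtype=bool)) == []


class TestDensityMap:
    def test_single_point_integral_and_peak(self):
        region = RectRegion(4000.0, 4000.0)
        xc, yc, dens = density_map(np.array([[2000.0, 2000.0]]), region,
                                   kernel_width_nm=180.0, grid_step_nm=40.0)
        step_um2 = (40.0 / 1000.0) ** 2
        assert dens.sum() * step_um2 == pytest.approx(1.0, abs=0.01)
        iy, ix = np.unravel_index(np.argmax(dens), dens.shape)
        assert xc[ix] == pytest.approx(2000.0, abs=40.0)
        assert yc[iy] == pytest.approx(2000.0, abs=40.0)

    def test_csr_field_mean_matches_intensity(self, rng):
        spec = PatternSpec("csr", (20_000.0, 20_000.0), intensity_per_um2=2.5)
        pts, _ = simulate_point_pattern(spec, rng)
        region = RectRegion(20_000.0, 20_000.0)
        xc, yc, dens = density_map(pts, region, grid_step_nm=100.0)
        inside = ((xc[None, :] > 1000) & (xc[None, :] < 19_000)
                  & (yc[:, None] > 1000) & (yc[:, None] < 19_000))
        assert dens[inside].mean() == pytest.approx(2.5, rel=0.15)


class TestRipley:
    def test_two_point_closed_form(self):
        # below the pair distance K = 0 so H(r) = -r
        region = RectRegion(10_000.0, 10_000.0)
        pts = np.array([[3000.0, 5000.0], [7000.0, 5000.0]])
        r = np.arange(0.0, 3000.0, 100.0)
        curve = ripley_h(PointPattern(pts, region), r,
                         edge_correction="none", min_points=2)
        np.testing.assert_allclose(curve.H_um, -r / 1000.0, atol=1e-12)

    def test_exact_match_with_brute_force_oracle(self, rng):
        region = RectRegion(10_000.0, 10_000.0)
        pts = rng.uniform(0, 10_000.0, size=(20, 2))
        r = np.arange(0.0, 2500.0, 20.0)
        curve = ripley_h(PointPattern(pts, region), r, edge_correction="none")
        oracle = brute_force_K(pts, region.area_um2, r)
        np.testing.assert_allclose(curve.K_um2, oracle, rtol=0, atol=1e-12)
        np.testing.assert_allclose(curve.L_um, np.sqrt(curve.K_um2 / np.pi))
        np.testing.assert_allclose(curve.H_um, curve.L_um - curve.r_um)

    def test_K_nondecreasing(self, rng):
        region = RectRegion(8000.0, 8000.0)
        pts = rng.uniform(0, 8000.0, size=(40, 2))
        curve = ripley_h(PointPattern(pts, region))
        assert np.all(np.diff(curve.K_um2) >= -1e-12)

    def test_isotropic_correction_weights_exceed_one_near_edges(self, rng):
        region = RectRegion(5000.0, 5000.0)
        pts = rng.uniform(0, 5000.0, size=(30, 2))
        r = np.arange(0.0, 1200.0, 50.0)
        none = ripley_h(PointPattern(pts, region), r, edge_correction="none")
        iso = ripley_h(PointPattern(pts, region), r, edge_correction="isotropic")
        assert np.all(iso.K_um2 >= none.K_um2 - 1e-12)

    def test_mask_region_equivalent_to_rect_for_full_mask(self, rng):
        pts = rng.uniform(100, 4900, size=(25, 2))
        r = np.arange(0.0, 1000.0, 50.0)
        rect = ripley_h(PointPattern(pts, RectRegion(5000.0, 5000.0)), r,
                        edge_correction="none")
        mask = MaskRegion(np.ones((50, 50), dtype=bool), pixel_size_nm=100.0)
        masked = ripley_h(PointPattern(pts, mask), r, edge_correction="none")
        np.testing.assert_allclose(rect.K_um2, masked.K_um2)

    def test_too_few_points_rejected(self):
        region = RectRegion(1000.0, 1000.0)
        with pytest.raises(ParameterError):
            ripley_h(PointPattern(np.array([[1.0, 1.0]]), region))

    def test_points_outside_region_rejected(self):
        with pytest.raises(ParameterError):
            PointPattern(np.array([[2000.0, 500.0]]), RectRegion(1000.0, 1000.0))


class TestCurveSummaries:
    @staticmethod
    def make_curve(r_um, H_um):
        L = H_um + r_um
        return RipleyCurve(r_um=r_um, K_um2=np.pi * L * L, L_um=L, H_um=H_um,
                           n_points=100, area_um2=100.0)

    def test_constant_gradient_curve(self):
        r = np.arange(0.0, 5.0, 0.02)
        curve = self.make_curve(r, 0.004 * r)
        assert clustering_gradient(curve) == pytest.approx(0.004, abs=1e-4)

    def test_flat_curve_zero_gradient(self):
        r = np.arange(0.0, 5.0, 0.02)
        curve = self.make_curve(r, np.zeros_like(r))
        assert clustering_gradient(curve) == pytest.approx(0.0, abs=1e-4)

    def test_two_point_nn_distance_is_last_negative_radius(self):
        r = np.arange(0.0, 3.0, 0.02)
        d_um = 1.5
        H = np.where(r < d_um, -r, 0.1)
        curve = self.make_curve(r, H)
        nn = nearest_neighbor_distance(curve)
        assert nn == pytest.approx((d_um - 0.02) * 1000.0, abs=1e-6)

    def test_positive_everywhere_curve_has_no_nn_distance(self):
        r = np.arange(0.0, 3.0, 0.02)
        curve = self.make_curve(r, 0.01 * np.ones_like(r))
        assert nearest_neighbor_distance(curve) is None

    def test_scale_covariance(self, rng):
        spec = PatternSpec("lattice_jitter", (10_000.0, 10_000.0),
                           spacing_nm=800.0, jitter_rms_nm=200.0)
        pts, _ = simulate_point_pattern(spec, rng)
        pattern = PointPattern(pts, RectRegion(10_000.0, 10_000.0))
        r = np.arange(0.0, 2000.0, 20.0)
        c1 = ripley_h(pattern, r, edge_correction="none")
        c2 = ripley_h(pattern.rescaled(2.0), 2.0 * r, edge_correction="none")
        nn1 = nearest_neighbor_distance(c1)
        nn2 = nearest_neighbor_distance(c2)
        assert nn2 == pytest.approx(2.0 * nn1, rel=1e-9)
        # dimensionless gradient is scale-free
        g1 = clustering_gradient(c1)
        g2 = clustering_gradient(c2)
        assert g2 == pytest.approx(g1, abs=5e-3)
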
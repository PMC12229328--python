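"""Metric suite: pixel errors, PSNR conventions, SSIM, ENL and Pratt FOM."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity

import mkdespeckle as mk
from mkdespeckle.metrics import DegenerateRegionError, edge_map, gaussian_window


def brute_force_mse(g, p):
    total, count = 0.0, 0
    for idx in np.ndindex(g.shape):
        total += (g[idx] - p[idx]) ** 2
        count += 1
    return total / count


class TestPixelErrors:
    def test_identity_gives_zero(self, rng):
        x = rng.random((8, 8))
        assert mk.mse(x, x) == 0.0
        assert mk.rmse(x, x) == 0.0
        assert mk.mae(x, x) == 0.0

    def test_constant_offset(self):
        assert mk.mse(np.zeros((4, 4)), np.ones((4, 4))) == 1.0

    def test_mse_matches_double_loop(self, rng):
        g, p = rng.random((8, 8)), rng.random((8, 8))
        assert abs(mk.mse(g, p) - brute_force_mse(g, p)) < 1e-12
        assert abs(mk.rmse(g, p) - np.sqrt(brute_force_mse(g, p))) < 1e-12

    def test_mae_example_and_oracle(self, rng):
        g = np.array([[0.0, 1.0], [1.0, 0.0]])
        p = np.array([[1.0, 1.0], [0.0, 0.0]])
        assert mk.mae(g, p) == 0.5
        a, b = rng.random((8, 8)), rng.random((8, 8))
        assert abs(mk.mae(a, b) - np.mean([abs(a[i] - b[i])
                                           for i in np.ndindex(a.shape)])) < 1e-12

    def test_rmse_squared_equals_mse(self, rng):
        g, p = rng.random((16, 16)), rng.random((16, 16))
        assert mk.rmse(g, p) ** 2 == pytest.approx(mk.mse(g, p), rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mk.mse(np.zeros((4, 4)), np.zeros((4, 5)))


class TestPSNR:
    def test_twenty_db_case(self):
        g = np.zeros((10, 10))
        p = np.full((10, 10), 0.1)            # MSE = 0.01, peak 1
        assert mk.psnr(g, p, peak=1.0) == pytest.approx(20.0, abs=1e-12)

    def test_mse_zero_sentinel(self, rng):
        x = rng.random((8, 8))
        assert mk.psnr(x, x) == 0.0
        assert mk.psnr(x, x, mse_zero_sentinel=99.0) == 99.0

    def test_rmse_0p004_maps_to_about_48_db(self):
        g = np.zeros((10, 10))
        p = np.full((10, 10), 0.004)          # RMSE = 0.004
        assert mk.psnr(g, p, peak=1.0) == pytest.approx(20 * np.log10(1 / 0.004),
                                                        rel=1e-12)
        assert 47.9 < mk.psnr(g, p) < 48.0

    def test_literal_convention_differs(self):
        g, p = np.zeros((4, 4)), np.full((4, 4), 0.1)
        standard = mk.psnr(g, p, peak=1.0)
        literal = mk.psnr(g, p, peak=255.0, convention="peak_over_mse")
        assert standard == pytest.approx(20.0)
        assert literal == pytest.approx(10 * np.log10(255 / 0.01))

    def test_strictly_decreasing_in_mse(self):
        values = [mk.psnr(np.zeros(100), np.full(100, np.sqrt(m)))
                  for m in np.linspace(1e-4, 1.0, 100)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(ValueError):
            mk.psnr(np.zeros(4), np.ones(4), peak=0.0)


class TestSSIM:
    def test_identical_images_score_one(self, rng):
        x = rng.random((32, 32))
        assert mk.ssim(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_equal_constants_score_one(self):
        a, b = np.full((16, 16), 0.7), np.full((16, 16), 0.7)
        assert mk.ssim(a, b) == pytest.approx(1.0, abs=1e-9)
        # different constants differ in luminance, so the score drops
        assert mk.ssim(a, np.full((16, 16), 0.2)) < 1.0

    def test_symmetry(self, rng):
        g, p = rng.random((32, 32)), rng.random((32, 32))
        assert mk.ssim(g, p) == pytest.approx(mk.ssim(p, g), abs=1e-9)

    def test_matches_reference_implementation(self, rng):
        g = rng.random((64, 64))
        p = np.clip(g + 0.1 * rng.standard_normal(g.shape), 0, 1)
        expected = structural_similarity(
            g, p, win_size=11, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=1.0)
        assert mk.ssim(g, p) == pytest.approx(expected, abs=1e-9)

    def test_single_window_brute_force(self, rng):
        """One 11x11 window against direct evaluation of the SSIM formula."""
        g, p = rng.random((11, 11)), rng.random((11, 11))
        w = gaussian_window(11, 1.5)
        mu_x, mu_y = (w * g).sum(), (w * p).sum()
        sxx = (w * g * g).sum() - mu_x ** 2
        syy = (w * p * p).sum() - mu_y ** 2
        sxy = (w * g * p).sum() - mu_x * mu_y
        c1, c2 = 0.01 ** 2, 0.03 ** 2
        expected = ((2 * mu_x * mu_y + c1) * (2 * sxy + c2) /
                    ((mu_x ** 2 + mu_y ** 2 + c1) * (sxx + syy + c2)))
        assert mk.ssim(g, p) == pytest.approx(expected, abs=1e-9)

    def test_multichannel_replication_matches_single_channel(self, rng):
        g, p = rng.random((32, 32)), rng.random((32, 32))
        g3 = np.repeat(g[:, :, None], 3, axis=2)
        p3 = np.repeat(p[:, :, None], 3, axis=2)
        assert mk.ssim(g3, p3) == pytest.approx(mk.ssim(g, p), abs=1e-12)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            mk.ssim(np.zeros((8, 8)), np.zeros((8, 8)))


class TestENL:
    def test_mean_squared_over_variance(self):
        region = np.array([1.0, 3.0, 1.0, 3.0] * 8)   # mean 2, pop var 1
        img = region.reshape(4, 8)
        assert mk.enl(img, (0, 0, 4, 8)) == pytest.approx(4.0, abs=1e-12)

    def test_speckled_constant_region_gives_inverse_variance(self):
        c = np.full((256, 256), 0.5)
        noisy = mk.add_speckle(c, mk.SpeckleParams(sigma=0.01, seed=8))
        assert mk.enl(noisy, (0, 0, 256, 256)) == pytest.approx(100.0, rel=0.05)

    def test_scale_invariance(self, rng):
        img = rng.random((20, 20)) + 0.5
        roi = (2, 2, 18, 18)
        assert mk.enl(img * 7.3, roi) == pytest.approx(mk.enl(img, roi), rel=1e-9)

    def test_zero_variance_region_raises(self):
        with pytest.raises(DegenerateRegionError):
            mk.enl(np.full((8, 8), 0.5), (0, 0, 8, 8))

    def test_roi_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            mk.enl(np.zeros((8, 8)), (0, 0, 9, 8))


class TestFOM:
    def test_identical_edge_maps_score_one(self):
        edges = np.zeros((16, 16), dtype=bool)
        edges[8, 2:14] = True
        assert mk.pratt_fom(edges, edges) == 1.0

    def test_single_pixel_displaced_three(self):
        ref = np.zeros((9, 9), dtype=bool)
        det = np.zeros((9, 9), dtype=bool)
        ref[4, 1] = True
        det[4, 4] = True                      # distance 3
        assert mk.pratt_fom(det, ref, alpha_scale=1 / 9) == pytest.approx(0.5)

    def test_spurious_pixel_lowers_score(self):
        ref = np.zeros((16, 16), dtype=bool)
        ref[8, 2:14] = True
        det = ref.copy()
        det[8, 1] = True                      # extra pixel at distance 1
        assert mk.pratt_fom(det, ref) < 1.0

    def test_monotone_in_displacement(self):
        ref = np.zeros((32, 32), dtype=bool)
        ref[16, 2] = True
        scores = []
        for d in range(0, 12, 2):
            det = np.zeros((32, 32), dtype=bool)
            det[16, 2 + d] = True
            scores.append(mk.pratt_fom(det, ref))
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(10):
            det = rng.random((16, 16)) > 0.8
            ref = rng.random((16, 16)) > 0.8
            if ref.sum() == 0:
                continue
            assert 0.0 <= mk.pratt_fom(det, ref) <= 1.0

    def test_full_pipeline_identity(self, phantom):
        assert mk.fom(phantom, phantom) == pytest.approx(1.0)

    def test_no_reference_edges_rejected(self):
        flat = np.full((32, 32), 0.5)
        with pytest.raises(ValueError):
            mk.fom(flat, flat)

    def test_no_detected_edges_scores_zero(self, phantom):
        assert mk.fom(np.full_like(phantom, 0.5), phantom) == 0.0


class TestEvaluateSuite:
    def test_identity_pair_row(self, phantom):
        roi = mk.phantom_background_roi(*phantom.shape)
        report = mk.evaluate_suite([(phantom, phantom.copy())], rois=[roi])
        rec = report.records[0]
        assert rec["psnr"] == 0.0                       # MSE=0 sentinel
        assert rec["ssim"] == pytest.approx(1.0)
        assert rec["rmse"] == 0.0
        assert rec["fom"] == pytest.approx(1.0)
        assert np.isfinite(rec["enl"])                  # textured background ROI

    def test_aggregate_is_arithmetic_mean(self, phantom, rng):
        noisy1 = mk.add_speckle(phantom, mk.SpeckleParams(sigma=0.01, seed=1))
        noisy2 = mk.add_speckle(phantom, mk.SpeckleParams(sigma=0.09, seed=2))
        report = mk.evaluate_suite([(phantom, noisy1), (phantom, noisy2)])
        vals = [r["psnr"] for r in report.records]
        assert report.aggregates["overall"]["psnr"] == pytest.approx(np.mean(vals))

    def test_order_invariance(self, phantom):
        pairs = [(phantom, mk.add_speckle(phantom, mk.SpeckleParams(sigma=v, seed=i)))
                 for i, v in enumerate([0.01, 0.09, 0.25])]
        fwd = mk.evaluate_suite(pairs)
        rev = mk.evaluate_suite(pairs[::-1])
        for key in ("psnr", "ssim", "rmse", "fom"):
            assert fwd.aggregates["overall"][key] == pytest.approx(
                rev.aggregates["overall"][key], rel=1e-12)

    def test_degenerate_enl_flagged_not_fatal(self):
        img = np.full((32, 32), 0.5)
        img[0, 0] = 1.0                                 # give canny an edge-free field
        ref = mk.generate_phantom(seed=1, height=32, width=32, n_lesions=0)
        report = mk.evaluate_suite([(ref, np.full((32, 32), 0.5))],
                                   rois=[(4, 4, 12, 12)])
        assert report.records[0].get("enl_degenerate") is True

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mk.evaluate_suite([])
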
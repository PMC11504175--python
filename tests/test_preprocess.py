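"""Enhancement chain: oracles for each stage and pipeline contracts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from octfluid.errors import ConfigError
from octfluid.preprocess import (BScan, PreprocessParams, clahe,
                                 edge_map, edge_responses, extract_roi,
                                 gamma_correct, local_entropy,
                                 match_histogram, median_denoise,
                                 preprocess_pipeline)

RNG = np.random.default_rng(42)


class TestHistogramMatching:
    def test_self_matching_is_identity_within_quantization(self):
        x = BScan(RNG.random((32, 32)))
        out = match_histogram(x, x)
        assert np.abs(out.pixels - x.pixels).max() <= 1 / 255

    def test_matching_reduces_ks_distance_to_reference(self):
        img = BScan(RNG.beta(2, 5, (64, 64)))
        ref = BScan(RNG.beta(5, 2, (64, 64)))
        out = match_histogram(img, ref)

        def ks(a, b):
            grid = np.linspace(0, 1, 512)
            ca = np.searchsorted(np.sort(a.ravel()), grid) / a.size
            cb = np.searchsorted(np.sort(b.ravel()), grid) / b.size
            return np.abs(ca - cb).max()

        assert ks(out.pixels, ref.pixels) <= ks(img.pixels, ref.pixels)

    def test_constant_reference_rejected(self):
        with pytest.raises(ConfigError):
            match_histogram(BScan(RNG.random((8, 8))),
                            BScan(np.full((8, 8), 0.5)))


class TestMedian:
    def test_constant_unchanged(self):
        img = np.full((16, 16), 0.3)
        assert np.array_equal(median_denoise(BScan(img)).pixels, img)

    def test_impulse_removed(self):
        img = np.full((16, 16), 0.3)
        img[8, 8] = 1.0
        assert np.allclose(median_denoise(BScan(img), 3).pixels, 0.3)

    def test_agrees_with_sort_oracle_exactly(self):
        img = np.round(RNG.random((16, 16)) * 255) / 255
        out = median_denoise(BScan(img), 3).pixels
        padded = np.pad(img, 1, mode="edge")
        for r in range(16):
            for c in range(16):
                window = np.sort(padded[r:r + 3, c:c + 3].ravel())
                assert out[r, c] == window[4]

    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigError):
            median_denoise(BScan(np.zeros((8, 8))), 4)


class TestClahe:
    def test_constant_stays_constant(self):
        out = clahe(BScan(np.full((64, 64), 0.4)))
        assert np.ptp(out.pixels) == 0

    def test_output_bounded_for_random_images(self):
        for _ in range(50):
            out = clahe(BScan(RNG.random((40, 52))))
            assert out.pixels.min() >= 0 and out.pixels.max() <= 1

    def test_low_contrast_gradient_gains_contrast(self):
        g = np.tile(np.linspace(0.4, 0.6, 128), (128, 1))
        out = clahe(BScan(g))
        assert out.pixels.std() > g.std()


class TestGamma:
    @given(st.floats(min_value=0.2, max_value=5.0))
    def test_fixed_points_zero_and_one(self, gamma):
        img = BScan(np.array([[0.0, 1.0]]))
        out = gamma_correct(img, gamma)
        assert out.pixels[0, 0] == 0.0 and out.pixels[0, 1] == 1.0

    def test_unit_gamma_is_identity(self):
        img = BScan(RNG.random((8, 8)))
        assert np.allclose(gamma_correct(img, 1.0).pixels, img.pixels)

    def test_half_at_default_gamma(self):
        out = gamma_correct(BScan(np.array([[0.5]])), 1.7)
        assert abs(out.pixels[0, 0] - 0.5 ** 1.7) < 1e-12

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ConfigError):
            gamma_correct(BScan(np.zeros((4, 4))), 0.0)


class TestRoi:
    def test_constant_image_falls_back_to_full_extent(self):
        img = BScan(np.full((64, 64), 0.5))
        cropped, box = extract_roi(img)
        assert (box.row_start, box.row_end) == (0, 64)
        assert cropped.pixels.shape == (64, 64)

    def test_textured_band_recovered_within_margin(self):
        params = PreprocessParams()
        img = np.full((128, 64), 0.5)
        img[40:80] = RNG.random((40, 64))
        _, box = extract_roi(BScan(img), params)
        slack = params.roi_margin + params.entropy_window // 2 + 1
        assert box.row_start <= 40 and box.row_end >= 80
        assert 40 - box.row_start <= slack
        assert box.row_end - 80 <= slack

    def test_crop_of_crop_is_idempotent(self):
        img = np.full((128, 64), 0.5)
        img[40:80] = RNG.random((40, 64))
        cropped, _ = extract_roi(BScan(img))
        recropped, box2 = extract_roi(cropped)
        assert (box2.row_start, box2.row_end) == (0, cropped.height)

    def test_entropy_oracle_on_two_level_patch(self):
        """Histogram entropy of a checkerboard window is exactly 1 bit."""
        img = np.indices((32, 32)).sum(axis=0) % 2 * 0.6 + 0.2
        ent = local_entropy(BScan(img), window=9)
        interior = ent[8:-8, 8:-8]
        # 9x9 window on a checkerboard: 41/81 vs 40/81 pixels per level
        p = np.array([41 / 81, 40 / 81])
        expected = -(p * np.log2(p)).sum()
        assert np.allclose(interior, expected, atol=1e-12)


class TestEdgeMap:
    def test_constant_image_zero_response(self):
        em = edge_map(BScan(np.full((32, 32), 0.7)))
        assert np.all(em.response == 0)

    def test_step_edge_peaks_at_step(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 1.0
        em = edge_map(BScan(img))
        peaks = em.response.argmax(axis=1)
        assert np.all(np.abs(peaks - 16) <= 1)

    def test_offset_invariance_before_rescale(self):
        img = RNG.random((24, 24)) * 0.5
        rx1, ry1 = edge_responses(BScan(img), 1.8)
        rx2, ry2 = edge_responses(BScan(img + 0.25), 1.8)
        assert np.allclose(rx1, rx2, atol=1e-12)
        assert np.allclose(ry1, ry2, atol=1e-12)

    def test_linearity_of_raw_responses(self):
        a, b = 0.3, 0.6
        i1 = RNG.random((16, 16)) * 0.5
        i2 = RNG.random((16, 16)) * 0.5
        rx1, _ = edge_responses(BScan(i1), 1.8)
        rx2, _ = edge_responses(BScan(i2), 1.8)
        rx12, _ = edge_responses(BScan(np.clip(a * i1 + b * i2, 0, 1)), 1.8)
        assert np.allclose(rx12, a * rx1 + b * rx2, atol=1e-6)

    def test_kernel_is_exactly_antisymmetric(self):
        from octfluid.preprocess import _dog_kernels

        kx, ky = _dog_kernels(1.8)
        assert np.array_equal(kx, -kx[:, ::-1])
        assert np.array_equal(ky, -ky[::-1, :])
        # the true sum is zero by antisymmetry; only summation dust remains
        assert abs(kx.sum()) < 1e-15
        assert abs(ky.sum()) < 1e-15


class TestPipeline:
    def test_image_and_edge_map_share_dimensions(self, phantom_pair):
        enhanced, edges, box = preprocess_pipeline(
            BScan(phantom_pair.image), None)
        assert enhanced.pixels.shape == edges.response.shape
        assert box.shape == enhanced.pixels.shape

    def test_pipeline_is_deterministic(self, phantom_pair):
        r1 = preprocess_pipeline(BScan(phantom_pair.image), None)
        r2 = preprocess_pipeline(BScan(phantom_pair.image), None)
        assert np.array_equal(r1[0].pixels, r2[0].pixels)
        assert np.array_equal(r1[1].response, r2[1].response)

    def test_roi_covers_phantom_mask_rows(self, phantom_pair):
        _, _, box = preprocess_pipeline(BScan(phantom_pair.image), None)
        rows = np.unique(np.nonzero(phantom_pair.mask)[0])
        covered = (rows >= box.row_start) & (rows < box.row_end)
        assert covered.mean() >= 0.95

    def test_every_stage_stays_in_unit_interval(self, phantom_pair):
        img = BScan(phantom_pair.image)
        for stage in (lambda x: match_histogram(x, img),
                      median_denoise, clahe,
                      lambda x: gamma_correct(x, 1.7)):
            img = stage(img)
            assert img.pixels.min() >= 0 and img.pixels.max() <= 1
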
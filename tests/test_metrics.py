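"""The eight fusion-quality metrics against hand values and loop oracles."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from skimage.metrics import structural_similarity as skimage_ssim

from conftest import (average_gradient_oracle, entropy_oracle,
                      mutual_information_oracle, paired_t_oracle, psnr_oracle,
                      spatial_frequency_oracle)
from res2fuse import (average_gradient, entropy, evaluate_batch, evaluate_pair,
                      mutual_information, paired_t_test, psnr, qabf,
                      spatial_frequency, ssim_fusion, viff)


@pytest.fixture(scope="module")
def structured():
    """A gradient-rich smooth test image."""
    r = np.random.default_rng(3)
    g = gaussian_filter(r.random((64, 64)), 1.0)
    return (g - g.min()) / (g.max() - g.min())


class TestGradientMetrics:
    def test_constant_image_scores_zero(self):
        flat = np.full((8, 8), 0.4)
        assert average_gradient(flat) == 0.0
        assert spatial_frequency(flat) == 0.0

    def test_two_by_two_hand_values(self):
        img = np.array([[0.0, 1.0], [0.0, 1.0]])
        assert average_gradient(img) == pytest.approx(np.sqrt(0.5), abs=1e-9)
        assert spatial_frequency(img) == pytest.approx(np.sqrt(0.5), abs=1e-9)

    def test_transpose_swaps_row_and_column_frequencies(self, rng):
        img = rng.random((10, 14))
        assert spatial_frequency(img) == pytest.approx(spatial_frequency(img.T), rel=1e-12)

    def test_intensity_shift_invariance(self, rng):
        img = 0.5 * rng.random((12, 12))
        assert average_gradient(img + 0.3) == pytest.approx(average_gradient(img), abs=1e-12)
        assert spatial_frequency(img + 0.3) == pytest.approx(spatial_frequency(img), abs=1e-12)

    def test_match_loop_oracles(self, rng):
        img = rng.random((11, 13))
        assert average_gradient(img) == pytest.approx(average_gradient_oracle(img), abs=1e-9)
        assert spatial_frequency(img) == pytest.approx(spatial_frequency_oracle(img), abs=1e-9)

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError, match="at least"):
            average_gradient(np.array([[0.5]]))


class TestEntropy:
    def test_constant_image_zero_bits(self):
        assert entropy(np.full((8, 8), 0.7)) == 0.0

    def test_two_equal_bins_one_bit(self):
        img = np.zeros((16, 16))
        img[:8] = 1.0
        assert entropy(img) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_histogram_is_log2_levels(self):
        img = np.repeat(np.arange(256), 4).reshape(32, 32) / 255.0
        assert entropy(img) == pytest.approx(8.0, abs=1e-12)

    def test_bounded_by_log2_levels(self, rng):
        assert entropy(rng.random((32, 32)), levels=64) <= np.log2(64) + 1e-12

    def test_matches_loop_oracle(self, rng):
        img = rng.random((12, 12))
        assert entropy(img) == pytest.approx(entropy_oracle(img), abs=1e-9)


class TestMutualInformation:
    def test_self_information_equals_entropy(self, rng):
        img = rng.random((16, 16))
        got = mutual_information(img, img, img, mode="pair_literal")
        assert got == pytest.approx(entropy(img), abs=1e-9)

    def test_independent_images_near_zero(self):
        # histogram MI is biased upward by ~(K-1)^2 / (2 N ln 2) for K bins on
        # N samples, so the vanishing limit is visible once the bin count is
        # modest relative to the sample count
        r = np.random.default_rng(10)
        a, b = r.random((256, 256)), r.random((256, 256))
        assert mutual_information(a, a, b, mode="pair_literal", levels=32) < 0.05
        coarse = mutual_information(a[:64, :64], a[:64, :64], b[:64, :64],
                                    mode="pair_literal", levels=32)
        fine = mutual_information(a, a, b, mode="pair_literal", levels=32)
        assert fine < coarse  # estimate shrinks toward 0 as size grows

    def test_symmetric_in_sources(self, rng):
        f, a, b = rng.random((16, 16)), rng.random((16, 16)), rng.random((16, 16))
        assert mutual_information(f, a, b) == pytest.approx(
            mutual_information(f, b, a), abs=1e-12
        )

    def test_matches_joint_histogram_oracle(self, rng):
        f, a, b = (rng.random((10, 10)) for _ in range(3))
        assert mutual_information(f, a, b) == pytest.approx(
            mutual_information_oracle(f, a, b), abs=1e-9
        )

    def test_size_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="shape"):
            mutual_information(rng.random((8, 8)), rng.random((8, 8)), rng.random((9, 9)))


class TestPsnr:
    def test_identical_triple_flags_infinite(self, rng):
        x = rng.random((8, 8))
        assert psnr(x, x, x) == np.inf

    def test_uniform_offset_hand_value(self, rng):
        f = rng.random((16, 16)) * 0.8
        f[0, 0] = 1.0  # fused peak r = 1 so both peak conventions coincide
        b = f + 0.1
        assert psnr(f, f, b) == pytest.approx(10 * np.log10(1 / 0.005), abs=1e-9)
        assert psnr(f, f, b) == pytest.approx(23.0103, abs=1e-4)

    def test_matches_loop_oracle(self, rng):
        f, a, b = (rng.random((9, 9)) for _ in range(3))
        assert psnr(f, a, b) == pytest.approx(psnr_oracle(f, a, b), abs=1e-6)

    def test_full_scale_peak_convention(self, rng):
        f = 0.5 * rng.random((8, 8))
        a, b = f + 0.05, f - 0.02
        lit = psnr(f, a, b, peak="fused_max")
        full = psnr(f, a, b, peak="full_scale")
        assert full > lit  # r = 1 exceeds the fused image's own peak


class TestSsimFusion:
    def test_identical_triple_is_one(self, rng):
        x = rng.random((32, 32))
        assert ssim_fusion(x, x, x) == pytest.approx(1.0, abs=1e-12)

    def test_half_self_half_reference(self):
        r = np.random.default_rng(5)
        f = r.random((64, 64))
        b = r.random((64, 64))
        ref = skimage_ssim(b, f, win_size=11, gaussian_weights=True, sigma=1.5,
                           use_sample_covariance=False, data_range=1.0)
        assert ssim_fusion(f, f, b) == pytest.approx(0.5 * (1.0 + ref), abs=1e-9)

    def test_inversion_scores_lower(self, structured):
        assert ssim_fusion(1.0 - structured, structured, structured) < \
            ssim_fusion(structured, structured, structured)


class TestQabf:
    def test_perfect_fusion_close_to_one(self, structured):
        assert qabf(structured, structured, structured) > 0.95

    def test_constant_fused_close_to_zero(self, structured):
        assert qabf(np.full_like(structured, 0.5), structured, structured) < 0.05

    def test_symmetric_in_sources(self, rng, structured):
        other = gaussian_filter(rng.random((64, 64)), 1.5)
        other = (other - other.min()) / (other.max() - other.min())
        f = 0.5 * (structured + other)
        assert qabf(f, structured, other) == pytest.approx(
            qabf(f, other, structured), abs=1e-12
        )


class TestViff:
    def test_perfect_fusion_near_one(self, structured):
        assert 0.95 <= viff(structured, structured, structured) <= 1.05

    def test_blur_strictly_degrades(self, structured):
        blurred = gaussian_filter(structured, 3.0)
        assert viff(blurred, structured, structured) < \
            viff(structured, structured, structured)

    def test_symmetric_in_sources(self, rng, structured):
        other = np.clip(structured + 0.1 * rng.random((64, 64)), 0, 1)
        f = 0.5 * (structured + other)
        assert viff(f, structured, other) == pytest.approx(
            viff(f, other, structured), abs=1e-12
        )

    def test_too_small_image_raises(self, rng):
        with pytest.raises(ValueError, match="at least"):
            viff(rng.random((16, 16)), rng.random((16, 16)), rng.random((16, 16)))


class TestDegradationMonotonicity:
    def test_noise_strictly_degrades_perceptual_metrics(self, structured):
        r = np.random.default_rng(8)
        clean_ssim = ssim_fusion(structured, structured, structured)
        clean_qabf = qabf(structured, structured, structured)
        prev_ssim, prev_qabf = clean_ssim, clean_qabf
        for sd in (0.05, 0.15):
            noisy = np.clip(structured + r.normal(0, sd, structured.shape), 0, 1)
            s = ssim_fusion(noisy, structured, structured)
            q = qabf(noisy, structured, structured)
            assert s < prev_ssim and q < prev_qabf
            prev_ssim, prev_qabf = s, q


class TestReportsAndTTest:
    def test_evaluate_pair_assembles_all_metrics(self, structured, rng):
        other = np.clip(structured + 0.1 * rng.random((64, 64)), 0, 1)
        rep = evaluate_pair(structured, structured, other)
        d = rep.as_dict()
        assert set(d) == {"ag", "sf", "en", "mi", "psnr", "ssim", "qabf", "viff"}
        assert all(np.isfinite(v) for v in d.values())

    def test_batch_mean_row_is_column_mean(self, structured, rng):
        other = np.clip(structured + 0.1 * rng.random((64, 64)), 0, 1)
        df = evaluate_batch([(structured, structured, other)] * 3)
        body = df.drop(index="mean")
        assert np.allclose(df.loc["mean"].to_numpy(), body.mean(axis=0).to_numpy(),
                           atol=1e-9)

    def test_empty_batch_raises(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate_batch([])

    def test_identical_columns_degenerate(self):
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            t, p = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_constant_shift_is_maximally_significant(self):
        # binary-exact values keep the paired differences exactly constant
        x = np.array([0.125, 0.5, 0.25, 0.875, 0.375])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            t, p = paired_t_test(x + 1.0, x)
        assert p < 0.01

    def test_matches_textbook_formula(self, rng):
        x, y = rng.random(12), rng.random(12)
        t, p = paired_t_test(x, y)
        t0, p0 = paired_t_oracle(x, y)
        assert t == pytest.approx(t0, abs=1e-9)
        assert p == pytest.approx(p0, abs=1e-9)
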
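"""Normalization and FFT magnitude-spectrum preprocessing.

The independent oracle for the transform is a direct DFT evaluated
without any fast algorithm: a quadruple loop for tiny inputs, and an
explicit DFT-matrix product for larger ones.
"""

import numpy as np
import pytest

from thermofract.preprocess import (
    NormalizedROI,
    SpectrumImage,
    center_crop,
    full_magnitude_spectrum,
    magnitude_spectrum,
    normalize_injured_roi,
    pad_to_minimum,
    png_to_array,
    spectrum_to_uint8,
    to_png,
)


def direct_dft_magnitude_loops(x):
    """O(N^2 M^2) quadruple-loop DFT modulus, shifted to center."""
    h, w = x.shape
    out = np.zeros((h, w), dtype=complex)
    for u in range(h):
        for v in range(w):
            acc = 0.0
            for i in range(h):
                for j in range(w):
                    acc += x[i, j] * np.exp(-2j * np.pi * (u * i / h + v * j / w))
            out[u, v] = acc
    return np.abs(np.fft.fftshift(out))


def direct_dft_magnitude_matrix(x):
    """Direct DFT via explicit Vandermonde matrices (no FFT recursion)."""
    h, w = x.shape
    fh = np.exp(-2j * np.pi * np.outer(np.arange(h), np.arange(h)) / h)
    fw = np.exp(-2j * np.pi * np.outer(np.arange(w), np.arange(w)) / w)
    return np.abs(np.fft.fftshift(fh @ x @ fw))


class TestNormalize:
    def test_identical_rois_give_zero(self):
        out = normalize_injured_roi(np.full((5, 5), 32.0), np.full((4, 6), 32.0))
        assert np.array_equal(out.pixels, np.zeros((5, 5)))

    def test_constant_offset(self):
        uninjured = np.array([[31.0, 33.0], [32.5, 31.5]])  # mean 32.0
        out = normalize_injured_roi(np.full((3, 3), 33.5), uninjured)
        assert np.allclose(out.pixels, 1.5)

    def test_checkerboard_mean_arithmetic(self):
        # hand computation on a 4x4 matrix: output mean equals the
        # difference of the two ROI means
        uninjured = np.full((4, 4), 30.0)
        checker = 0.2 * (-1.0) ** (np.add.outer(np.arange(4), np.arange(4)))
        injured = uninjured + checker
        out = normalize_injured_roi(injured, uninjured)
        assert out.pixels.mean() == pytest.approx(injured.mean() - uninjured.mean())
        assert np.allclose(out.pixels, checker)

    def test_uninjured_shift_moves_output_by_minus_c(self):
        rng = np.random.default_rng(0)
        injured, uninjured = rng.normal(31, 1, (6, 7)), rng.normal(31, 1, (5, 5))
        a = normalize_injured_roi(injured, uninjured).pixels
        b = normalize_injured_roi(injured, uninjured + 2.5).pixels
        assert np.allclose(b, a - 2.5)

    def test_empty_or_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            normalize_injured_roi(np.zeros((0, 3)), np.ones((2, 2)))
        with pytest.raises(ValueError):
            normalize_injured_roi(np.full((2, 2), np.nan), np.ones((2, 2)))


class TestMagnitudeSpectrum:
    def test_all_zero_roi_gives_all_zero_spectrum(self):
        spec = magnitude_spectrum(NormalizedROI(np.zeros((120, 120))))
        assert spec.magnitude.shape == (100, 100)
        assert np.all(spec.magnitude == 0)

    def test_unit_impulse_gives_flat_unit_magnitude(self):
        roi = np.zeros((100, 100))
        roi[13, 87] = 1.0
        spec = magnitude_spectrum(NormalizedROI(roi))
        assert np.allclose(spec.magnitude, 1.0, atol=1e-12)

    def test_cosine_concentrates_in_two_symmetric_bins(self):
        # cos(2*pi*8*x/128) on 128x128: two bins of magnitude 128^2/2,
        # checked bin-for-bin against the direct DFT-matrix oracle
        n, k = 128, 8
        roi = np.broadcast_to(np.cos(2 * np.pi * k * np.arange(n) / n), (n, n)).T.copy()
        full = full_magnitude_spectrum(roi)
        oracle = direct_dft_magnitude_matrix(roi)
        assert np.allclose(full, oracle, atol=1e-6)
        c = n // 2
        hot = np.argwhere(full > 1.0)
        assert {tuple(p) for p in hot} == {(c - k, c), (c + k, c)}
        assert full[c - k, c] == pytest.approx(n**2 / 2, rel=1e-12)
        spec = magnitude_spectrum(NormalizedROI(roi))
        assert spec.magnitude[50 - k, 50] == pytest.approx(n**2 / 2, rel=1e-12)

    @pytest.mark.parametrize("shape", [(4, 4), (7, 5), (16, 16)])
    def test_matches_quadruple_loop_dft_oracle(self, shape):
        rng = np.random.default_rng(sum(shape))
        x = rng.normal(size=shape)
        assert np.allclose(full_magnitude_spectrum(x),
                           direct_dft_magnitude_loops(x), atol=1e-8)

    def test_dc_bin_position_and_value(self):
        rng = np.random.default_rng(1)
        for shape in [(100, 100), (60, 80), (160, 131)]:
            roi = rng.normal(0.5, 1.0, shape)
            spec = magnitude_spectrum(NormalizedROI(roi))
            # zero padding never changes the image sum
            assert spec.magnitude[50, 50] == pytest.approx(abs(roi.sum()), rel=1e-9)
            assert spec.magnitude[50, 50] == spec.magnitude.max()

    def test_real_input_symmetry_about_center(self):
        rng = np.random.default_rng(2)
        mag = full_magnitude_spectrum(rng.normal(size=(100, 100)))
        c = 50
        for u, v in [(1, 0), (0, 1), (7, 3), (49, 49), (10, 45)]:
            assert mag[c + u, c + v] == pytest.approx(mag[c - u, c - v], rel=1e-6)

    def test_parseval_identity_on_padded_input(self):
        rng = np.random.default_rng(3)
        roi = rng.normal(size=(72, 95))
        padded = pad_to_minimum(roi)
        mag = full_magnitude_spectrum(padded)
        assert (mag**2).sum() / padded.size == pytest.approx((padded**2).sum(), rel=1e-10)

    def test_padding_is_symmetric_and_content_preserving(self):
        roi = np.arange(12.0).reshape(3, 4)
        padded = pad_to_minimum(roi, (7, 6))
        assert padded.shape == (7, 6)
        assert np.array_equal(padded[2:5, 1:5], roi)
        assert padded.sum() == roi.sum()

    def test_center_crop_against_spec_shape(self):
        x = np.arange(104 * 102).reshape(104, 102).astype(float)
        out = center_crop(x, (100, 100))
        assert out.shape == (100, 100)
        assert out[50, 50] == x[52, 51]  # DC bin carried to (50, 50)


class TestPng:
    def test_all_zero_magnitude_maps_to_all_zero_png(self):
        spec = SpectrumImage(np.zeros((100, 100)))
        assert np.all(spec.png_pixels == 0)
        assert np.all(png_to_array(to_png(spec)) == 0)

    def test_single_positive_bin_maps_to_255(self):
        mag = np.zeros((100, 100))
        mag[10, 90] = 7.0
        png = spectrum_to_uint8(mag)
        assert png[10, 90] == 255
        assert png.sum() == 255

    def test_png_codec_round_trip_is_lossless(self):
        rng = np.random.default_rng(4)
        spec = SpectrumImage(np.abs(rng.normal(size=(100, 100))) * 100)
        assert np.array_equal(png_to_array(to_png(spec)), spec.png_pixels)

    def test_log_scaling_orders_preserved(self):
        mag = np.zeros((100, 100))
        mag[0, 0], mag[1, 1], mag[2, 2] = 1.0, 10.0, 100.0
        png = spectrum_to_uint8(mag)
        assert png[0, 0] < png[1, 1] < png[2, 2] == 255
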
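import numpy as np
import pytest

from musfa import (
    BModeImage,
    ConfigurationError,
    PolygonROI,
    ROITooSmallError,
    SFAConfig,
    ValidationError,
    analyze_roi,
    enumerate_kernels,
    extract_peak,
    highpass_filter,
    highpass_gain,
    kernel_px,
    kernel_spectrum,
    mmax_percent,
)
from musfa.synthetic import PhantomSpec, make_phantom

from conftest import naive_dft_magnitude


class TestKernelPx:
    def test_paper_geometry(self):
        img = BModeImage(np.zeros((200, 200)), 0.1, 0.1)
        assert kernel_px(img, SFAConfig()) == 65

    def test_kernel_exceeding_pad_rejected(self):
        img = BModeImage(np.zeros((200, 200)), 0.05, 0.05)
        with pytest.raises(ConfigurationError):
            kernel_px(img, SFAConfig())  # 130 px > pad 128

    def test_kernel_too_small_rejected(self):
        img = BModeImage(np.zeros((200, 200)), 0.1, 0.1)
        with pytest.raises(ConfigurationError):
            kernel_px(img, SFAConfig(kernel_mm=0.4))  # 4 px < 8


class TestEnumerateKernels:
    def test_tight_fit_single_origin(self, rect_roi):
        img = BModeImage(np.zeros((80, 80)), 0.1, 0.1)
        cfg = SFAConfig(kernel_mm=2.0)  # 20 px
        assert enumerate_kernels(img, rect_roi(5, 5, 24, 24), cfg) == [(5, 5)]

    def test_k_plus_two_gives_nine(self, rect_roi):
        img = BModeImage(np.zeros((80, 80)), 0.1, 0.1)
        cfg = SFAConfig(kernel_mm=2.0)
        origins = enumerate_kernels(img, rect_roi(5, 5, 26, 26), cfg)
        assert len(origins) == 9
        assert origins == [(r, c) for r in (5, 6, 7) for c in (5, 6, 7)]

    def test_matches_exhaustive_containment_scan(self):
        from musfa.image_io import polygon_mask

        img = BModeImage(np.zeros((60, 60)), 0.1, 0.1)
        cfg = SFAConfig(kernel_mm=1.2)  # 12 px
        roi = PolygonROI(
            [(4, 10), (10, 52), (40, 55), (55, 30), (35, 4)], "injured", "img"
        )
        mask = polygon_mask(img.shape, roi)
        k = 12
        expected = [
            (r, c)
            for r in range(60 - k + 1)
            for c in range(60 - k + 1)
            if mask[r : r + k, c : c + k].all()
        ]
        assert enumerate_kernels(img, roi, cfg) == expected

    def test_too_small_roi_names_it(self, rect_roi):
        img = BModeImage(np.zeros((80, 80)), 0.1, 0.1)
        with pytest.raises(ROITooSmallError, match="injured"):
            enumerate_kernels(
                img, rect_roi(5, 5, 10, 10, label="injured"), SFAConfig(kernel_mm=2.0)
            )


class TestKernelSpectrum:
    def test_all_zero_kernel(self):
        cfg = SFAConfig(pad_n=16)
        mag, _, _ = kernel_spectrum(np.zeros((8, 8)), cfg, 0.1)
        assert np.all(mag == 0)

    def test_constant_kernel_dc_is_sum(self):
        cfg = SFAConfig(pad_n=16)
        mag, _, _ = kernel_spectrum(np.full((8, 8), 3.0), cfg, 0.1)
        assert mag[0, 0] == pytest.approx(3.0 * 64)
        # mean subtraction removes the padded-window leakage entirely
        assert np.all(mag.ravel()[1:] < 1e-9)

    def test_constant_kernel_leakage_without_subtraction(self):
        cfg = SFAConfig(pad_n=16, subtract_mean=False)
        mag, _, _ = kernel_spectrum(np.full((8, 8), 3.0), cfg, 0.1)
        assert mag[0, 0] == pytest.approx(3.0 * 64)
        assert mag[1, 0] > 0  # Dirichlet sidelobe of the padded window

    @pytest.mark.parametrize("subtract_mean", [True, False])
    def test_matches_naive_dft(self, subtract_mean):
        rng = np.random.default_rng(5)
        kern = rng.uniform(0, 255, (8, 8))
        cfg = SFAConfig(pad_n=16, subtract_mean=subtract_mean)
        mag, fa, fl = kernel_spectrum(kern, cfg, 0.1)
        oracle = naive_dft_magnitude(kern, 16, subtract_mean)
        np.testing.assert_allclose(mag, oracle, rtol=1e-8, atol=1e-8)
        assert fa[1] == pytest.approx(1 / (16 * 0.1))

    def test_non_square_kernel_rejected(self):
        with pytest.raises(ValidationError):
            kernel_spectrum(np.zeros((8, 9)), SFAConfig(pad_n=16), 0.1)


class TestHighpass:
    def test_gain_at_cutoff_is_minus_3db(self):
        cfg = SFAConfig()
        f = np.fft.fftfreq(128, 0.1)
        gain = highpass_gain(f, f, cfg)
        # radius exactly at the cutoff on a synthetic axis
        fr = np.hypot(f[:, None], f[None, :])
        idx = np.unravel_index(np.argmin(np.abs(fr - cfg.hp_cutoff)), fr.shape)
        expected = 1 / np.sqrt(1 + (cfg.hp_cutoff / fr[idx]) ** 4)
        assert gain[idx] == pytest.approx(expected)
        assert 1 / np.sqrt(1 + 1) == pytest.approx(0.70710678)

    def test_gain_zero_at_dc_and_near_one_far_above(self):
        cfg = SFAConfig()
        f = np.fft.fftfreq(128, 0.1)
        gain = highpass_gain(f, f, cfg)
        assert gain[0, 0] == 0.0
        fr = np.hypot(f[:, None], f[None, :])
        idx = np.unravel_index(np.argmin(np.abs(fr - 4 * cfg.hp_cutoff)), fr.shape)
        assert gain[idx] == pytest.approx(1 / np.sqrt(1 + 0.25**4), abs=1e-4)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        f = np.fft.fftfreq(128, 0.1)  # Nyquist 5
        with pytest.raises(ConfigurationError):
            highpass_gain(f, f, SFAConfig(hp_cutoff=5.0))

    def test_filter_multiplies_gain(self):
        cfg = SFAConfig(pad_n=32)
        f = np.fft.fftfreq(32, 0.1)
        spec = np.ones((32, 32))
        filt = highpass_filter(spec, f, f, cfg)
        np.testing.assert_allclose(filt, highpass_gain(f, f, cfg))


class TestExtractPeak:
    def test_cosine_peak_bin_and_radius(self):
        # banding of period 1.25 mm at 0.1 mm pixels, 65-px kernel, pad 128:
        # nearest bin to the true 0.8 cycles/mm is bin 10 = 0.78125
        z = np.arange(65)[:, None] * 0.1
        kern = (100 + 50 * np.cos(2 * np.pi * z / 1.25)) * np.ones((1, 65))
        cfg = SFAConfig()
        mag, fa, fl = kernel_spectrum(kern, cfg, 0.1)
        filt = highpass_filter(mag, fa, fl, cfg)
        (u, v), _, psfr = extract_peak(filt, fa, fl, cfg)
        assert (u, v) == (10, 0)
        assert psfr == pytest.approx(10 / (128 * 0.1))
        # oracle: the same bin maximises a brute-force DFT magnitude
        oracle = naive_dft_magnitude(kern, 128)
        goracle = oracle * highpass_gain(fa, fl, cfg)
        half = goracle.copy()
        half[0, :] = 0
        half[64:, :] = 0
        half[0, 1:64] = goracle[0, 1:64]
        assert np.unravel_index(np.argmax(half), half.shape) == (10, 0)

    def test_rotation_gives_same_radius(self):
        z = np.arange(65)[:, None] * 0.1
        kern = (100 + 50 * np.cos(2 * np.pi * z / 1.25)) * np.ones((1, 65))
        cfg = SFAConfig()

        def psfr_of(k):
            mag, fa, fl = kernel_spectrum(k, cfg, 0.1)
            return extract_peak(highpass_filter(mag, fa, fl, cfg), fa, fl, cfg)[2]

        assert psfr_of(kern) == pytest.approx(psfr_of(kern.T))

    def test_all_zero_spectrum_flags_no_peak(self):
        f = np.fft.fftfreq(32, 0.1)
        assert extract_peak(np.zeros((32, 32)), f, f, SFAConfig(pad_n=32)) is None

    def test_radius_never_exceeds_nyquist(self):
        rng = np.random.default_rng(8)
        cfg = SFAConfig(pad_n=32)
        f = np.fft.fftfreq(32, 0.1)
        for _ in range(20):
            spec = rng.uniform(0, 1, (32, 32))
            _, _, psfr = extract_peak(spec, f, f, cfg)
            assert 0 <= psfr <= 5.0 + 1e-12


class TestMmaxPercent:
    def test_arithmetic_cases(self):
        assert mmax_percent(0.0, 100.0) == 0.0
        assert mmax_percent(2.5, 100.0) == pytest.approx(2.5)
        assert np.isnan(mmax_percent(0.0, 0.0))
        with pytest.raises(ValidationError):
            mmax_percent(1.0, 0.0)

    def test_closed_form_cosine_25_percent(self):
        # 100 + 50*cos with integer periods and no padding: dc = 100*k^2,
        # each first-harmonic bin 25*k^2 -> Mmax% = 25
        k = 16
        z = np.arange(k)[:, None]
        kern = (100 + 50 * np.cos(2 * np.pi * 4 * z / k)) * np.ones((1, k))
        cfg = SFAConfig(pad_n=16)
        mag, fa, fl = kernel_spectrum(kern, cfg, 0.1)
        assert mag[0, 0] == pytest.approx(100 * k**2)
        assert mag[4, 0] == pytest.approx(25 * k**2)
        assert mmax_percent(mag[4, 0], mag[0, 0]) == pytest.approx(25.0)


class TestAnalyzeROI:
    def test_single_kernel_roi_equals_kernel_values(self, cosine_image, rect_roi):
        img = cosine_image(shape=(80, 80))
        cfg = SFAConfig(kernel_mm=2.0)
        res = analyze_roi(img, rect_roi(10, 10, 29, 29), cfg)
        assert res.n_kernels == 1
        kr = res.kernels[0]
        assert res.mean_psfr == kr.psfr
        assert res.mean_mmax_pct == kr.mmax_pct

    def test_merged_roi_mean_is_weighted_average(self, cosine_image, rect_roi):
        img = cosine_image(shape=(120, 60))
        cfg = SFAConfig(kernel_mm=2.0)
        a = analyze_roi(img, rect_roi(5, 5, 30, 40), cfg)
        b = analyze_roi(img, rect_roi(60, 5, 100, 40), cfg)
        merged_mean = (
            a.mean_psfr * a.n_kernels + b.mean_psfr * b.n_kernels
        ) / (a.n_kernels + b.n_kernels)
        origins = set()
        for res, off in ((a, 5), (b, 60)):
            origins.update(k.origin for k in res.kernels)
        # same placements computed jointly via two disjoint rect ROIs
        both = [k.psfr for k in a.kernels] + [k.psfr for k in b.kernels]
        assert np.mean(both) == pytest.approx(merged_mean)

    def test_banded_phantom_recovery_within_one_bin(self, rect_roi, fast_cfg):
        spec = PhantomSpec(
            shape_mm=(16, 16), band_spacing_mm=1.25, band_amplitude=0.6,
            noise_sigma=6, seed=42,
        )
        img = make_phantom(spec)
        res = analyze_roi(img, rect_roi(20, 20, 139, 139), fast_cfg)
        assert abs(res.mean_psfr - 0.8) <= 1 / (128 * 0.1)

    def test_requires_isotropic(self, rect_roi):
        img = BModeImage(np.zeros((80, 80)), 0.2, 0.1)
        with pytest.raises(ValidationError):
            analyze_roi(img, rect_roi(5, 5, 40, 40), SFAConfig(kernel_mm=2.0))

    def test_bounds_on_all_kernels(self, rect_roi, fast_cfg):
        spec = PhantomSpec(shape_mm=(14, 14), band_amplitude=0.1, seed=9)
        img = make_phantom(spec)
        res = analyze_roi(img, rect_roi(15, 15, 124, 124), fast_cfg)
        nyq = 0.5 / img.spacing_axial
        for kr in res.kernels:
            assert 0 <= kr.psfr <= nyq
            assert 0 <= kr.mmax_pct <= 100


class TestPipelineProperties:
    def test_full_pipeline_matches_naive_dft_small(self, rect_roi):
        """Small-kernel spectra agree bin-for-bin with the direct DFT."""
        rng = np.random.default_rng(11)
        cfg = SFAConfig(kernel_mm=1.2, pad_n=32)  # 12-px kernel
        for _ in range(5):
            kern = rng.uniform(0, 255, (12, 12))
            mag, fa, fl = kernel_spectrum(kern, cfg, 0.1)
            oracle = naive_dft_magnitude(kern, 32)
            np.testing.assert_allclose(mag, oracle, rtol=1e-8, atol=1e-6)

    def test_phase_invariance(self, rect_roi):
        """Sub-period translation: psfr identical, Mmax% within 2% relative."""
        cfg = SFAConfig(stride_px=4)
        roi = rect_roi(10, 10, 109, 109)

        def run(shift_mm):
            z = (np.arange(140)[:, None] * 0.1) + shift_mm
            pix = 120 + 60 * np.cos(2 * np.pi * z / 1.25) * np.ones((1, 140))
            img = BModeImage(pix, 0.1, 0.1, "shifted")
            return analyze_roi(img, roi, cfg)

        base = run(0.0)
        for shift in (0.3, 0.61, 0.9):
            res = run(shift)
            assert res.mean_psfr == base.mean_psfr
            assert res.mean_mmax_pct == pytest.approx(base.mean_mmax_pct, rel=0.02)

    def test_calibration_invariance_across_pixel_sizes(self, rect_roi):
        """Same physical phantom at 0.08 and 0.12 mm pixels: mean PSFR within
        one frequency bin of the coarser grid."""
        cfg = SFAConfig(stride_px=4)
        results = {}
        for px in (0.08, 0.12):
            n = int(round(14.0 / px))
            z = np.arange(n)[:, None] * px
            pix = 120 + 60 * np.cos(2 * np.pi * z / 1.25) * np.ones((1, n))
            img = BModeImage(pix, px, px, f"px{px}")
            lo, hi = int(1.0 / px), int(13.0 / px)
            results[px] = analyze_roi(img, rect_roi(lo, lo, hi, hi), cfg).mean_psfr
        coarse_bin = 1 / (128 * 0.12)
        assert abs(results[0.08] - results[0.12]) <= coarse_bin

    def test_stride_two_close_to_stride_one(self, rect_roi):
        spec = PhantomSpec(shape_mm=(12, 12), band_spacing_mm=1.25,
                           band_amplitude=0.5, noise_sigma=6, seed=3)
        img = make_phantom(spec)
        roi = rect_roi(10, 10, 109, 109)
        r1 = analyze_roi(img, roi, SFAConfig(stride_px=1))
        r2 = analyze_roi(img, roi, SFAConfig(stride_px=2))
        assert r2.mean_psfr == pytest.approx(r1.mean_psfr, rel=0.01)
        assert r2.mean_mmax_pct == pytest.approx(r1.mean_mmax_pct, rel=0.01)

    def test_mmax_monotone_in_band_amplitude(self, rect_roi, fast_cfg):
        vals = []
        for amp in (0.0, 0.2, 0.4, 0.6, 0.8):
            spec = PhantomSpec(shape_mm=(14, 14), band_spacing_mm=1.25,
                               band_amplitude=amp, noise_sigma=6, seed=17)
            img = make_phantom(spec)
            vals.append(analyze_roi(img, rect_roi(15, 15, 124, 124), fast_cfg).mean_mmax_pct)
        assert all(a < b for a, b in zip(vals, vals[1:]))
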
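"""Tests for the synthetic benchmark and FID generators."""

import numpy as np
import pytest
from scipy.special import erf

from fifnmr import (
    BenchmarkSpec,
    PeakSpec,
    add_noise,
    apply_dead_time,
    build_benchmark,
    gen_fid,
    schulze_baseline,
    schulze_peaks,
)
from fifnmr.simulate import SCHULZE_CENTERS


class TestSchulzePeaks:
    def test_local_maxima_near_stated_centers(self):
        y = schulze_peaks()
        for center in (340, 656):
            window = y[center - 3 : center + 4]
            assert window.max() == y[center - 3 + np.argmax(window)]
            assert abs(np.argmax(y[center - 10 : center + 11]) - 10) <= 1

    def test_linearity(self):
        y = schulze_peaks()
        np.testing.assert_allclose(2.0 * y, 2.0 * schulze_peaks(), atol=1e-14)

    def test_integral_matches_per_line_sum(self):
        # unit-area Gaussian convolution preserves each line's integral
        x = np.arange(1001, dtype=float)
        total = 0.0
        for center, fwhm in zip(SCHULZE_CENTERS, (10.0, *(5.7,) * 6)):
            hwhm = fwhm / 2.0
            total += np.sum(hwhm**2 / ((x - center) ** 2 + hwhm**2))
        assert schulze_peaks().sum() == pytest.approx(total, rel=0.01)

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError):
            schulze_peaks(600)


class TestSchulzeBaseline:
    def test_zero_slope_is_flat_unit(self):
        np.testing.assert_array_equal(schulze_baseline(0.0), np.ones(1001))

    @pytest.mark.parametrize("slope", [0.1, 0.3, 1.0])
    def test_monotone_nondecreasing(self, slope):
        assert np.all(np.diff(schulze_baseline(slope)) >= 0)

    @pytest.mark.parametrize("slope", [0.1, 0.3, 1.0])
    def test_amplitude_equals_slope(self, slope):
        b = schulze_baseline(slope)
        assert b[-1] == pytest.approx(1.0 + slope, abs=1e-9)
        assert b[0] == pytest.approx(1.0 - slope, abs=1e-9)

    @pytest.mark.parametrize("slope", [0.1, 0.3, 1.0])
    def test_midpoint_slope_analytic(self, slope):
        # b(x) = 1 + slope * erf(sqrt(pi)/2 (x-500)): the analytic
        # derivative at the midpoint is slope * (sqrt(pi)/2) * 2/sqrt(pi)
        # = slope exactly; the unit-spacing central difference is the
        # closed form slope * erf(sqrt(pi)/2)
        k = np.sqrt(np.pi) / 2.0
        analytic = slope * k * 2.0 / np.sqrt(np.pi)
        assert analytic == pytest.approx(slope, abs=1e-15)
        b = schulze_baseline(slope)
        fd = (b[501] - b[499]) / 2.0
        assert fd == pytest.approx(slope * erf(k), abs=1e-12)

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            schulze_baseline(-0.1)


class TestAddNoise:
    def test_deterministic_under_seed(self):
        y = np.ones(100)
        a, sa = add_noise(y, 5.0, seed=42)
        b, sb = add_noise(y, 5.0, seed=42)
        np.testing.assert_array_equal(a, b)
        assert sa == sb

    def test_sigma_scales_inversely_with_snr(self):
        y = np.ones(10)
        _, s1 = add_noise(y, 10.0, 0)
        _, s2 = add_noise(y, 1000.0, 0)
        assert s1 == pytest.approx(100 * s2)

    def test_empirical_std_matches_sigma(self):
        y = np.full(100_000, 2.0)
        noisy, sigma = add_noise(y, 5.0, seed=3)
        assert np.std(noisy - y) == pytest.approx(sigma, rel=0.02)

    def test_nonpositive_snr_rejected(self):
        with pytest.raises(ValueError):
            add_noise(np.ones(10), 0.0, 0)


class TestGenFid:
    def test_single_on_resonance_peak_decays_exponentially(self):
        fid = gen_fid([PeakSpec(4.7, 50.0)], 1024, sw_ppm=20.0)
        mag = np.abs(fid)
        ratio = mag[1:] / mag[:-1]
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-10)

    def test_spectral_fwhm_matches_requested(self):
        n = 16384
        fwhm_hz = 200.0
        fid = gen_fid([PeakSpec(10.0, fwhm_hz)], n, sw_ppm=50.0, field_T=14.1)
        # phased absorption lineshape: the real channel
        spec = np.fft.fftshift(np.fft.fft(fid)).real
        half = spec.max() / 2
        above = np.where(spec >= half)[0]
        sw_hz = 50.0 * 42.577478461 * 14.1
        measured = (above[-1] - above[0] + 1) * sw_hz / n
        assert measured == pytest.approx(fwhm_hz, rel=0.05)

    def test_two_peaks_superpose_linearly(self):
        p1, p2 = PeakSpec(0.0, 40.0), PeakSpec(8.0, 90.0)
        both = gen_fid([p1, p2], 512, 30.0)
        separate = gen_fid([p1], 512, 30.0) + gen_fid([p2], 512, 30.0)
        np.testing.assert_allclose(both, separate, atol=1e-10)


class TestApplyDeadTime:
    def test_zero_alterations_is_identity(self):
        fid = gen_fid([PeakSpec(2.0, 50.0)], 256, 20.0)
        np.testing.assert_array_equal(apply_dead_time(fid, 0), fid)

    def test_single_point_gives_flat_offset(self):
        # zeroing one sample subtracts a constant from the spectrum
        fid = gen_fid([PeakSpec(2.0, 50.0)], 256, 20.0)
        delta = np.fft.fft(fid - apply_dead_time(fid, 1))
        np.testing.assert_allclose(delta, delta[0], atol=1e-9 * np.abs(delta[0]))

    def test_distortion_grows_with_dead_points(self):
        fid = gen_fid([PeakSpec(4.7, 25.0)], 4096, 50.0)
        clean = np.fft.fft(fid).real
        off_peak = np.abs(clean) < 0.01 * clean.max()

        def off_rms(n_alt):
            distorted = np.fft.fft(apply_dead_time(fid, n_alt)).real
            return np.sqrt(np.mean((distorted - clean)[off_peak] ** 2))

        assert off_rms(16) > off_rms(4)

    def test_scale_mode(self):
        fid = np.ones(16, complex)
        out = apply_dead_time(fid, 4, mode="scale", scale_factor=0.25)
        np.testing.assert_array_equal(out[:4], 0.25 * np.ones(4))
        np.testing.assert_array_equal(out[4:], fid[4:])

    def test_too_many_points_rejected(self):
        with pytest.raises(ValueError):
            apply_dead_time(np.ones(8, complex), 8)


class TestBuildBenchmark:
    def test_sbr_zero_has_no_peaks(self):
        inst = build_benchmark(BenchmarkSpec(sbr=0.0, snr=10, slope=0.3, seed=0))
        np.testing.assert_array_equal(inst.true_signal, 0.0)
        np.testing.assert_allclose(
            inst.spectrum, inst.true_baseline + (inst.spectrum - inst.true_baseline)
        )

    @pytest.mark.parametrize("sbr,slope", [(0.05, 0.1), (1.0, 1.0), (10.0, 0.3)])
    def test_sbr_contract(self, sbr, slope):
        inst = build_benchmark(BenchmarkSpec(sbr=sbr, snr=10, slope=slope, seed=1))
        ratio = inst.true_signal.max() / inst.true_baseline.max()
        assert ratio == pytest.approx(sbr, abs=1e-9)

    def test_rolling_with_zero_dead_points_is_flat(self):
        inst = build_benchmark(
            BenchmarkSpec(sbr=1.0, snr=10, distortion="rolling", dead_points=0, seed=2)
        )
        np.testing.assert_allclose(inst.true_baseline, 1.0, atol=1e-9)

    def test_construction_bookkeeping_is_exact(self):
        spec = BenchmarkSpec(sbr=1.0, snr=5, slope=0.3, seed=3)
        inst = build_benchmark(spec)
        noise = inst.spectrum - inst.true_signal - inst.true_baseline
        assert np.std(noise) == pytest.approx(inst.noise_sigma, rel=0.1)

    def test_seeded_reproducibility(self):
        spec = BenchmarkSpec(sbr=1.0, snr=5, slope=0.3, seed=9)
        a, b = build_benchmark(spec), build_benchmark(spec)
        np.testing.assert_array_equal(a.spectrum, b.spectrum)

    def test_extended_sw_grid_and_fom_region(self):
        inst = build_benchmark(BenchmarkSpec(sbr=1.0, snr=10, slope=0.3, sw_ppm=72, seed=4))
        assert inst.spectrum.size == round(1001 * 72 / 12)
        assert inst.fom_slice.stop - inst.fom_slice.start == 1001
        # peaks live inside the FoM block
        assert inst.true_signal[inst.fom_slice].max() == inst.true_signal.max()
        outside = inst.true_signal.copy()
        outside[inst.fom_slice] = 0.0
        assert outside.max() < 1e-3 * inst.true_signal.max()

    def test_inconsistent_spec_rejected(self):
        with pytest.raises(ValueError):
            BenchmarkSpec(sbr=1.0, snr=10, slope=0.3, distortion="rolling", seed=0)
        with pytest.raises(ValueError):
            BenchmarkSpec(sbr=1.0, snr=10, dead_points=4, distortion="asymmetric", seed=0)
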
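import numpy as np
import pytest

from pgti import (Histogram1D, distal_maximum, falloff_shift,
                  fit_gauss_conv_uniform, fwhm_to_rms, rms_to_fwhm,
                  subtract_flat_background, subtract_pgti_background)

from conftest import SEED


class TestFwhmRms:
    def test_known_pair(self):
        assert fwhm_to_rms(268.0) == pytest.approx(113.81, abs=0.05)
        assert rms_to_fwhm(113.81) == pytest.approx(268.0, abs=0.1)

    def test_roundtrip(self):
        assert rms_to_fwhm(fwhm_to_rms(100.0)) == pytest.approx(100.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fwhm_to_rms(-1.0)


class TestHistogram1D:
    def test_from_samples_binning(self):
        h = Histogram1D.from_samples([0.5, 1.5, 1.6], 1.0, window=(0.0, 3.0))
        assert len(h.counts) == 3
        assert h.total == 3.0
        assert h.counts[1] == 2.0

    def test_cumulative_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(SEED)
        h = Histogram1D.from_samples(rng.normal(0, 1, 1000), 0.2,
                                     window=(-4, 4))
        c = h.cumulative()
        assert c[0] == 0.0
        assert c[-1] == pytest.approx(1.0)
        assert np.all(np.diff(c) >= 0)

    def test_empty_cumulative_rejected(self):
        h = Histogram1D(np.array([0.0, 1.0]), np.array([0.0]))
        with pytest.raises(ValueError):
            h.cumulative()

    def test_edge_validation(self):
        with pytest.raises(ValueError):
            Histogram1D(np.array([0.0, 1.0, 0.5]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            Histogram1D(np.array([0.0, 1.0]), np.array([1.0, 2.0]))

    def test_io_roundtrip(self, tmp_path):
        rng = np.random.default_rng(SEED)
        h = Histogram1D.from_samples(rng.normal(0, 1, 500), 0.25,
                                     window=(-3, 3))
        path = tmp_path / "hist.tsv"
        h.write(path)
        back = Histogram1D.read(path)
        assert np.allclose(back.bin_edges, h.bin_edges)
        assert np.allclose(back.counts, h.counts)


class TestCtrFit:
    def test_recovers_gaussian_sigma(self):
        rng = np.random.default_rng(SEED)
        sigma, width = 113.8, 51.0
        t = rng.normal(0.0, sigma, 20000) + rng.uniform(-width / 2, width / 2,
                                                        20000)
        h = Histogram1D.from_samples(t, 20.0, window=(-600, 600))
        fit = fit_gauss_conv_uniform(h, uniform_width=width)
        assert fit.sigma == pytest.approx(sigma, rel=0.03)
        assert abs(fit.centroid) < 5.0
        assert fit.uncertainties["sigma"] > 0

    def test_too_few_bins_rejected(self):
        h = Histogram1D(np.linspace(0, 100, 6), np.array([1, 5, 9, 5, 1.0]))
        with pytest.raises(ValueError):
            fit_gauss_conv_uniform(h, uniform_width=51.0)


class TestBackgroundSubtraction:
    def test_flat_level_removed(self):
        rng = np.random.default_rng(SEED)
        t = rng.normal(500.0, 50.0, 5000)
        h = Histogram1D.from_samples(t, 10.0, window=(0, 1000))
        noisy = Histogram1D(h.bin_edges, h.counts + 7.0)
        sub, level = subtract_flat_background(noisy, (800.0, 1000.0))
        assert level == pytest.approx(7.0, abs=0.5)
        assert sub.counts[:20].mean() == pytest.approx(0.0, abs=1.0)

    def test_overlap_with_signal_rejected(self):
        h = Histogram1D(np.linspace(0, 10, 11), np.ones(10))
        with pytest.raises(ValueError):
            subtract_flat_background(h, (4.0, 6.0), signal_window=(0.0, 5.0))

    def test_template_amplitude_recovered(self):
        rng = np.random.default_rng(SEED)
        edges = np.linspace(0.0, 10.0, 41)
        template = np.exp(-np.linspace(0, 10, 40) / 4.0)
        template /= template.sum()
        signal = np.histogram(rng.normal(3.0, 0.7, 3000), bins=edges)[0]
        h = Histogram1D(edges, signal + 500.0 * template)
        sub, amp = subtract_pgti_background(h, template, (7.0, 10.0))
        assert amp == pytest.approx(500.0, rel=0.2)

    def test_template_shape_mismatch(self):
        h = Histogram1D(np.linspace(0, 10, 11), np.ones(10))
        with pytest.raises(ValueError):
            subtract_pgti_background(h, np.ones(5), (7.0, 10.0))


class TestFalloffShift:
    @staticmethod
    def _asym_profile(rng, n, shift=0.0):
        # plateau with a sharp distal fall-off, PG-profile-like
        u = rng.random(n)
        x = 10.0 * np.sqrt(u)  # rising density up to the edge at 10
        return x + shift

    def test_distal_maximum_location(self):
        rng = np.random.default_rng(SEED)
        h = Histogram1D.from_samples(self._asym_profile(rng, 50000), 0.25,
                                     window=(0, 12))
        assert 9.0 < distal_maximum(h) < 10.2

    def test_translation_recovered_within_one_bin(self):
        rng = np.random.default_rng(SEED)
        ref = Histogram1D.from_samples(self._asym_profile(rng, 100000), 0.25,
                                       window=(0, 14))
        for shift in (0.5, 1.0, 2.0):
            prof = Histogram1D.from_samples(
                self._asym_profile(rng, 100000, shift), 0.25, window=(0, 14))
            d = falloff_shift(prof, ref).d
            assert d == pytest.approx(shift, abs=0.25)

    def test_identical_profiles_give_zero(self):
        rng = np.random.default_rng(SEED)
        x = self._asym_profile(rng, 50000)
        ref = Histogram1D.from_samples(x, 0.25, window=(0, 12))
        assert falloff_shift(ref, ref).d == pytest.approx(0.0, abs=1e-12)

    def test_count_independence(self):
        # the statistic works on normalized cumulatives: scaling counts is a no-op
        rng = np.random.default_rng(SEED)
        ref = Histogram1D.from_samples(self._asym_profile(rng, 50000), 0.25,
                                       window=(0, 12))
        scaled = Histogram1D(ref.bin_edges, ref.counts * 37.0)
        assert falloff_shift(scaled, ref).d == pytest.approx(0.0, abs=1e-9)

    def test_x_ref_outside_support_rejected(self):
        h = Histogram1D(np.linspace(0, 10, 11), np.ones(10))
        with pytest.raises(ValueError):
            falloff_shift(h, h, x_ref=50.0)
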
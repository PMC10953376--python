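"""Spectral-FWHM defocus metric: oracle values, invariances, edge cases."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import duofocus as df
from duofocus.metrics import _profile_fwhm, _profile_std


def gaussian_profile(sigma: float, n: int = 256) -> np.ndarray:
    x = np.arange(n) - (n - 1) / 2
    return np.exp(-x * x / (2.0 * sigma * sigma))


def dense_dft_fwhm(profile: np.ndarray, pad: int = 64) -> float:
    """Independent oracle: power-spectrum FWHM from a heavily zero-padded
    DFT of the raw profile, measured on the near-continuous spectrum."""
    n = profile.size
    spec = np.abs(np.fft.rfft(profile, n * pad)) ** 2
    half = spec[0] / 2.0
    k = np.flatnonzero(spec < half)[0]
    frac = (spec[k - 1] - half) / (spec[k - 1] - spec[k])
    return 2.0 * (k - 1 + frac) / pad


class TestPowerSpectrumFwhm:
    @pytest.mark.parametrize("sigma", [3.0, 5.0, 10.0, 20.0, 30.0])
    def test_matches_dense_dft_oracle(self, sigma):
        prof = gaussian_profile(sigma)
        oracle = dense_dft_fwhm(prof)
        assert df.power_spectrum_fwhm(prof) == pytest.approx(oracle, rel=0.02)

    def test_gaussian_sigma5_closed_form(self):
        # continuous-limit value N*sqrt(ln 2)/(pi*sigma) ~ 13.57 bins
        val = df.power_spectrum_fwhm(gaussian_profile(5.0))
        assert val == pytest.approx(256 * np.sqrt(np.log(2)) / (np.pi * 5.0),
                                    rel=0.03)

    def test_inverse_width_scaling(self):
        v5 = df.power_spectrum_fwhm(gaussian_profile(5.0))
        v10 = df.power_spectrum_fwhm(gaussian_profile(10.0))
        assert v10 == pytest.approx(v5 / 2.0, rel=0.02)

    def test_delta_profile_gives_maximal_width(self):
        prof = np.zeros(256)
        prof[100] = 1.0
        assert df.power_spectrum_fwhm(prof) == 2.0 * 128

    def test_all_zero_profile_invalid(self):
        with pytest.raises(df.InvalidMetricError):
            df.power_spectrum_fwhm(np.zeros(256))

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            df.power_spectrum_fwhm(np.ones(8))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3), sigma=st.floats(3.0, 25.0))
    def test_scale_invariance(self, scale, sigma):
        prof = gaussian_profile(sigma)
        assert df.power_spectrum_fwhm(scale * prof) == pytest.approx(
            df.power_spectrum_fwhm(prof), rel=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(shift=st.integers(-120, 120), sigma=st.floats(3.0, 25.0))
    def test_translation_invariance(self, shift, sigma):
        # the power spectrum discards phase, so beam displacement on the
        # sensor does not move the metric
        prof = gaussian_profile(sigma)
        assert df.power_spectrum_fwhm(np.roll(prof, shift)) == pytest.approx(
            df.power_spectrum_fwhm(prof), rel=1e-9)

    def test_pedestal_insensitivity(self):
        # mean subtraction keeps the half-max reference on the signal lobe
        prof = gaussian_profile(8.0)
        assert df.power_spectrum_fwhm(prof + 5.0) == pytest.approx(
            df.power_spectrum_fwhm(prof), rel=1e-9)


class TestProjections:
    def test_constant_image(self):
        pair = df.project(np.full((40, 60), 3.5))
        assert np.allclose(pair.proj_fast, 3.5)
        assert np.allclose(pair.proj_slow, 3.5)
        assert pair.proj_fast.size == 60
        assert pair.proj_slow.size == 40

    def test_separable_gaussian_projects_to_gaussians(self, mini_setup):
        img = df.expectation_image(10.0, mini_setup["beam"],
                                   mini_setup["camera"])
        sf, ss = df.spot_widths(10.0, mini_setup["beam"])
        pair = df.project(img)
        for proj, sigma in [(pair.proj_fast, sf), (pair.proj_slow, ss)]:
            x = np.arange(proj.size)
            mu = (proj * x).sum() / proj.sum()
            measured = np.sqrt((proj * (x - mu) ** 2).sum() / proj.sum())
            assert measured == pytest.approx(sigma, rel=0.02)

    def test_total_intensity_consistency(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 10, (48, 96))
        pair = df.project(img)
        assert pair.proj_fast.sum() * 48 == pytest.approx(
            pair.proj_slow.sum() * 96)


class TestSubtractBackground:
    def test_frame_equals_background_gives_zero(self, mini_setup):
        bg = mini_setup["background"]
        out = df.subtract_background(bg.pixels, bg)
        assert np.all(out == 0.0)

    def test_zero_background_identity(self):
        img = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(df.subtract_background(img, None), img)

    def test_mean_linearity_and_negatives_kept(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 50, (32, 32))
        bg = rng.uniform(0, 50, (32, 32))
        out = df.subtract_background(img, bg)
        assert out.mean() == pytest.approx(img.mean() - bg.mean())
        assert (out < 0).any()

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            df.subtract_background(np.zeros((8, 8)), np.ones((4, 4)))


class TestComputeMetrics:
    def test_metric_larger_closer_to_focus(self, mini_setup):
        vals = {}
        for z in (0.0, 20.0):
            f = df.render_frame(z, mini_setup["beam"], mini_setup["camera"],
                                mini_setup["background"], noise=False)
            vals[z] = df.compute_metrics(f, mini_setup["background"])
        assert vals[0.0].m_fast > vals[20.0].m_fast

    def test_slow_metric_peaks_at_focus_offset_not_zero(self, mini_calib):
        ipk = int(np.argmax(mini_calib.curve_slow))
        assert mini_calib.z_grid[ipk] == pytest.approx(2.0, abs=0.5)
        assert mini_calib.z_grid[int(np.argmax(mini_calib.curve_fast))] == \
            pytest.approx(0.0, abs=0.5)

    def test_pure_background_frame_invalid(self, mini_setup):
        bg = mini_setup["background"]
        with pytest.raises(df.InvalidMetricError):
            df.compute_metrics(bg.pixels, bg)

    def test_metric_tracks_inverse_spot_width(self, mini_setup):
        # spectral metric ~ 1/sigma for noiseless separable frames
        ratios = []
        for z in (0.0, 10.0, 20.0):
            f = df.render_frame(z, mini_setup["beam"], mini_setup["camera"],
                                None, noise=False)
            m = df.compute_metrics(f, None)
            sf, _ = df.spot_widths(z, mini_setup["beam"])
            ratios.append(m.m_fast * sf)
        assert np.ptp(ratios) / np.mean(ratios) < 0.03


class TestBaselineMetrics:
    def test_profile_fwhm_of_gaussian(self):
        assert _profile_fwhm(gaussian_profile(10.0)) == pytest.approx(
            2.355 * 10.0, rel=0.02)

    def test_profile_std_of_gaussian(self):
        assert _profile_std(gaussian_profile(10.0)) == pytest.approx(
            10.0, rel=0.05)

    def test_spectral_metric_displacement_robustness_vs_baseline(self):
        # rationale for the spectral choice: a clipped-at-the-edge displaced
        # spot distorts the spatial FWHM more than the spectral metric
        prof = gaussian_profile(10.0)
        shifted = np.roll(prof, 100)
        spectral_shift = abs(df.power_spectrum_fwhm(shifted)
                             - df.power_spectrum_fwhm(prof))
        assert spectral_shift < 1e-9
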
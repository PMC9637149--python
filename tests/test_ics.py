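"""Autocorrelation, G-curve extraction, Lorentzian fit, droplet counting."""

import numpy as np
import pytest

from ldics import ics, preprocess, synthetic
from ldics.errors import FitError
from ldics.images import HyphaMask, Image2D
from ldics.synthetic import NoiseModel

from conftest import small_spec


def brute_force_g(pixels):
    """Direct circular-shift fluctuation autocorrelation (test oracle)."""
    n = pixels.shape[0]
    mean = pixels.mean()
    delta = pixels - mean
    g = np.empty((n, n))
    for dy in range(n):
        for dx in range(n):
            rolled = np.roll(np.roll(delta, -dy, axis=0), -dx, axis=1)
            g[dy, dx] = (delta * rolled).mean() / mean ** 2
    return np.fft.fftshift(g)


class TestToPow2Square:
    def test_power_of_two_input_unchanged(self):
        img = Image2D(pixels=np.arange(64 * 64, dtype=float).reshape(64, 64),
                      pixel_size_um=0.1)
        out = ics.to_pow2_square(img)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_crop_center(self):
        pixels = np.zeros((1000, 900))
        pixels[244:756, 194:706] = 1.0  # the centered 512×512 block
        img = Image2D(pixels=pixels, pixel_size_um=0.1)
        out = ics.to_pow2_square(img, mode="crop_center")
        assert out.shape == (512, 512)
        assert np.all(out.pixels == 1.0)

    def test_pad_zero(self):
        img = Image2D(pixels=np.ones((300, 300)), pixel_size_um=0.1)
        out = ics.to_pow2_square(img, mode="pad_zero")
        assert out.shape == (512, 512)
        assert out.pixels.sum() == pytest.approx(300 * 300)
        assert out.pixels[256, 256] == 1.0


class TestAutocorrelate:
    def test_constant_image_gives_zero_surface(self):
        img = Image2D(pixels=np.full((32, 32), 5.0), pixel_size_um=0.1)
        surface = ics.autocorrelate(img)
        np.testing.assert_allclose(surface.g, 0.0, atol=1e-12)

    def test_all_zero_image_errors(self):
        img = Image2D(pixels=np.zeros((32, 32)), pixel_size_um=0.1)
        with pytest.raises(ValueError):
            ics.autocorrelate(img)

    def test_non_square_errors(self):
        img = Image2D(pixels=np.ones((32, 64)), pixel_size_um=0.1)
        with pytest.raises(ValueError):
            ics.autocorrelate(img)

    @pytest.mark.parametrize("n", [8, 16])
    def test_single_pixel_closed_form(self, n):
        pixels = np.zeros((n, n))
        pixels[2, 3] = 4.0
        surface = ics.autocorrelate(Image2D(pixels=pixels, pixel_size_um=0.1))
        assert surface.zero_lag == pytest.approx(n ** 2 - 1, rel=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            pixels = rng.uniform(0.5, 10.0, size=(16, 16))
            fast = ics.autocorrelate(
                Image2D(pixels=pixels, pixel_size_um=0.1)).g
            slow = brute_force_g(pixels)
            assert np.abs(fast - slow).max() <= 1e-10 * np.abs(slow).max()

    def test_invariant_under_intensity_scaling(self, rng):
        pixels = rng.uniform(1, 5, size=(32, 32))
        g1 = ics.autocorrelate(Image2D(pixels=pixels, pixel_size_um=0.1)).g
        g2 = ics.autocorrelate(Image2D(pixels=7.3 * pixels,
                                       pixel_size_um=0.1)).g
        np.testing.assert_allclose(g1, g2, atol=1e-12)

    def test_point_symmetry(self, rng):
        pixels = rng.uniform(0.5, 10.0, size=(32, 32))
        g = ics.autocorrelate(Image2D(pixels=pixels, pixel_size_um=0.1)).g
        # periodic point symmetry: g(ξ, η) = g(−ξ, −η)
        sym = np.roll(np.flip(g), (1, 1), axis=(0, 1))
        np.testing.assert_allclose(g, sym, atol=1e-12)


class TestExtractGCurve:
    @pytest.fixture()
    def surface(self):
        pixels = np.full((32, 32), 1.0)
        pixels[16, 16] = 21.0
        return ics.autocorrelate(Image2D(pixels=pixels, pixel_size_um=0.1))

    def test_maximum_at_zero_lag(self, surface):
        curve = ics.extract_g_curve(surface)
        assert curve.values.argmax() == np.where(curve.lags_pix == 0)[0][0]

    @pytest.mark.parametrize("mode", ["horizontal", "vertical"])
    def test_profile_symmetry(self, surface, mode):
        curve = ics.extract_g_curve(surface, mode=mode)
        center = np.where(curve.lags_pix == 0)[0][0]
        left = curve.values[1:center][::-1]   # lags −15…−1
        right = curve.values[center + 1: center + 1 + len(left)]
        np.testing.assert_allclose(left, right, atol=1e-12)

    def test_radial_mean_zero_lag(self, surface):
        curve = ics.extract_g_curve(surface, mode="radial_mean")
        center = np.where(curve.lags_pix == 0)[0][0]
        assert curve.values[center] == pytest.approx(surface.zero_lag)


class TestFitLorentzian:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(g0=st.floats(0.1, 100.0), w=st.floats(0.5, 8.0),
           offset=st.floats(-5.0, 5.0))
    def test_recovers_arbitrary_exact_lorentzians(self, g0, w, offset):
        lags = np.arange(-32, 33, dtype=float)
        values = g0 * w ** 2 / (lags ** 2 + w ** 2) + offset
        fit = ics.fit_lorentzian(ics.GCurve(lags_pix=lags, values=values,
                                            n_pix=64))
        assert fit.g0 == pytest.approx(g0, rel=1e-5, abs=1e-7)
        assert fit.w_pix == pytest.approx(w, rel=1e-5)
        assert fit.offset == pytest.approx(offset, rel=1e-4, abs=1e-6)

    def test_exact_samples_recovered(self):
        lags = np.arange(-20, 21, dtype=float)
        values = 2.0 * 9.0 / (lags ** 2 + 9.0)
        fit = ics.fit_lorentzian(ics.GCurve(lags_pix=lags, values=values,
                                            n_pix=64))
        assert fit.g0 == pytest.approx(2.0, abs=1e-8)
        assert fit.w_pix == pytest.approx(3.0, abs=1e-8)
        assert fit.offset == pytest.approx(0.0, abs=1e-8)
        assert fit.fwhm_pix == pytest.approx(6.0, abs=1e-8)
        assert fit.r_pix == fit.w_pix

    def test_offset_shift_invariance(self):
        lags = np.arange(-20, 21, dtype=float)
        values = 2.0 * 9.0 / (lags ** 2 + 9.0) + 0.5
        fit = ics.fit_lorentzian(ics.GCurve(lags_pix=lags, values=values,
                                            n_pix=64))
        assert fit.g0 == pytest.approx(2.0, abs=1e-8)
        assert fit.w_pix == pytest.approx(3.0, abs=1e-8)
        assert fit.offset == pytest.approx(0.5, abs=1e-8)

    def test_zero_lag_spike_excluded(self):
        lags = np.arange(-20, 21, dtype=float)
        values = 2.0 * 9.0 / (lags ** 2 + 9.0)
        values[20] += 50.0  # shot-noise spike at ξ = 0
        fit = ics.fit_lorentzian(ics.GCurve(lags_pix=lags, values=values,
                                            n_pix=64), exclude_zero_lag=True)
        assert fit.g0 == pytest.approx(2.0, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ics.fit_lorentzian(ics.GCurve(lags_pix=np.arange(3.0),
                                          values=np.ones(3)))

    def test_single_droplet_width_tracks_diameter(self):
        # one droplet of known diameter: fitted FWHM within ±30% of the
        # PSF-broadened diameter in pixels
        spec = small_spec(n_droplets=1, diameter_mean_um=1.0,
                          diameter_sd_um=1e-6, wall_peak=1e-9,
                          background_level=0.0,
                          noise_model=NoiseModel.none(), seed=2)
        image, truth = synthetic.generate_hypha_image(spec)
        _, params, _ = ics.quantify(image, truth.hypha_mask)
        d_pix = truth.droplet_diameters_um[0] / spec.pixel_size_um
        psf_fwhm_pix = 2.355 * spec.psf_sigma_um / spec.pixel_size_um
        expected = np.hypot(d_pix, psf_fwhm_pix)
        assert params.fwhm_pix == pytest.approx(expected, rel=0.3)


class TestCountLds:
    @pytest.fixture()
    def unit_mask(self):
        return HyphaMask(mask=np.ones((16, 16), dtype=bool), pixel_size_um=1.0)

    @pytest.mark.parametrize("n_pix,r,g0,expected", [
        (128, 2.0, 1.0, 128 ** 2 / (4 * np.pi)),
        (256, 4.0, 0.5, 256 ** 2 / (16 * np.pi * 0.5)),
        (64, 1.5, 2.0, 64 ** 2 / (1.5 ** 2 * np.pi * 2.0)),
    ])
    def test_formula(self, unit_mask, n_pix, r, g0, expected):
        params = ics.LorentzianParams(g0=g0, w_pix=r, offset=0.0)
        result = ics.count_lds(params, n_pix, unit_mask, pixel_size_um=0.1)
        assert result.n_ld == pytest.approx(expected, rel=1e-12)
        assert result.density_per_um2 == pytest.approx(
            expected / unit_mask.area_um2, rel=1e-12)
        assert result.mean_diameter_um == pytest.approx(2 * r * 0.1, rel=1e-12)

    def test_non_positive_amplitude_rejected(self, unit_mask):
        params = ics.LorentzianParams(g0=0.0, w_pix=2.0, offset=0.0)
        with pytest.raises(ValueError):
            ics.count_lds(params, 64, unit_mask, pixel_size_um=0.1)


class TestEstimatorProperties:
    def test_g0_halves_when_droplet_count_doubles(self):
        # fitted amplitude scales ≈ 1/N for sparse identical droplets
        ratios = []
        for seed in range(10):
            g0s = []
            for n in (50, 100):
                spec = small_spec(image_size_pix=512, hypha_length_um=40,
                                  hypha_width_um=8, n_droplets=n,
                                  diameter_sd_um=0.05, seed=500 + seed)
                image, truth = synthetic.generate_hypha_image(spec)
                sub = preprocess.subtract_background(image, truth.hypha_mask, 20)
                cleared = preprocess.clear_outside(sub, truth.hypha_mask)
                _, params, _ = ics.quantify(cleared, truth.hypha_mask)
                g0s.append(params.g0)
            ratios.append(g0s[1] / g0s[0])
        assert 0.4 <= float(np.median(ratios)) <= 0.6

    def test_estimated_diameter_monotone_in_true_diameter(self):
        medians = []
        for diameter in (0.9, 0.7, 0.5):
            estimates = []
            for seed in range(5):
                spec = small_spec(image_size_pix=512, hypha_length_um=40,
                                  hypha_width_um=8, n_droplets=20,
                                  diameter_mean_um=diameter,
                                  diameter_sd_um=0.05, seed=700 + seed)
                image, truth = synthetic.generate_hypha_image(spec)
                sub = preprocess.subtract_background(image, truth.hypha_mask, 20)
                cleared = preprocess.clear_outside(sub, truth.hypha_mask)
                result, _, _ = ics.quantify(cleared, truth.hypha_mask)
                estimates.append(result.mean_diameter_um)
            medians.append(float(np.median(estimates)))
        assert medians[0] > medians[1] > medians[2]
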
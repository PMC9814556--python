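import numpy as np
import pytest

from chromspect.io import ReferenceSpectrum, SpectralChromatogram, ValidationError
from chromspect.preprocess import (
    ChannelChromatogram,
    compute_absorbance,
    detect_peaks,
    extract_channel,
    first_derivative,
    resample_to_grid,
    savgol_smooth,
)
from chromspect.synthetic import SimulationConfig, SpeciesSpec, make_library, simulate_chromatogram
from scipy.optimize import curve_fit


class TestAbsorbance:
    @pytest.mark.parametrize(
        "i, i0, dark, expected",
        [
            (np.full(4, 500.0), np.full(4, 500.0), 0.0, 0.0),   # I = I0 → A = 0
            (np.full(4, 50.0), np.full(4, 500.0), 0.0, 1.0),    # tenfold attenuation
            (np.full(4, 190.0), np.full(4, 1000.0), 100.0, 1.0),  # −log10(90/900)
        ],
    )
    def test_known_values(self, i, i0, dark, expected):
        np.testing.assert_allclose(compute_absorbance(i, i0, dark), expected, atol=1e-12)

    def test_blank_below_dark_rejected(self):
        with pytest.raises(ValidationError, match="blank"):
            compute_absorbance(np.ones(3), np.full(3, 5.0), 10.0)

    def test_opaque_channel_clipped_to_amax(self):
        a = compute_absorbance(np.array([0.0, 100.0]), np.array([100.0, 100.0]), 0.0, a_max=4.0)
        assert a[0] == 4.0


class TestResample:
    def test_on_grid_values_unchanged(self):
        wl = np.linspace(200, 300, 101)
        s = ReferenceSpectrum("x", wl, np.sin(wl / 10) ** 2)
        vals, valid = resample_to_grid(s, wl)
        assert valid.all()
        np.testing.assert_allclose(vals, s.absorbance)

    def test_linear_ramp_exact(self):
        wl = np.linspace(200, 300, 26)
        s = ReferenceSpectrum("x", wl, 0.01 * wl)
        grid = np.linspace(210.3, 290.7, 57)
        vals, valid = resample_to_grid(s, grid)
        np.testing.assert_allclose(vals[valid], 0.01 * grid[valid], atol=1e-12)

    def test_outside_support_flagged_missing(self):
        wl = np.linspace(200, 450, 120)
        s = ReferenceSpectrum("x", wl, np.ones_like(wl))
        grid = np.linspace(180, 890, 200)
        vals, valid = resample_to_grid(s, grid)
        assert np.isnan(vals[~valid]).all()
        assert ((grid[~valid] < 200) | (grid[~valid] > 450)).all()

    def test_no_overlap_rejected(self):
        wl = np.linspace(200, 250, 30)
        s = ReferenceSpectrum("x", wl, np.ones_like(wl))
        with pytest.raises(ValidationError):
            resample_to_grid(s, np.linspace(500, 600, 10))


class TestSavgol:
    def test_exact_on_degree_4_polynomial(self):
        x = np.linspace(0, 20, 200)
        y = 1 + 0.5 * x - 0.2 * x**2 + 0.01 * x**3 + 0.001 * x**4
        out = savgol_smooth(y, grid_step=x[1] - x[0])
        np.testing.assert_allclose(out, y, atol=1e-9)

    def test_constant_unchanged(self):
        out = savgol_smooth(np.full(100, 3.7), grid_step=1.0)
        np.testing.assert_allclose(out, 3.7, atol=1e-12)

    def test_noise_variance_reduced(self, rng):
        noise = rng.normal(0, 1.0, 2000)
        out = savgol_smooth(noise, grid_step=1.0)
        assert out.std() < noise.std()

    def test_window_too_small_for_order(self):
        with pytest.raises(ValidationError, match="order 5"):
            savgol_smooth(np.ones(50), grid_step=3.0)  # window length 5 <= order 5


class TestDerivative:
    def test_constant_gives_zero(self):
        g = np.linspace(200, 300, 50)
        np.testing.assert_allclose(first_derivative(np.full(50, 2.0), g), 0.0, atol=1e-12)

    def test_offset_cancelled(self, rng):
        g = np.linspace(200, 300, 80)
        s = rng.normal(size=80)
        np.testing.assert_allclose(
            first_derivative(s, g), first_derivative(s + 0.3, g), atol=1e-12
        )

    def test_quadratic_closed_form(self):
        g = np.arange(0.0, 30.0)
        d = first_derivative(g**2, g)
        np.testing.assert_allclose(d[1:-1], 2 * g[1:-1], atol=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            first_derivative(np.ones(2), np.arange(2.0))


class TestExtractChannel:
    def make(self):
        lib = make_library(2, seed=0)
        cfg = SimulationConfig(
            species=[SpeciesSpec(lib.species[0], 5.0, 0.1, 1.0)],
            time_start=4.0,
            time_stop=6.0,
        )
        return simulate_chromatogram(cfg, lib)

    def test_zero_halfwindow_selects_single_column(self):
        chrom, _ = self.make()
        ch = extract_channel(chrom, 250.0, 0.0)
        j = int(np.where(chrom.wavelength == 250.0)[0][0])
        np.testing.assert_array_equal(ch.absorbance, chrom.absorbance[:, j])

    def test_constant_matrix_gives_constant_channel(self):
        chrom = SpectralChromatogram(
            np.arange(20.0), 200 + np.arange(30.0), np.full((20, 30), 1.5)
        )
        ch = extract_channel(chrom, 215.0, 2.0)
        np.testing.assert_allclose(ch.absorbance, 1.5)

    def test_noise_free_channel_recovers_rt(self):
        chrom, truth = self.make()
        S = truth["S"]
        j = int(np.argmax(S[:, 0]))
        ch = extract_channel(chrom, float(chrom.wavelength[j]), 2.0)
        gauss = lambda t, a, mu, sg: a * np.exp(-0.5 * ((t - mu) / sg) ** 2)
        popt, _ = curve_fit(gauss, ch.time, ch.absorbance, p0=[1.0, 5.05, 0.2])
        assert popt[1] == pytest.approx(5.0, abs=1e-6)

    def test_commutes_with_time_cropping(self):
        chrom, _ = self.make()
        a = extract_channel(chrom.crop_time(4.5, 5.5), 250.0, 2.0)
        b = extract_channel(chrom, 250.0, 2.0).crop(4.5, 5.5)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)

    def test_empty_window_rejected(self):
        chrom, _ = self.make()
        with pytest.raises(ValidationError):
            extract_channel(chrom, 600.0, 2.0)


def gaussian_channel(rts, sigmas, amps, noise=0.0, offset=0.0, seed=0):
    t = np.arange(0.0, 10.0, 0.005)
    y = offset + sum(
        a * np.exp(-0.5 * ((t - mu) / sg) ** 2) for a, mu, sg in zip(amps, rts, sigmas)
    )
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, t.size)
    return ChannelChromatogram(t, y, 230.0, 2.0)


class TestDetectPeaks:
    def test_flat_trace_empty(self):
        ch = ChannelChromatogram(np.arange(100.0), np.zeros(100), 230.0, 2.0)
        assert detect_peaks(ch) == []

    def test_single_gaussian_flank_times_closed_form(self):
        # exp(−x²/2σ²) = 0.1 at x = σ·sqrt(2 ln 10)
        ch = gaussian_channel([5.0], [0.1], [1.0])
        peaks = detect_peaks(ch)
        assert len(peaks) == 1
        p = peaks[0]
        half = 0.1 * np.sqrt(2 * np.log(10))
        assert p.apex_time == pytest.approx(5.0, abs=0.005)
        assert p.rise_time_10pct == pytest.approx(5.0 - half, abs=0.01)
        assert p.trail_time_10pct == pytest.approx(5.0 + half, abs=0.01)

    def test_two_distant_gaussians_found(self):
        ch = gaussian_channel([4.0, 5.0], [0.1, 0.1], [1.0, 0.7], noise=0.005)
        peaks = detect_peaks(ch, min_separation_min=0.2)
        assert [round(p.apex_time, 1) for p in peaks] == [4.0, 5.0]

    def test_constant_offset_invariance(self):
        a = detect_peaks(gaussian_channel([5.0], [0.1], [1.0], noise=0.004, seed=3))
        b = detect_peaks(
            gaussian_channel([5.0], [0.1], [1.0], noise=0.004, offset=2.0, seed=3)
        )
        assert len(a) == len(b) == 1
        assert a[0].rise_time_10pct == pytest.approx(b[0].rise_time_10pct, abs=1e-9)
        assert a[0].trail_time_10pct == pytest.approx(b[0].trail_time_10pct, abs=1e-9)

    def test_short_trace_rejected(self):
        with pytest.raises(ValidationError):
            detect_peaks(ChannelChromatogram(np.arange(5.0), np.zeros(5), 230.0, 2.0))
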
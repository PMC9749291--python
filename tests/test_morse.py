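import numpy as np
import pytest

from ctgmorse import (
    MorseParams,
    Segment,
    Stage,
    build_filterbank,
    cwt,
    demodulate_skewness,
    morse_psi_hat,
    normalizing_constant,
    peak_frequency,
    render_scalogram,
    ridge_frequency,
)
from ctgmorse.morse import frequency_std, png_bytes

AIRY60 = MorseParams(gamma=3.0, P2=60.0)


def brute_force_peak(params, lo=1e-3, hi=50.0, n=500001):
    """Independent argmax of w**beta * exp(-w**gamma) on a dense grid."""
    w = np.linspace(lo, hi, n)
    y = params.beta * np.log(w) - w ** params.gamma
    return w[np.argmax(y)]


def half_power_bandwidth(params, n=400001):
    """Width of the band where the filter exceeds peak/sqrt(2)."""
    wp = peak_frequency(params)
    w = np.linspace(1e-4, 4 * wp, n)
    y = morse_psi_hat(w, params)
    above = w[y >= y.max() / np.sqrt(2.0)]
    return above[-1] - above[0]


class TestWaveletDefinition:
    def test_zero_at_nonpositive_frequencies(self):
        assert morse_psi_hat(-1.0, AIRY60) == 0.0
        assert morse_psi_hat(0.0, AIRY60) == 0.0
        vals = morse_psi_hat(np.array([-2.0, -0.5, 0.0, 0.5]), AIRY60)
        assert np.all(vals[:3] == 0.0) and vals[3] > 0.0

    @pytest.mark.parametrize(
        "params",
        [AIRY60, MorseParams(3, 55), MorseParams.from_beta(1, 20), MorseParams(2, 8)],
    )
    def test_peak_matches_brute_force(self, params):
        assert peak_frequency(params) == pytest.approx(
            brute_force_peak(params), abs=2e-4
        )

    @pytest.mark.parametrize(
        "params", [AIRY60, MorseParams(3, 55), MorseParams.from_beta(1, 20)]
    )
    def test_peak_value_is_two(self, params):
        assert morse_psi_hat(peak_frequency(params), params) == pytest.approx(
            2.0, abs=1e-9
        )

    def test_normalizing_constant_closed_form(self):
        assert normalizing_constant(MorseParams.from_beta(3, 1)) == pytest.approx(
            2.0 * (3 * np.e) ** (1 / 3)
        )
        assert normalizing_constant(MorseParams.from_beta(1, 1)) == pytest.approx(
            2.0 * np.e
        )

    def test_peak_monotone_in_beta(self):
        peaks = [
            peak_frequency(MorseParams.from_beta(3, b)) for b in (5, 10, 20, 40)
        ]
        assert np.all(np.diff(peaks) > 0)

    def test_gamma_one_is_cauchy_shape(self):
        params = MorseParams.from_beta(1, 5)
        w = np.linspace(0.5, 10, 50)
        ratio = morse_psi_hat(w, params) / (w ** 5 * np.exp(-w))
        assert np.allclose(ratio, ratio[0])


class TestDemodulateSkewness:
    @pytest.mark.parametrize("P2", [55.0, 60.0])
    def test_zero_at_gamma_three(self, P2):
        assert abs(demodulate_skewness(MorseParams(3.0, P2))) < 1e-6

    def test_nonzero_for_cauchy_family(self):
        params = MorseParams.from_beta(1.0, 20.0)
        skew = demodulate_skewness(params)
        # analytic cumulant oracle: L'''(wp)/(-L''(wp))**1.5 with
        # L'''(wp) = beta*(2-(g-1)(g-2))/wp**3 and -L''(wp) = beta*g/wp**2
        wp = peak_frequency(params)
        b, g = params.beta, params.gamma
        exact = (b * (2 - (g - 1) * (g - 2)) / wp ** 3) / (b * g / wp ** 2) ** 1.5
        assert skew == pytest.approx(exact, rel=1e-4)
        assert abs(skew) > 0.1


class TestFilterBank:
    def test_analyticity_of_rows(self):
        bank = build_filterbank(4800, 4.0, AIRY60)
        omega = 2 * np.pi * np.fft.fftfreq(4800)
        assert np.all(bank.psi_hat[:, omega <= 0] == 0.0)
        assert np.all(bank.psi_hat >= 0.0)

    def test_voice_grid_geometry(self):
        bank = build_filterbank(4800, 4.0, AIRY60)
        ratios = bank.center_frequencies[:-1] / bank.center_frequencies[1:]
        assert np.allclose(ratios, 2 ** (1 / 12), atol=1e-12)
        scale_ratios = bank.scales[1:] / bank.scales[:-1]
        assert np.allclose(scale_ratios, 2 ** (1 / 12), atol=1e-12)

    def test_grid_endpoints_follow_contract(self):
        # top endpoint depends only on the wavelet parameters; the bottom
        # tracks the signal length (4 P / n rad per sample, up to one voice)
        P = AIRY60.P
        for n in (4800, 3600):
            bank = build_filterbank(n, 4.0, AIRY60)
            w_top = 2 * np.pi * bank.center_frequencies[0] / 4.0
            assert w_top == pytest.approx(np.pi / (1 + 2 / P))
            w_bot = 2 * np.pi * bank.center_frequencies[-1] / 4.0
            w_lo = 4 * P / n
            assert w_lo <= w_bot < w_lo * 2 ** (1 / 12)

    def test_bandwidth_decreases_with_p2(self):
        widths = [half_power_bandwidth(MorseParams(3.0, p2)) for p2 in (4, 60, 120)]
        assert widths[0] > widths[1] > widths[2]

    def test_too_short_signal(self):
        with pytest.raises(ValueError):
            build_filterbank(8, 4.0, AIRY60)


@pytest.fixture(scope="module")
def bank():
    return build_filterbank(4800, 4.0, AIRY60)


class TestCWT:

    def test_tone_ridge_within_one_voice(self, bank):
        t = np.arange(4800) / 4.0
        for f0 in (0.2, 0.5, 1.0):
            scal = cwt(np.sin(2 * np.pi * f0 * t), bank)
            fr = ridge_frequency(scal)
            assert abs(np.log2(fr / f0)) <= 1 / 12 + 1e-9

    def test_constant_signal_is_silent(self, bank):
        scal = cwt(np.full(4800, 137.0), bank)
        assert scal.magnitude.max() < 1e-9

    def test_two_tone_ridges(self, bank):
        t = np.arange(4800) / 4.0
        x = np.sin(2 * np.pi * 0.2 * t) + np.sin(2 * np.pi * 1.0 * t)
        scal = cwt(x, bank)
        profile = scal.magnitude[:, 1200:3600].mean(axis=1)
        rows = []
        for f0 in (0.2, 1.0):
            near = np.abs(np.log2(scal.freq_axis / f0)) <= 2 / 12
            rows.append(int(np.flatnonzero(near)[np.argmax(profile[near])]))
        # both ridge rows are local maxima of the scale profile
        for r in rows:
            assert profile[r] >= profile[r - 1] and profile[r] >= profile[r + 1]

    def test_linearity_of_magnitude(self, bank):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4800)
        m1 = cwt(x, bank).magnitude
        m2 = cwt(3.5 * x, bank).magnitude
        np.testing.assert_allclose(m2, 3.5 * m1, rtol=1e-9, atol=1e-12)

    def test_length_mismatch(self, bank):
        with pytest.raises(ValueError):
            cwt(np.ones(1000), bank)


@pytest.fixture(scope="module")
def scal():
    small_bank = build_filterbank(3600, 4.0, AIRY60)
    t = np.arange(3600) / 4.0
    x = np.sin(2 * np.pi * 0.4 * t) * np.exp(-((t - 450) ** 2) / 2e4)
    return cwt(x, small_bank)


class TestRendering:

    def test_image_contract(self, scal):
        img = render_scalogram(scal)
        assert img.shape == (224, 224, 3) and img.dtype == np.uint8

    def test_min_max_normalization_invariance(self, scal):
        from dataclasses import replace

        img1 = render_scalogram(scal)
        scaled = replace(scal, magnitude=scal.magnitude * 41.7)
        img2 = render_scalogram(scaled)
        np.testing.assert_array_equal(img1, img2)

    def test_byte_identical_png_across_runs(self, scal):
        assert png_bytes(render_scalogram(scal)) == png_bytes(render_scalogram(scal))

    def test_flat_magnitude_renders_uniform(self, scal):
        from dataclasses import replace

        flat = replace(scal, magnitude=np.zeros_like(scal.magnitude))
        img = render_scalogram(flat)
        assert (img == img[0, 0]).all()


def test_frequency_std_matches_gaussian_fit():
    # the log-filter's curvature at the peak implies std wp / P
    params = AIRY60
    wp = peak_frequency(params)
    h = 1e-4
    w = np.array([wp - h, wp, wp + h])
    L = np.log(morse_psi_hat(w, params))
    curv = (L[0] - 2 * L[1] + L[2]) / h ** 2
    assert np.sqrt(-1 / curv) == pytest.approx(frequency_std(params), rel=1e-4)
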
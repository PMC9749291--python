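"""Generalized Morse wavelets, the CWT filter bank, and scalogram images.

The generalized Morse wavelet is the exactly analytic two-parameter family
defined in the frequency domain by

    psi_hat(omega) = U(omega) * alpha * omega**beta * exp(-omega**gamma)

where U is the unit step (so there is no negative-frequency leakage at all),
gamma controls the wavelet's time-domain symmetry and beta its decay; the
time-bandwidth product is P**2 = gamma * beta.  gamma = 1 gives the Cauchy
family, gamma = 2 the analytic derivative-of-Gaussian family, and gamma = 3
the "Airy" family — the most symmetric members, with zero demodulate
skewness and minimal Heisenberg area — which is the setting used for FHR
time-frequency representation here (with P**2 of 55 or 60).

The filter bank evaluates the wavelet on the FFT frequency grid of the
signal over a geometric scale ladder (12 voices per octave by default).
The transform is FFT-based (periodic boundary), the signal mean is removed
first, and the scalogram magnitude can be rendered to a fixed-size 8-bit
RGB image for an image classifier (default 224 x 224 x 3, "jet" colormap).

Normalisation convention: alpha = 2 * (e * gamma / beta)**(beta / gamma),
which sets the filter's peak value to exactly 2 so that a unit-amplitude
real tone at a filter's center frequency yields unit coefficient magnitude.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import matplotlib
import numpy as np
from PIL import Image

from .preprocess import Segment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MorseParams:
    """Generalized Morse wavelet parameters (gamma, P**2)."""

    gamma: float = 3.0
    P2: float = 60.0

    def __post_init__(self) -> None:
        if not (self.gamma > 0 and self.P2 > 0):
            raise ValueError("gamma and P2 must be positive")

    @property
    def beta(self) -> float:
        """Decay/compactness parameter: beta = P**2 / gamma."""
        return self.P2 / self.gamma

    @property
    def P(self) -> float:
        """sqrt of the time-bandwidth product; the wavelet's duration factor."""
        return float(np.sqrt(self.P2))

    @classmethod
    def from_beta(cls, gamma: float, beta: float) -> "MorseParams":
        return cls(gamma=gamma, P2=gamma * beta)


def peak_frequency(params: MorseParams) -> float:
    """Angular frequency (rad/sample at unit scale) maximizing psi_hat."""
    return float((params.beta / params.gamma) ** (1.0 / params.gamma))


def normalizing_constant(params: MorseParams) -> float:
    """alpha such that psi_hat(peak_frequency) == 2."""
    b, g = params.beta, params.gamma
    return float(2.0 * (np.e * g / b) ** (b / g))


def morse_psi_hat(omega, params: MorseParams) -> np.ndarray | float:
    """Frequency-domain Morse wavelet: alpha * w**beta * exp(-w**gamma), 0 for w <= 0."""
    w = np.asarray(omega, dtype=float)
    scalar = w.ndim == 0
    w = np.atleast_1d(w)
    out = np.zeros_like(w)
    pos = w > 0
    b, g = params.beta, params.gamma
    log_alpha = np.log(2.0) + (b / g) * (1.0 + np.log(g) - np.log(b))
    with np.errstate(over="ignore", under="ignore"):
        out[pos] = np.exp(log_alpha + b * np.log(w[pos]) - w[pos] ** g)
    return float(out[0]) if scalar else out


def demodulate_skewness(params: MorseParams, rel_step: float = 5e-3) -> float:
    """Third standardized moment of the demodulated wavelet.

    Shifting the wavelet's spectrum down by its peak frequency makes
    psi_hat(peak + nu) (a non-negative, integrable bump) act as the
    characteristic function of the demodulated wavelet's time variable, so
    the time-domain cumulants are derivatives of log psi_hat at the peak:
    kappa2 = -L''(w_p) and Im(kappa3) = L'''(w_p) with L = log psi_hat.
    The skewness is the standardized imaginary third cumulant
    L'''(w_p) / (-L''(w_p))**1.5, computed here by Richardson-extrapolated
    central differences.  It vanishes identically at gamma = 3.
    """
    wp = peak_frequency(params)
    b, g = params.beta, params.gamma

    def L(w: np.ndarray) -> np.ndarray:
        return b * np.log(w) - w ** g

    def d3(h: float) -> float:
        pts = wp + h * np.array([-2.0, -1.0, 1.0, 2.0])
        v = L(pts)
        return float((v[3] - 2.0 * v[2] + 2.0 * v[1] - v[0]) / (2.0 * h ** 3))

    def d2(h: float) -> float:
        v = L(np.array([wp - h, wp, wp + h]))
        return float((v[0] - 2.0 * v[1] + v[2]) / h ** 2)

    h = rel_step * wp
    third = (4.0 * d3(h / 2.0) - d3(h)) / 3.0
    second = (4.0 * d2(h / 2.0) - d2(h)) / 3.0
    variance = -second
    return third / variance ** 1.5


def frequency_std(params: MorseParams) -> float:
    """Gaussian-approximation std of psi_hat around its peak: w_p / P."""
    return peak_frequency(params) / params.P


@dataclass
class MorseFilterBank:
    """Frequency-domain Morse filters on a geometric scale ladder.

    ``psi_hat`` has one row per scale, evaluated on the FFT angular-frequency
    grid of an ``n_samples`` transform; rows are exactly zero at non-positive
    frequencies.  ``center_frequencies`` are in Hz, descending.
    """

    params: MorseParams
    fs: float
    n_samples: int
    voices_per_octave: int
    scales: np.ndarray
    psi_hat: np.ndarray
    center_frequencies: np.ndarray


def build_filterbank(
    n_samples: int,
    fs: float = 4.0,
    params: MorseParams = MorseParams(),
    voices_per_octave: int = 12,
) -> MorseFilterBank:
    """Construct the CWT filter bank for signals of ``n_samples`` at ``fs``.

    The highest center frequency places the wavelet peak two frequency
    standard deviations below Nyquist (w_c * (1 + 2/P) = pi); the lowest is
    set so two time-domain standard deviations of the wavelet fit inside the
    signal on each side (w_c = 4 P / n_samples).  Centers descend
    geometrically with ratio 2**(1/voices_per_octave).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    wp = peak_frequency(params)
    P = params.P
    w_hi = np.pi / (1.0 + 2.0 / P)          # rad/sample
    w_lo = 4.0 * P / n_samples
    if w_hi <= w_lo:
        raise ValueError(
            f"signal of {n_samples} samples too short for P2={params.P2}"
        )
    n_voices = int(np.floor(voices_per_octave * np.log2(w_hi / w_lo))) + 1
    centers = w_hi * 2.0 ** (-np.arange(n_voices) / voices_per_octave)
    scales = wp / centers
    omega = 2.0 * np.pi * np.fft.fftfreq(n_samples)   # rad/sample, signed
    psi = np.empty((n_voices, n_samples))
    for k, s in enumerate(scales):
        psi[k] = morse_psi_hat(s * omega, params)
    return MorseFilterBank(
        params=params,
        fs=fs,
        n_samples=n_samples,
        voices_per_octave=voices_per_octave,
        scales=scales,
        psi_hat=psi,
        center_frequencies=centers * fs / (2.0 * np.pi),
    )


@dataclass
class Scalogram:
    """CWT magnitude over (scale x time), with physical axes."""

    magnitude: np.ndarray
    freq_axis: np.ndarray      # Hz, one per scale row, descending
    time_axis: np.ndarray      # seconds
    params: MorseParams = field(default_factory=MorseParams)


def cwt(segment: Segment | np.ndarray, bank: MorseFilterBank) -> Scalogram:
    """Continuous wavelet transform magnitude of one segment.

    The segment mean is removed, the transform is computed per scale as the
    inverse FFT of (signal spectrum x filter row), and |coefficients| is
    returned.  Boundary handling is periodic (FFT-native), so ridge
    measurements should avoid the outermost wavelet-width of samples.
    """
    x = segment.samples if isinstance(segment, Segment) else np.asarray(segment, float)
    if len(x) != bank.n_samples:
        raise ValueError(
            f"segment length {len(x)} != filter bank length {bank.n_samples}"
        )
    spectrum = np.fft.fft(x - x.mean())
    coeffs = np.fft.ifft(spectrum[None, :] * bank.psi_hat, axis=1)
    return Scalogram(
        magnitude=np.abs(coeffs),
        freq_axis=bank.center_frequencies.copy(),
        time_axis=np.arange(bank.n_samples) / bank.fs,
        params=bank.params,
    )


def render_scalogram(
    scal: Scalogram,
    size: tuple[int, int] = (224, 224),
    colormap: str = "jet",
) -> np.ndarray:
    """Render a scalogram as an H x W x 3 uint8 image.

    The magnitude is min-max normalized per image (so the rendering is
    invariant to positive rescaling of the signal), quantized through a
    256-level colormap, and bilinearly resized.  Row order puts the highest
    frequency at the top.
    """
    mag = scal.magnitude
    lo, hi = float(mag.min()), float(mag.max())
    if hi <= lo:
        logger.warning("flat scalogram magnitude; rendering uniform image")
        norm = np.zeros_like(mag)
    else:
        norm = (mag - lo) / (hi - lo)
    cmap = matplotlib.colormaps[colormap].resampled(256)
    levels = np.clip((norm * 255.0).round().astype(int), 0, 255)
    rgb = (cmap(levels)[..., :3] * 255.0).round().astype(np.uint8)
    h, w = size
    img = Image.fromarray(rgb).resize((w, h), Image.BILINEAR)
    return np.asarray(img)


def save_png(image: np.ndarray, path) -> None:
    Image.fromarray(image).save(path, format="PNG")


def png_bytes(image: np.ndarray) -> bytes:
    buf = io.BytesIO()
    Image.fromarray(image).save(buf, format="PNG")
    return buf.getvalue()


def ridge_frequency(scal: Scalogram, margin_fraction: float = 0.25) -> float:
    """Center frequency (Hz) of the scale row with maximal interior energy.

    The outer ``margin_fraction`` of the time axis on each side is excluded
    to avoid periodic-boundary artifacts.
    """
    n = scal.magnitude.shape[1]
    lo = int(n * margin_fraction)
    interior = scal.magnitude[:, lo : n - lo]
    row = int(np.argmax(interior.mean(axis=1)))
    return float(scal.freq_axis[row])
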
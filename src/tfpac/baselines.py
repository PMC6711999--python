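"""Reference PAC estimators: bandpass+Hilbert MVL and Morse-wavelet MVL.

These are the conventional pipelines the time-frequency estimator is
benchmarked against.  The Hilbert route bandpasses the signal around the
amplitude frequency with a proportional bandwidth (f_a +- 0.4 f_a) and
around the phase frequency with a narrow band (f_p +- 1 Hz), then reads
envelope and phase off the analytic signal.  The wavelet route uses
generalized Morse wavelets (beta=6, gamma=3), whose analytic transform
bandpasses with a bandwidth that scales with frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .pac import AmplitudeEnvelope, PACResult, PhaseSeries, pac_metric, settle_slice
from .signal import Signal

__all__ = [
    "HilbertPACConfig",
    "MorseWaveletConfig",
    "hilbert_bands",
    "hilbert_envelope_phase",
    "hilbert_mvl",
    "morse_peak_frequency",
    "morse_filterbank",
    "wavelet_transform",
    "wavelet_envelope_phase",
    "wavelet_mvl",
]


@dataclass(frozen=True)
class HilbertPACConfig:
    """Bandpass+Hilbert settings.

    ``filter_order`` is the Butterworth prototype order before the
    zero-phase forward-backward pass; ``fa_bw_factor`` sets the amplitude
    band ``f_a (1 +- factor)``; ``fp_halfwidth`` the phase band half-width.
    """

    filter_order: int = 4
    fa_bw_factor: float = 0.4
    fp_halfwidth: float = 1.0

    def __post_init__(self) -> None:
        if self.filter_order < 2:
            raise ValueError("filter_order must be >= 2")
        if not 0 < self.fa_bw_factor < 1:
            raise ValueError("fa_bw_factor must lie in (0, 1)")


@dataclass(frozen=True)
class MorseWaveletConfig:
    """Generalized Morse wavelet settings (beta, gamma and the scale grid)."""

    beta: float = 6.0
    gamma: float = 3.0
    n_scales: int = 120
    freq_range: tuple[float, float] = (2.0, 100.0)

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.gamma <= 0:
            raise ValueError("beta and gamma must be positive")
        if self.n_scales < 2:
            raise ValueError("need at least 2 scales")


# --------------------------------------------------------------------------
# Hilbert route


def hilbert_bands(f_p: float, f_a: float,
                  cfg: HilbertPACConfig) -> tuple[tuple[float, float], tuple[float, float]]:
    """(phase band, amplitude band) in Hz for the Hilbert pipeline."""
    return ((f_p - cfg.fp_halfwidth, f_p + cfg.fp_halfwidth),
            (f_a * (1 - cfg.fa_bw_factor), f_a * (1 + cfg.fa_bw_factor)))


def _bandpass(x: np.ndarray, band: tuple[float, float], fs: float, order: int) -> np.ndarray:
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band [{lo:g}, {hi:g}] Hz not designable at fs={fs:g} Hz")
    sos = butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def hilbert_envelope_phase(signal: Signal, f_p, f_a: float,
                           cfg: HilbertPACConfig | None = None,
                           trim: bool = True) -> tuple[AmplitudeEnvelope, PhaseSeries]:
    """Analytic-signal envelope and phase after zero-phase Butterworth bandpass.

    ``f_p`` may be a scalar (band f_p +- fp_halfwidth) or an explicit
    (lo, hi) band.
    """
    cfg = cfg or HilbertPACConfig()
    x = np.real(signal.samples)
    if np.isscalar(f_p):
        p_band, a_band = hilbert_bands(float(f_p), f_a, cfg)
        f_low = float(f_p)
    else:
        p_band = (float(f_p[0]), float(f_p[1]))
        a_band = hilbert_bands(np.mean(p_band), f_a, cfg)[1]
        f_low = float(np.mean(p_band))
    env = np.abs(hilbert(_bandpass(x, a_band, signal.fs, cfg.filter_order)))
    ph = np.angle(hilbert(_bandpass(x, p_band, signal.fs, cfg.filter_order)))
    sl = settle_slice(signal.n, signal.fs, f_low) if trim else slice(None)
    return (AmplitudeEnvelope(env[sl], a_band, signal.fs, "magnitude"),
            PhaseSeries(ph[sl], f_low, signal.fs))


def hilbert_mvl(signal: Signal, f_p, f_a: float,
                cfg: HilbertPACConfig | None = None, metric: str = "mvl") -> PACResult:
    """Conventional bandpass+Hilbert MVL (or PLV/MI) estimate."""
    env, ph = hilbert_envelope_phase(signal, f_p, f_a, cfg)
    return pac_metric(env, ph, metric=metric)


# --------------------------------------------------------------------------
# Morse wavelet route


def morse_peak_frequency(beta: float, gamma: float) -> float:
    """Peak radian frequency (beta/gamma)^(1/gamma) of the mother wavelet."""
    return (beta / gamma) ** (1.0 / gamma)


def morse_filterbank(n: int, fs: float, cfg: MorseWaveletConfig):
    """Frequency-domain Morse filters with bandpass (unit-peak) normalisation.

    Returns (centre_freqs_hz, filters) with one row per scale; centre
    frequencies are log-spaced over ``cfg.freq_range`` and each filter
    peaks (value 2, analytic convention) at its centre frequency.
    """
    lo, hi = cfg.freq_range
    if not 0 < lo < hi <= fs / 2:
        raise ValueError(f"freq_range {cfg.freq_range} not realisable at fs={fs}")
    centres = np.geomspace(lo, hi, cfg.n_scales)
    omega = 2.0 * np.pi * np.fft.fftfreq(n, d=1.0 / fs)
    wp = morse_peak_frequency(cfg.beta, cfg.gamma)
    filters = np.zeros((cfg.n_scales, n))
    for i, fc in enumerate(centres):
        s = wp / (2.0 * np.pi * fc)                       # scale: peak at fc
        w = s * omega
        pos = w > 0
        # log-form keeps w^beta e^{-w^gamma} stable; peak value (w = wp) is 2,
        # the analytic bandpass normalisation
        filters[i, pos] = 2.0 * np.exp(cfg.beta * np.log(w[pos] / wp)
                                       - (w[pos] ** cfg.gamma - wp ** cfg.gamma))
    return centres, filters


def wavelet_transform(signal: Signal, cfg: MorseWaveletConfig | None = None):
    """Analytic Morse wavelet coefficients, shape (n_scales, n)."""
    cfg = cfg or MorseWaveletConfig()
    x = np.real(signal.samples)
    centres, filters = morse_filterbank(signal.n, signal.fs, cfg)
    spec = np.fft.fft(x)
    coeffs = np.fft.ifft(spec[None, :] * filters, axis=1)
    return centres, coeffs


def _nearest_scale(centres: np.ndarray, f: float, what: str) -> int:
    if not centres.min() <= f <= centres.max():
        raise ValueError(
            f"{what}={f:g} Hz outside the realised scale range "
            f"[{centres.min():.2f}, {centres.max():.2f}] Hz")
    return int(np.argmin(np.abs(centres - f)))


def wavelet_envelope_phase(signal: Signal, f_p: float, f_a: float,
                           cfg: MorseWaveletConfig | None = None,
                           trim: bool = True) -> tuple[AmplitudeEnvelope, PhaseSeries]:
    """Envelope at the scale nearest f_a, phase at the scale nearest f_p."""
    cfg = cfg or MorseWaveletConfig()
    centres, coeffs = wavelet_transform(signal, cfg)
    ia = _nearest_scale(centres, f_a, "f_a")
    ip = _nearest_scale(centres, f_p, "f_p")
    env = np.abs(coeffs[ia])
    ph = np.angle(coeffs[ip])
    sl = settle_slice(signal.n, signal.fs, float(centres[ip])) if trim else slice(None)
    return (AmplitudeEnvelope(env[sl], (float(centres[ia]), float(centres[ia])),
                              signal.fs, "magnitude"),
            PhaseSeries(ph[sl], float(centres[ip]), signal.fs))


def wavelet_mvl(signal: Signal, f_p: float, f_a: float,
                cfg: MorseWaveletConfig | None = None, metric: str = "mvl") -> PACResult:
    """Generalized-Morse-wavelet MVL (or PLV/MI) estimate."""
    env, ph = wavelet_envelope_phase(signal, f_p, f_a, cfg)
    return pac_metric(env, ph, metric=metric)
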
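"""Synthetic phase-amplitude-coupled test signals.

Two generators emulate the standard simulation protocols of the PAC
methods literature:

* :func:`generate_coupled_sinusoids` — a slow sinusoid plus a fast
  sinusoid whose envelope is driven by the slow phase, with a tunable
  uncoupled fraction ``chi`` (coupling strength ``1 - chi``), optionally
  buried in pink + white background noise.
* :func:`generate_brownian_pac` — bandpass-filtered Brownian noise in a
  low and a high band, with monophasic coupling injected by multiplying
  the high-band series by DC-shifted Hanning windows centred on the
  relative maxima of the low-band series (Kramer–Eden construction).

Both generators are pure functions of their spec (including the seed),
and calibrate the additive noise so the realised SNR matches the request
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import argrelmax, butter, sosfiltfilt

from .signal import Signal

__all__ = [
    "SinusoidalPACSpec",
    "BrownianPACSpec",
    "generate_coupled_sinusoids",
    "sinusoidal_envelope",
    "add_composite_noise",
    "generate_dataset1",
    "generate_brownian_pac",
    "powerlaw_noise",
    "brownian_noise",
]


# --------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class SinusoidalPACSpec:
    """Parameters of the coupled-sinusoid generator.

    ``x(t) = K_fp sin(2 pi f_p t) + A(t) sin(2 pi f_a t) [+ noise]`` with
    ``A(t) = K_fa ((1 - chi) sin(2 pi f_p t - phi_c) + chi + 1) / 2``.
    ``chi`` is the uncoupled fraction of the fast envelope, so the coupling
    strength is ``1 - chi``.  ``phi_c`` is the slow phase at which the fast
    bursts peak.  ``snr_db=None`` means noise-free.
    """

    f_p: float = 5.0
    f_a: float = 70.0
    K_fp: float = 1.0
    K_fa: float = 1.0
    chi: float = 0.5
    phi_c: float = 0.0
    fs: float = 1000.0
    duration: float = 2.0
    snr_db: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.chi <= 1.0:
            raise ValueError(f"chi must lie in [0, 1], got {self.chi}")
        if not 0 < self.f_p < self.f_a:
            raise ValueError("need 0 < f_p < f_a")
        if self.f_a >= self.fs / 2:
            raise ValueError(
                f"f_a={self.f_a} Hz aliases at fs={self.fs} Hz (Nyquist {self.fs / 2})")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def coupling_strength(self) -> float:
        return 1.0 - self.chi


@dataclass(frozen=True)
class BrownianPACSpec:
    """Parameters of the Brownian-noise PAC generator.

    The low band supplies the phase signal, the high band the amplitude
    signal; ``intensity`` scales the DC-shifted Hanning gain (baseline 1,
    peak ``1 + intensity``) applied at each relative maximum of the phase
    signal.  ``window_ms`` is the Hanning window duration.
    """

    fp_band: tuple[float, float] = (8.0, 10.0)
    fa_band: tuple[float, float] = (50.0, 70.0)
    intensity: float = 0.9
    window_ms: float = 42.0
    fs: float = 1000.0
    duration: float = 10.0
    snr_db: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo_p, hi_p = self.fp_band
        lo_a, hi_a = self.fa_band
        if not (0 < lo_p < hi_p and 0 < lo_a < hi_a):
            raise ValueError("bands must be non-empty with positive increasing edges")
        if hi_p >= lo_a:
            raise ValueError(f"fp_band {self.fp_band} must lie entirely below fa_band {self.fa_band}")
        if hi_a >= self.fs / 2:
            raise ValueError(f"fa_band upper edge {hi_a} Hz at or above Nyquist {self.fs / 2} Hz")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError(f"intensity must lie in [0, 1], got {self.intensity}")
        # windows centred 1/hi_p apart at worst; longer windows overlap pathologically
        max_window_ms = 1000.0 / hi_p
        if self.window_ms > max_window_ms:
            raise ValueError(
                f"window_ms={self.window_ms} exceeds the mean inter-maximum interval "
                f"~{max_window_ms:.0f} ms implied by fp_band {self.fp_band}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


# --------------------------------------------------------------------------
# noise primitives


def powerlaw_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^beta noise via frequency-domain shaping of white noise."""
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n)
    spec[1:] /= f[1:] ** (beta / 2.0)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / x.std()


def brownian_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Brownian (red, beta=2) noise.

    Discrete Brownian motion: cumulative sum of white Gaussian steps,
    mean-removed and scaled to unit variance.  The log-periodogram slope
    is -2 over the analysis band (asserted by the test-suite).
    """
    b = np.cumsum(rng.standard_normal(n))
    b -= b.mean()
    std = b.std()
    return b / std if std > 0 else b


def _scale_to_snr(signal: np.ndarray, noise: np.ndarray, snr_db: float) -> np.ndarray:
    """Scale ``noise`` so 10 log10(P_signal / P_noise) equals ``snr_db`` exactly."""
    p_sig = np.mean(signal ** 2)
    p_noise = np.mean(noise ** 2)
    if p_noise == 0:
        raise ValueError("cannot scale all-zero noise")
    return noise * np.sqrt(p_sig / (10.0 ** (snr_db / 10.0) * p_noise))


# --------------------------------------------------------------------------
# generator 1: coupled sinusoids


def sinusoidal_envelope(spec: SinusoidalPACSpec, t: np.ndarray) -> np.ndarray:
    """Closed-form fast-component envelope A(t) of the coupled-sinusoid model."""
    return spec.K_fa * (
        (1.0 - spec.chi) * np.sin(2.0 * np.pi * spec.f_p * t - spec.phi_c)
        + spec.chi + 1.0) / 2.0


def generate_coupled_sinusoids(spec: SinusoidalPACSpec) -> Signal:
    """Noise-free coupled-sinusoid signal (slow tone + modulated fast tone)."""
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    x_p = spec.K_fp * np.sin(2.0 * np.pi * spec.f_p * t)
    x_a = sinusoidal_envelope(spec, t) * np.sin(2.0 * np.pi * spec.f_a * t)
    return Signal(x_p + x_a, fs=spec.fs)


def add_composite_noise(signal: Signal, snr_db: float, seed: int,
                        beta: float = 1.0) -> Signal:
    """Add power-law plus white Gaussian noise at an exact SNR.

    The composite noise is 1/f^beta "background activity" plus white
    "measurement" noise whose power is half the power-law component's
    power.  The mixture is then scaled so the measured SNR equals
    ``snr_db`` (the white/power-law 1:2 power ratio is preserved).
    """
    rng = np.random.default_rng(seed)
    n = signal.n
    coloured = powerlaw_noise(n, beta, rng)              # unit variance
    white = rng.standard_normal(n) * np.sqrt(0.5)        # half the coloured power
    eps = _scale_to_snr(np.real(signal.samples), coloured + white, snr_db)
    return replace(signal, samples=np.real(signal.samples) + eps)


def generate_dataset1(spec: SinusoidalPACSpec, noise_beta: float = 1.0) -> Signal:
    """Coupled sinusoids plus composite noise when ``spec.snr_db`` is set."""
    clean = generate_coupled_sinusoids(spec)
    if spec.snr_db is None:
        return clean
    return add_composite_noise(clean, spec.snr_db, seed=spec.seed, beta=noise_beta)


# --------------------------------------------------------------------------
# generator 2: Brownian noise with Hanning-window coupling


def _bandpass(x: np.ndarray, band: tuple[float, float], fs: float,
              order: int = 4) -> np.ndarray:
    sos = butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def generate_brownian_pac(spec: BrownianPACSpec) -> Signal:
    """Brownian-noise PAC signal with Hanning-window monophasic coupling.

    Procedure: draw Brownian noise; bandpass it at ``fp_band`` (phase
    signal) and at ``fa_band`` (amplitude signal); find the relative
    maxima of the phase signal; at each maximum multiply the amplitude
    series by ``1 + intensity * hanning(window_ms)`` (overlapping windows
    combine multiplicatively); sum the two series; finally add an
    independently drawn band-matched Brownian noise at ``spec.snr_db``.
    """
    n = int(round(spec.duration * spec.fs))
    rng = np.random.default_rng(spec.seed)
    raw = brownian_noise(n, rng)
    x_p = _bandpass(raw, spec.fp_band, spec.fs)
    x_a = _bandpass(raw, spec.fa_band, spec.fs)

    # relative maxima: strictly greater than both neighbours (earliest kept on ties)
    peaks = argrelmax(x_p)[0]
    n_w = max(int(round(spec.window_ms / 1000.0 * spec.fs)), 3)
    window = np.hanning(n_w)
    gain = np.ones(n)
    for p in peaks:
        lo = max(0, p - n_w // 2)
        hi = min(n, lo + n_w)
        gain[lo:hi] *= 1.0 + spec.intensity * window[: hi - lo]
    x = x_p + x_a * gain

    if spec.snr_db is not None:
        raw_n = brownian_noise(n, rng)
        eps = _bandpass(raw_n, spec.fp_band, spec.fs) + _bandpass(raw_n, spec.fa_band, spec.fs)
        x = x + _scale_to_snr(x, eps, spec.snr_db)
    return Signal(x, fs=spec.fs)
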
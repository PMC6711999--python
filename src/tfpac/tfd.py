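"""Rihaczek and RID-Rihaczek complex time-frequency distributions.

The Rihaczek distribution ``C(t,f) = x(t) X*(f) e^{-j 2 pi f t}`` is a
complex energy density with exact time and frequency marginals.  Being
bilinear it carries cross-terms for multicomponent signals; the reduced
interference (RID) variant multiplies the signal's ambiguity function by
the Choi-Williams kernel ``exp(-(theta tau)^2 / sigma)`` before the 2-D
transform back to the time-frequency plane, suppressing components away
from the ambiguity-domain axes (cross-terms and most noise) while leaving
the axes — and hence the marginals — intact.

Discretisation
--------------
The analytic signal (one-sided spectrum) is formed first, so envelopes and
phases of real inputs are meaningful.  Lag products are circular on the
sample grid; the Rihaczek half-lag kernel ``e^{j theta tau / 2}`` is folded
exactly into the asymmetric lag product ``sum_v x(v) x*(v - tau) e^{j theta v}``,
which keeps every quantity on integer grids.  The Choi-Williams argument is
evaluated with both ambiguity coordinates expressed as angles on their DFT
circles (``theta = 2 pi k / N`` rad/sample, ``tau_hat = 2 pi m / N``); the
overall normalisation is fixed so the plain-kernel time marginal equals
``|x_a(t)|^2`` exactly, which makes that normalisation the module's single
source of truth.

The full surface is an O(N^2) complex matrix; long inputs should be
decimated first (``Signal.decimated``) — the surface cost, not aliasing,
is the binding constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .signal import Signal

__all__ = [
    "KernelConfig",
    "AmbiguityMatrix",
    "TimeFrequencyDistribution",
    "analytic_signal",
    "ambiguity_function",
    "compute_tfd",
]

DEFAULT_SIGMA = 0.001  # Choi-Williams parameter used throughout the study
DEFAULT_MAX_SAMPLES = 8192


@dataclass(frozen=True)
class KernelConfig:
    """Ambiguity-domain kernel: plain Rihaczek or Choi-Williams filtered."""

    kind: str = "rid_rihaczek"
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self) -> None:
        if self.kind not in ("rihaczek", "rid_rihaczek"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class AmbiguityMatrix:
    """Symmetric ambiguity function A(theta, tau) on shifted DFT grids.

    ``values[i, j]`` corresponds to doppler ``theta_axis[i]`` (rad/sample)
    and lag ``tau_axis[j]`` (samples); A(0,0) is the signal energy and
    A(-theta,-tau) = A*(theta,tau).
    """

    values: np.ndarray
    theta_axis: np.ndarray
    tau_axis: np.ndarray


@dataclass(frozen=True)
class TimeFrequencyDistribution:
    """Complex time x frequency surface with its axis grids.

    ``values[i, j]`` is C(t_i, f_j); the frequency axis spans 0..fs/2
    (analytic-signal convention, so the time marginal is |x_a(t)|^2).
    """

    values: np.ndarray
    time_axis: np.ndarray
    freq_axis: np.ndarray
    fs: float
    kernel: KernelConfig = field(default_factory=KernelConfig)
    full_time_marginal: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.time_axis.size

    def time_marginal(self) -> np.ndarray:
        """Per-sample sum over frequency (instantaneous power).

        Evaluated over the *full* circular frequency grid: the Choi-Williams
        kernel is identity on the zero-lag column, so the full-grid marginal
        is exact for both kernels, while the stored non-negative half alone
        would miss smoothing leakage that only cancels on the full circle.
        """
        if self.full_time_marginal is not None:
            return self.full_time_marginal
        return self.values.sum(axis=1)

    def frequency_marginal(self) -> np.ndarray:
        """Sum over time per stored bin; |X(f)|^2 (unitary DFT) for the plain kernel."""
        return self.values.sum(axis=0)

    def energy(self) -> float:
        return float(np.real(self.time_marginal().sum()))

    def band_columns(self, f_lo: float, f_hi: float) -> np.ndarray:
        sel = (self.freq_axis >= f_lo) & (self.freq_axis <= f_hi)
        if not sel.any():
            raise ValueError(
                f"no frequency bins inside [{f_lo}, {f_hi}] Hz "
                f"(grid step {self.freq_axis[1] - self.freq_axis[0]:.3g} Hz)")
        return sel

    def nearest_bin(self, f: float) -> int:
        return int(np.argmin(np.abs(self.freq_axis - f)))

    def export_magnitude(self, path) -> None:
        """Write |C(t,f)| as delimited text with axis header rows."""
        out = np.zeros((self.n + 1, self.freq_axis.size + 1))
        out[0, 1:] = self.freq_axis
        out[1:, 0] = self.time_axis
        out[1:, 1:] = np.abs(self.values)
        np.savetxt(path, out, header="row 0: freq_Hz; column 0: time_s; body: |C|")


def analytic_signal(signal: Signal) -> np.ndarray:
    """One-sided (analytic) version of the signal's samples."""
    x = np.asarray(signal.samples)
    if np.iscomplexobj(x):
        return x
    return hilbert(x)


def _lag_matrix(z: np.ndarray) -> np.ndarray:
    """Circular asymmetric lag products L[v, m] = z(v) z*((v - m) mod N)."""
    n = z.size
    v = np.arange(n)
    idx = (v[:, None] - v[None, :]) % n
    return z[:, None] * np.conj(z[idx])


def _asymmetric_ambiguity(z: np.ndarray) -> np.ndarray:
    """A_R[k, m] = sum_v z(v) z*(v - m) e^{j 2 pi k v / N} (rows: doppler k)."""
    L = _lag_matrix(z)
    return z.size * np.fft.ifft(L, axis=0)


def ambiguity_function(signal: Signal) -> AmbiguityMatrix:
    """Symmetric ambiguity function of the (analytic) signal.

    The asymmetric transform above equals the symmetric-lag ambiguity
    function times the Rihaczek half-lag kernel ``e^{j theta tau / 2}``;
    dividing that phase back out yields the symmetric A(theta, tau).
    """
    z = analytic_signal(signal)
    n = z.size
    if n < 2:
        raise ValueError("ambiguity function needs at least 2 samples")
    a_r = _asymmetric_ambiguity(z)
    k = np.fft.fftfreq(n) * n          # signed doppler index
    m = np.fft.fftfreq(n) * n          # signed lag index
    theta = 2.0 * np.pi * k / n        # rad/sample
    half_lag = np.exp(-0.5j * np.outer(theta, m))
    values = np.fft.fftshift(a_r * half_lag)
    return AmbiguityMatrix(values=values,
                           theta_axis=np.fft.fftshift(theta),
                           tau_axis=np.fft.fftshift(m))


def choi_williams(n: int, sigma: float) -> np.ndarray:
    """Choi-Williams weights exp(-(theta tau)^2 / sigma) on unshifted DFT grids.

    Both coordinates are taken as angles on their DFT circles, making the
    argument dimensionless and the kernel's pass region scale with the
    record rather than with the sampling rate.
    """
    ang = 2.0 * np.pi * np.fft.fftfreq(n)   # signed angles 2 pi k / N
    prod = np.outer(ang, ang)
    return np.exp(-(prod ** 2) / sigma)


def compute_tfd(signal: Signal, kernel: KernelConfig | None = None,
                max_samples: int = DEFAULT_MAX_SAMPLES) -> TimeFrequencyDistribution:
    """Rihaczek or RID-Rihaczek surface of a signal.

    For ``kind="rihaczek"`` the result equals ``x_a(t) X*(f) e^{-j2 pi f t} / N``
    on DFT grids (verified against the direct product in the test-suite);
    the Choi-Williams path multiplies the ambiguity function before the
    inverse 2-D transform.  Only the non-negative frequency half is stored
    (the analytic signal has no content above fs/2).

    Raises
    ------
    ValueError
        If the record exceeds ``max_samples`` — the O(N^2) surface would
        not fit a sane memory budget; decimate first (``Signal.decimated``).
    """
    kernel = kernel or KernelConfig()
    z = analytic_signal(signal)
    n = z.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    if n > max_samples:
        raise ValueError(
            f"record of {n} samples exceeds max_samples={max_samples}; "
            "decimate the signal or raise the budget explicitly")

    a_r = _asymmetric_ambiguity(z)
    if kernel.kind == "rid_rihaczek":
        a_r = choi_williams(n, kernel.sigma) * a_r
    # inverse 2-D transform; /N fixed so the plain time marginal is |z(t)|^2
    g = np.fft.fft(a_r, axis=0) / n            # (t, tau)
    c = np.fft.fft(g, axis=1) / n              # (t, f), full DFT grid

    n_keep = n // 2 + 1
    freq = np.arange(n_keep) * signal.fs / n
    return TimeFrequencyDistribution(
        values=c[:, :n_keep],
        time_axis=np.arange(n) / signal.fs,
        freq_axis=freq,
        fs=signal.fs,
        kernel=kernel,
        full_time_marginal=c.sum(axis=1),
    )
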
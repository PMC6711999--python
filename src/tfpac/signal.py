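"""Uniformly sampled signals and plain-text signal I/O.

A :class:`Signal` is the common currency of the package: a finite 1-D
real- (or analytic complex-) valued series with its sampling rate.  Signals
are written either as two-column delimited text (time in seconds, value) or
as a single value column with the sampling rate in a YAML sidecar file.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import decimate as _decimate

__all__ = ["Signal", "read_signal", "write_signal"]


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled time series.

    Parameters
    ----------
    samples : ndarray
        1-D array of finite values (real, or complex for analytic signals).
    fs : float
        Sampling rate in Hz, > 0.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("signal must be 1-D with at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite samples")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds (n / fs)."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    def power(self) -> float:
        """Mean squared value (average power)."""
        return float(np.mean(np.abs(self.samples) ** 2))

    def decimated(self, max_freq: float, min_factor_over_max_freq: float = 4.0) -> "Signal":
        """Anti-aliased downsampling for quadratic time-frequency analysis.

        Picks the largest integer factor q such that the decimated rate
        stays at least ``min_factor_over_max_freq`` times ``max_freq``
        (a safety margin well above Nyquist), and applies a zero-phase
        FIR decimator.  Returns ``self`` unchanged when q would be 1.
        """
        if max_freq <= 0:
            raise ValueError("max_freq must be positive")
        q = int(self.fs // (min_factor_over_max_freq * max_freq))
        if q <= 1:
            return self
        out = _decimate(np.real(self.samples), q, ftype="fir", zero_phase=True)
        return replace(self, samples=out, fs=self.fs / q)


def write_signal(path: str | Path, signal: Signal, fmt: str = "two_column") -> None:
    """Write a signal as delimited text.

    ``fmt="two_column"`` writes (time_s, value) rows; ``fmt="column"``
    writes a single value column plus a ``<path>.yml`` sidecar holding the
    sampling rate.
    """
    path = Path(path)
    if fmt == "two_column":
        np.savetxt(path, np.column_stack([signal.times, np.real(signal.samples)]),
                   header="time_s value")
    elif fmt == "column":
        np.savetxt(path, np.real(signal.samples))
        with open(path.with_suffix(path.suffix + ".yml"), "w") as fh:
            yaml.safe_dump({"fs": float(signal.fs)}, fh)
    else:
        raise ValueError(f"unknown signal format {fmt!r}")


def read_signal(path: str | Path, fs: float | None = None) -> Signal:
    """Read a signal written by :func:`write_signal`.

    Two-column files carry their own time axis; single-column files need
    ``fs`` or the YAML sidecar.
    """
    path = Path(path)
    data = np.loadtxt(path)
    if data.ndim == 2 and data.shape[1] >= 2:
        t, v = data[:, 0], data[:, 1]
        dt = np.diff(t)
        if dt.size and (dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError(f"{path}: time column is not uniformly increasing")
        return Signal(v, fs=1.0 / dt[0])
    if fs is None:
        sidecar = path.with_suffix(path.suffix + ".yml")
        if sidecar.exists():
            with open(sidecar) as fh:
                fs = float(yaml.safe_load(fh)["fs"])
        else:
            raise ValueError(f"{path}: single-column signal needs fs or a sidecar file")
    return Signal(np.atleast_1d(data), fs=fs)
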
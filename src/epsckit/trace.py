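"""Core trace container and shared signal-conditioning primitives.

A :class:`Trace` is a uniformly sampled single-channel current signal
(conventionally in pA, negative deflections = inward currents) together with
its sampling rate.  All detectors in this package consume traces that have
been smoothed, baseline-corrected and/or unit-scaled by the functions below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

__all__ = [
    "Trace",
    "FilterKernel",
    "blackman_harris_kernel",
    "smooth",
    "correct_baseline",
    "scale_unit",
    "resample",
]


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled current trace.

    Parameters
    ----------
    samples : ndarray
        Current values, pA (or dimensionless after unit scaling).
    sampling_rate : float
        Sampling rate in Hz, > 0.
    units_flag : str
        One of ``"raw"``, ``"baseline_corrected"``, ``"unit_scaled"``.
    """

    samples: np.ndarray
    sampling_rate: float
    units_flag: str = "raw"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("trace must be a non-empty 1-d sample sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError("trace samples must all be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.units_flag not in ("raw", "baseline_corrected", "unit_scaled"):
            raise ValueError(f"unknown units_flag {self.units_flag!r}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n samples / rate)."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.sampling_rate

    def with_samples(self, samples: np.ndarray, units_flag: str | None = None) -> "Trace":
        return replace(
            self, samples=samples, units_flag=units_flag or self.units_flag
        )


@dataclass(frozen=True)
class FilterKernel:
    """A symmetric, unit-sum FIR smoothing kernel of odd width."""

    coefficients: np.ndarray
    width: int = field(init=False)

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coeffs)
        object.__setattr__(self, "width", coeffs.size)
        if coeffs.size < 1 or coeffs.size % 2 == 0:
            raise ValueError("kernel width must be odd and positive")
        if not np.allclose(coeffs, coeffs[::-1]):
            raise ValueError("kernel must be symmetric")
        if not np.isclose(coeffs.sum(), 1.0):
            raise ValueError("kernel must sum to 1")


def blackman_harris_kernel(width: int) -> FilterKernel:
    """Minimum 4-term Blackman-Harris window of odd ``width``, rescaled to unit sum.

    The unit-sum rescaling makes smoothing preserve the DC level of a trace.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be an odd positive integer")
    w = _signal.windows.blackmanharris(width, sym=True)
    return FilterKernel(w / w.sum())


def smooth(trace: Trace, kernel: FilterKernel) -> Trace:
    """Convolve ``trace`` with ``kernel`` (reflect padding; output length preserved)."""
    if len(trace) < kernel.width:
        raise ValueError(
            f"trace length {len(trace)} shorter than kernel width {kernel.width}"
        )
    smoothed = smooth_array(trace.samples, kernel)
    return trace.with_samples(smoothed)


def smooth_array(x: np.ndarray, kernel: FilterKernel) -> np.ndarray:
    """Reflect-padded same-length convolution on a bare array."""
    half = kernel.width // 2
    if half == 0:
        return np.asarray(x, dtype=float) * kernel.coefficients[0]
    padded = np.pad(np.asarray(x, dtype=float), half, mode="reflect")
    return np.convolve(padded, kernel.coefficients, mode="valid")


def correct_baseline(trace: Trace, window_len: int) -> Trace:
    """Remove the slowly floating baseline.

    The trace is smoothed by a kernel with ten times the length of the
    analysis window and the smoothed series is subtracted, so structure much
    slower than the analysis window is eliminated while brief events pass.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    long_len = 10 * window_len
    if long_len % 2 == 0:
        long_len += 1  # odd width required by the kernel
    if len(trace) < 10 * window_len:
        raise ValueError(
            f"trace length {len(trace)} shorter than 10 x window_len = {10 * window_len}"
        )
    kernel = blackman_harris_kernel(long_len)
    corrected = trace.samples - smooth_array(trace.samples, kernel)
    return trace.with_samples(corrected, units_flag="baseline_corrected")


def scale_unit(trace: Trace) -> Trace:
    """Affinely rescale the trace to the range [0, 1]."""
    lo = trace.samples.min()
    hi = trace.samples.max()
    if hi == lo:
        raise ValueError("cannot unit-scale a constant trace")
    return trace.with_samples((trace.samples - lo) / (hi - lo), units_flag="unit_scaled")


def resample(trace: Trace, target_rate: float) -> Trace:
    """Polyphase FIR resampling of the trace to ``target_rate`` Hz."""
    if not target_rate > 0:
        raise ValueError("target_rate must be positive")
    if np.isclose(target_rate, trace.sampling_rate):
        return trace
    from fractions import Fraction

    frac = Fraction(target_rate / trace.sampling_rate).limit_denominator(10_000)
    out = _signal.resample_poly(trace.samples, frac.numerator, frac.denominator)
    return replace(trace, samples=out, sampling_rate=target_rate)
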
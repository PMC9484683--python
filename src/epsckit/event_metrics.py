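"""Per-event kinetic parameters and kernel-density summaries.

For each detected event the module measures duration, peak amplitude,
10–90% rise time and the time constant of a single-exponential decay fit.
Distributions across detectors are summarized as jointly normalized kernel
density estimates: the per-detector areas are proportional to set sizes and
sum to 1, so the areas convey relative set size directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize as _optimize
from scipy import stats as _stats

from .events import Event, EventSet
from .trace import Trace

__all__ = ["EventKinetics", "DensitySummary", "measure_event", "measure_event_set",
           "density_summary"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EventKinetics:
    """Measured kinetics of one event (times in ms, amplitude in trace units)."""

    duration_ms: float
    amplitude: float
    rise_time_10_90_ms: Optional[float]
    decay_tau_ms: Optional[float]
    fit_quality: Optional[float]  # RMS of decay-fit residuals


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float) -> Optional[float]:
    """First downward crossing of ``level``, linearly interpolated."""
    below = y <= level
    if not below.any():
        return None
    k = int(np.argmax(below))
    if k == 0:
        return float(t[0])
    y0, y1 = y[k - 1], y[k]
    if y1 == y0:
        return float(t[k])
    frac = (level - y0) / (y1 - y0)
    return float(t[k - 1] + frac * (t[k] - t[k - 1]))


def _fit_decay(t_s: np.ndarray, z: np.ndarray) -> tuple[Optional[float], Optional[float]]:
    """Single-exponential fit z ~ A exp(-t/tau); returns (tau_s, rms)."""
    mask = z > z.max() * 1e-3
    if mask.sum() < 3:
        return None, None
    tm, zm = t_s[mask], z[mask]
    # log-linear seed, then nonlinear refinement
    slope, intercept = np.polyfit(tm, np.log(zm), 1)
    if slope >= 0:
        return None, None
    tau0 = -1.0 / slope
    a0 = float(np.exp(intercept))
    try:
        popt, _ = _optimize.curve_fit(
            lambda t, a, tau: a * np.exp(-t / tau),
            tm, zm, p0=(a0, tau0), maxfev=2000,
        )
        a_fit, tau = popt
        if tau <= 0:
            return None, None
        resid = zm - a_fit * np.exp(-tm / tau)
        return float(tau), float(np.sqrt(np.mean(resid**2)))
    except RuntimeError:
        logger.debug("decay fit failed to converge")
        return None, None


def measure_event(trace: Trace, event: Event,
                  baseline_span_ms: float = 2.0) -> EventKinetics:
    """Measure duration, amplitude, 10–90% rise time and decay tau of an event.

    The baseline is the event's linearized start value when present,
    otherwise the median over a short pre-event span.  When the detector
    provides no end, one is imputed at peak + 4 fitted decay constants
    (logged).
    """
    y = trace.samples
    fs = trace.sampling_rate
    n = len(y)
    peak = event.peak_index
    span = int(round(baseline_span_ms * 1e-3 * fs))
    start = event.start_index
    if start is None:
        start = max(0, peak - span)
    if event.start_value is not None:
        baseline = float(event.start_value)
    else:
        lo = max(0, start - span)
        baseline = float(np.median(y[lo:start])) if start > lo else float(y[start])
    amplitude = baseline - float(y[peak])

    # 10-90% rise time on the falling (toward-peak) flank
    rise = None
    if amplitude > 0 and peak > start:
        t = np.arange(start, peak + 1) / fs
        seg = y[start : peak + 1]
        t10 = _interp_crossing(t, seg, baseline - 0.1 * amplitude)
        t90 = _interp_crossing(t, seg, baseline - 0.9 * amplitude)
        if t10 is not None and t90 is not None and t90 > t10:
            rise = (t90 - t10) * 1e3

    # decay fit from peak to end (imputing an end if needed)
    end = event.end_index
    imputed = end is None
    if imputed:
        # rough tau: time to recover to baseline - A/e
        tail = y[peak : min(n, peak + int(0.05 * fs))]
        rec = _interp_crossing(
            np.arange(tail.size) / fs, -tail, -(baseline - amplitude / np.e)
        )
        rough = rec if rec else 2e-3
        end = min(n - 1, peak + int(round(4 * rough * fs)))
        logger.debug("imputed event end at peak + 4 tau (%d samples)", end - peak)
    tau_ms = None
    rms = None
    if end > peak + 2:
        t_s = np.arange(end - peak + 1) / fs
        z = baseline - y[peak : end + 1]
        tau_s, rms = _fit_decay(t_s, z)
        if tau_s is not None:
            tau_ms = tau_s * 1e3
    duration = (end - start) / fs * 1e3
    return EventKinetics(
        duration_ms=float(duration),
        amplitude=float(amplitude),
        rise_time_10_90_ms=rise,
        decay_tau_ms=tau_ms,
        fit_quality=rms,
    )


def measure_event_set(trace: Trace, events: EventSet) -> pd.DataFrame:
    """Kinetics of every event in a set, as a tidy frame."""
    rows = []
    for e in events:
        k = measure_event(trace, e)
        rows.append(
            {
                "method": e.method_tag or events.method_tag,
                "peak_s": e.peak_index / events.sampling_rate,
                "duration_ms": k.duration_ms,
                "amplitude": k.amplitude,
                "rise_time_10_90_ms": k.rise_time_10_90_ms,
                "decay_tau_ms": k.decay_tau_ms,
                "fit_quality": k.fit_quality,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["method", "peak_s", "duration_ms", "amplitude",
                 "rise_time_10_90_ms", "decay_tau_ms", "fit_quality"],
    )


@dataclass
class DensitySummary:
    """Jointly normalized per-detector kernel densities on a common grid."""

    grid: np.ndarray
    densities: dict[str, np.ndarray]
    counts: dict[str, int]

    def areas(self) -> dict[str, float]:
        return {k: float(np.trapezoid(v, self.grid)) for k, v in self.densities.items()}

    def to_dataframe(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame({"grid": self.grid, "detector": name, "density": dens})
            for name, dens in self.densities.items()
        ]
        return pd.concat(frames, ignore_index=True)


def density_summary(values_by_detector: dict[str, np.ndarray],
                    bw_method=None, grid_size: int = 512,
                    min_bandwidth_frac: float = 0.01) -> DensitySummary:
    """Gaussian KDE per detector, areas proportional to set sizes, summing to 1.

    ``bw_method`` is passed to the KDE (Scott's rule by default).  Groups
    with fewer than two distinct values get a Gaussian spike with a minimum
    bandwidth floor instead of a degenerate KDE.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_detector.items()
              if len(v) > 0}
    if not groups or max(len(v) for v in groups.values()) < 2:
        raise ValueError("need at least one detector with >= 2 values")
    pooled = np.concatenate(list(groups.values()))
    lo, hi = pooled.min(), pooled.max()
    pad = 0.25 * (hi - lo) if hi > lo else max(1.0, abs(hi))
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    floor = min_bandwidth_frac * (grid[-1] - grid[0])
    total = sum(len(v) for v in groups.values())
    densities = {}
    for name, vals in groups.items():
        if len(vals) < 2 or np.ptp(vals) == 0:
            dens = _stats.norm.pdf(grid, loc=vals.mean(), scale=floor)
        else:
            dens = _stats.gaussian_kde(vals, bw_method=bw_method)(grid)
        area = np.trapezoid(dens, grid)
        densities[name] = dens / area * (len(vals) / total)
    return DensitySummary(
        grid=grid, densities=densities, counts={k: len(v) for k, v in groups.items()}
    )
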
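"""Classical threshold detectors for negative-going synaptic events.

Two complementary algorithms:

* ``SimpleThresholdDetector`` — finds local minima, pairs each with its
  nearest preceding local maximum, and reports an event when both the
  peak-to-peak amplitude of that step and the steepest negative slope within
  it exceed preset thresholds.  It cannot locate the end of an event.
* ``SlopeDetector`` — a sequential trigger on the first derivative of the
  filtered signal: a steep negative slope opens an event, the local minimum
  is the peak, and the event closes when the positive slope of the decay
  phase falls back below a threshold.  Events longer than a preset maximum
  duration are discarded.

Both run on a Blackman-Harris-filtered copy of the trace and share the
event-start linearization of :func:`linearize_event_start`.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as _signal
from sklearn.base import BaseEstimator

from .events import Event, EventSet
from .trace import Trace, blackman_harris_kernel, smooth

__all__ = [
    "SimpleThresholdDetector",
    "SlopeDetector",
    "detect_simple",
    "detect_slope",
    "linearize_event_start",
]

logger = logging.getLogger(__name__)


def linearize_event_start(
    trace: Trace,
    step_window: tuple[int, int],
    zero_slope_frac: float = 0.05,
    lookback: int = 250,
) -> tuple[int, float]:
    """Refine the start of a falling step by linearizing its steepest flank.

    Inside ``step_window`` the inflection point (extremum of the first
    derivative) is located; scanning backwards from it, the nearest
    near-zero-slope sample gives the pre-event baseline value.  The returned
    start is the intersection of the tangent line at the inflection point
    with that baseline level — a point that generally does not lie on the
    signal itself but marks a proper start time and value.

    Falls back to the window start (logged) when no falling step or no
    zero-slope point is found.
    """
    i0, i1 = step_window
    i0 = max(0, int(i0))
    i1 = min(len(trace) - 1, int(i1))
    y = trace.samples
    if i1 <= i0:
        return i0, float(y[i0])
    d = np.gradient(y)  # units per sample
    infl = i0 + int(np.argmin(d[i0 : i1 + 1]))
    m = d[infl]
    if m >= 0:
        logger.debug("linearize_event_start: no falling step in window, falling back")
        return i0, float(y[i0])
    zero_tol = zero_slope_frac * abs(m)
    z = None
    for idx in range(infl - 1, max(-1, infl - 1 - lookback), -1):
        if abs(d[idx]) < zero_tol:
            z = idx
            break
    if z is None:
        logger.debug("linearize_event_start: no zero-slope point, falling back")
        return i0, float(y[i0])
    start_value = float(y[z])
    t = infl + (start_value - y[infl]) / m
    start_index = int(round(np.clip(t, 0, infl)))
    return start_index, start_value


class SimpleThresholdDetector(BaseEstimator):
    """Local-extrema event detector ("simple" algorithm).

    Parameters
    ----------
    amplitude_threshold : float
        Minimum local-max-to-local-min amplitude of a step, trace units.
    slope_threshold : float
        Minimum magnitude of the steepest negative slope within the step,
        trace units per second.
    filter_width : int
        Width (odd, samples) of the Blackman-Harris smoothing kernel.
    """

    method_tag = "simple"

    def __init__(self, amplitude_threshold: float = 10.0,
                 slope_threshold: float = 1e4, filter_width: int = 21):
        self.amplitude_threshold = amplitude_threshold
        self.slope_threshold = slope_threshold
        self.filter_width = filter_width

    def fit(self, X=None, y=None):
        """Stateless detector; validates parameters and returns self."""
        if not (self.amplitude_threshold > 0 and self.slope_threshold > 0):
            raise ValueError("thresholds must be positive")
        blackman_harris_kernel(self.filter_width)  # validates width
        self.is_fitted_ = True
        return self

    def detect(self, trace: Trace) -> EventSet:
        self.fit()
        filt = smooth(trace, blackman_harris_kernel(self.filter_width))
        y = filt.samples
        fs = trace.sampling_rate
        deriv = np.gradient(y) * fs
        minima, _ = _signal.find_peaks(-y)
        maxima, _ = _signal.find_peaks(y)
        events = []
        prev_min = 0
        for m in minima:
            prior = maxima[(maxima < m) & (maxima >= prev_min)]
            if prior.size:
                mx = int(prior[-1])
            else:
                # flat stretch without a strict local maximum: take the
                # highest sample since the previous minimum
                mx = prev_min + int(np.argmax(y[prev_min:m]))
            prev_min = m
            amp = y[mx] - y[m]
            if amp < self.amplitude_threshold:
                continue
            steepest = deriv[mx : m + 1].min()
            if -steepest < self.slope_threshold:
                continue
            events.append(
                Event(
                    peak_index=int(m),
                    start_index=int(mx),
                    start_value=float(y[mx]),
                    amplitude=float(amp),
                    method_tag=self.method_tag,
                )
            )
        return EventSet(
            events=events,
            sampling_rate=fs,
            method_tag=self.method_tag,
            parameters=self.get_params(),
        )

    predict = detect


class SlopeDetector(BaseEstimator):
    """Derivative-trigger event detector ("slope" algorithm).

    Parameters
    ----------
    neg_slope_threshold : float
        Negative trigger, trace units per second (< 0).  An event opens when
        the derivative of the filtered signal falls below it.
    pos_slope_threshold : float
        Positive closing threshold (> 0).  After the peak the event closes
        at the first sample where the positive decay slope falls back below
        this value (having exceeded it once).
    max_duration_ms : float
        Events spanning longer than this from start to end are discarded.
    filter_width : int
        Width of the Blackman-Harris smoothing kernel.
    refine_start : bool
        Refine event starts with :func:`linearize_event_start`.
    """

    method_tag = "slope"

    def __init__(self, neg_slope_threshold: float = -2.2e4,
                 pos_slope_threshold: float = 2.2e3, max_duration_ms: float = 10.0,
                 filter_width: int = 21, refine_start: bool = True):
        self.neg_slope_threshold = neg_slope_threshold
        self.pos_slope_threshold = pos_slope_threshold
        self.max_duration_ms = max_duration_ms
        self.filter_width = filter_width
        self.refine_start = refine_start

    def fit(self, X=None, y=None):
        if not (self.neg_slope_threshold < 0 < self.pos_slope_threshold):
            raise ValueError("need neg_slope_threshold < 0 < pos_slope_threshold")
        if not self.max_duration_ms > 0:
            raise ValueError("max_duration_ms must be positive")
        blackman_harris_kernel(self.filter_width)
        self.is_fitted_ = True
        return self

    def detect(self, trace: Trace) -> EventSet:
        self.fit()
        filt = smooth(trace, blackman_harris_kernel(self.filter_width))
        y = filt.samples
        fs = trace.sampling_rate
        d = np.gradient(y) * fs
        n = len(y)
        max_span = int(round(self.max_duration_ms * 1e-3 * fs))
        events = []
        discarded_unclosed = 0
        discarded_too_long = 0
        i = 1
        while i < n:
            if d[i] >= self.neg_slope_threshold:
                i += 1
                continue
            trigger = i
            # peak: first non-negative derivative after the negative trigger
            j = trigger
            while j < n and d[j] < 0:
                j += 1
            if j >= n:
                discarded_unclosed += 1
                break
            peak = j - 1 + int(np.argmin(y[j - 1 : min(j + 2, n)]))
            # close: positive slope exceeds then falls below the threshold
            armed = False
            end = None
            k = peak + 1
            limit = trigger + 2 * max_span  # scan guard
            while k < n and k <= limit:
                if d[k] >= self.pos_slope_threshold:
                    armed = True
                elif armed and d[k] < self.pos_slope_threshold:
                    end = k
                    break
                k += 1
            if end is None:
                discarded_unclosed += 1
                i = k
                continue
            start, start_value = trigger, float(y[trigger])
            if self.refine_start:
                start, start_value = linearize_event_start(
                    filt, (max(0, trigger - self.filter_width), peak)
                )
            if end - start > max_span:
                discarded_too_long += 1
                i = end + 1
                continue
            events.append(
                Event(
                    peak_index=int(peak),
                    start_index=int(min(start, peak)),
                    end_index=int(end),
                    start_value=start_value,
                    amplitude=float(max(0.0, start_value - y[peak])),
                    method_tag=self.method_tag,
                )
            )
            i = end + 1
        if discarded_unclosed:
            logger.info("slope detector: %d unclosed events discarded", discarded_unclosed)
        params = self.get_params()
        params["discarded_unclosed"] = discarded_unclosed
        params["discarded_too_long"] = discarded_too_long
        # duplicate peaks cannot occur (sequential scan), but be safe
        seen: set[int] = set()
        uniq = [e for e in events if not (e.peak_index in seen or seen.add(e.peak_index))]
        return EventSet(
            events=uniq, sampling_rate=fs, method_tag=self.method_tag, parameters=params
        )

    predict = detect


def detect_simple(trace: Trace, amplitude_threshold: float, slope_threshold: float,
                  filter_width: int = 21) -> EventSet:
    """Functional wrapper over :class:`SimpleThresholdDetector`."""
    return SimpleThresholdDetector(
        amplitude_threshold, slope_threshold, filter_width
    ).detect(trace)


def detect_slope(trace: Trace, neg_slope_threshold: float, pos_slope_threshold: float,
                 max_duration_ms: float = 10.0, filter_width: int = 21) -> EventSet:
    """Functional wrapper over :class:`SlopeDetector`."""
    return SlopeDetector(
        neg_slope_threshold, pos_slope_threshold, max_duration_ms, filter_width
    ).detect(trace)
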
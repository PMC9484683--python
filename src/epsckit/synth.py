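"""Ground-truthed synthetic spEPSC traces.

Generates irregular sequences of negative-going biexponential events with
variable amplitude and kinetics, superimposed on band-limited noise and a
slowly floating sinusoidal baseline — the statistical structure every
detector in this package assumes.  Each generated trace comes with its exact
ground truth, so precision/recall and kinetics recovery can be measured
without any recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .trace import Trace

__all__ = ["SyntheticSpec", "GroundTruth", "analytic_event", "generate_trace"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic spontaneous-EPSC recording.

    Defaults emulate a good-quality voltage-clamp recording of fast
    glutamatergic spEPSCs: ~20 pA mean peak amplitude, sub-millisecond rise,
    ~2 ms decay, a few pA of recording noise and a slow baseline drift.
    """

    duration_s: float = 10.0
    sampling_rate: float = 25_000.0
    event_rate: float = 8.0          # events/s, Poisson intensity
    amplitude_mean: float = 20.0     # pA, mean peak magnitude
    amplitude_cv: float = 0.3        # CV of the log-normal amplitude distribution
    tau_rise_ms: float = 0.4
    tau_decay_ms: float = 2.0
    kinetic_jitter: float = 0.25     # CV applied per event to both taus
    noise_sigma: float = 0.2         # pA, white component (residual above the
                                     # acquisition anti-aliasing filter)
    noise_lowpass_hz: float = 1_000.0  # cutoff of the band-limited component
    noise_lowpass_sigma: float = 1.5   # pA, band-limited component after filtering
    drift_amplitude: float = 5.0     # pA, slow sinusoidal baseline
    drift_period_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tau_rise_ms < self.tau_decay_ms:
            raise ValueError("tau_rise must be < tau_decay")
        for name in ("duration_s", "sampling_rate", "tau_rise_ms", "tau_decay_ms",
                     "drift_period_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("event_rate", "amplitude_mean", "amplitude_cv", "kinetic_jitter",
                     "noise_sigma", "noise_lowpass_sigma", "drift_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Per-event truth of a synthetic trace, sorted by onset."""

    onset_s: np.ndarray
    peak_s: np.ndarray
    amplitude_pA: np.ndarray
    tau_rise_ms: np.ndarray
    tau_decay_ms: np.ndarray

    def __len__(self) -> int:
        return self.onset_s.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": self.onset_s,
                "peak_s": self.peak_s,
                "amplitude_pA": self.amplitude_pA,
                "tau_rise_ms": self.tau_rise_ms,
                "tau_decay_ms": self.tau_decay_ms,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def biexp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Closed-form argmax of exp(-t/tau_d) - exp(-t/tau_r), same units as the taus."""
    return tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)


def analytic_event(
    amplitude: float,
    tau_rise_ms: float,
    tau_decay_ms: float,
    sampling_rate: float,
    n_decay_constants: float = 8.0,
) -> np.ndarray:
    """A single noiseless negative-going biexponential event waveform.

    The waveform is ``-A * k * (exp(-t/tau_d) - exp(-t/tau_r))`` with ``k``
    chosen so the peak magnitude equals ``amplitude`` exactly; it spans from
    onset to ``peak + n_decay_constants * tau_d``.
    """
    if tau_rise_ms >= tau_decay_ms:
        raise ValueError("tau_rise must be < tau_decay")
    tau_r = tau_rise_ms * 1e-3
    tau_d = tau_decay_ms * 1e-3
    t_peak = biexp_peak_time(tau_r, tau_d)
    n = max(2, int(np.ceil((t_peak + n_decay_constants * tau_d) * sampling_rate)))
    t = np.arange(n) / sampling_rate
    shape = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    # normalize on the sampled grid so the realized peak equals the amplitude
    return -amplitude * shape / shape.max()


def _band_limited_noise(n: int, sigma: float, cutoff_hz: float,
                        sampling_rate: float, rng: np.random.Generator) -> np.ndarray:
    """White Gaussian noise through a first-order low-pass, rescaled to sigma."""
    white = rng.standard_normal(n)
    if cutoff_hz >= sampling_rate / 2:
        return sigma * white
    b, a = _signal.butter(1, cutoff_hz, fs=sampling_rate)
    filt = _signal.lfilter(b, a, white)
    sd = filt.std()
    if sd == 0:
        return np.zeros(n)
    return sigma * filt / sd


def generate_trace(spec: SyntheticSpec) -> tuple[Trace, GroundTruth]:
    """Generate one synthetic trace and its ground truth.

    Event arrivals are a homogeneous Poisson process; amplitudes are
    log-normal with the spec's mean and CV; both time constants get an
    independent log-normal jitter per event (redrawn if it would invert the
    rise/decay ordering).  Overlapping events sum linearly.  Identical seed
    means bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    n = int(round(spec.duration_s * fs))
    trace = np.zeros(n)

    # slow sinusoidal baseline with a random phase
    phase = rng.uniform(0, 2 * np.pi)
    if spec.drift_amplitude > 0:
        t = np.arange(n) / fs
        trace += spec.drift_amplitude * np.sin(
            2 * np.pi * t / spec.drift_period_s + phase
        )

    n_events = rng.poisson(spec.event_rate * spec.duration_s)
    onsets = np.sort(rng.uniform(0, spec.duration_s, size=n_events))

    if spec.amplitude_cv > 0:
        s2 = np.log1p(spec.amplitude_cv**2)
        amps = rng.lognormal(np.log(spec.amplitude_mean) - s2 / 2, np.sqrt(s2), n_events)
    else:
        amps = np.full(n_events, spec.amplitude_mean)

    tau_r = np.full(n_events, spec.tau_rise_ms)
    tau_d = np.full(n_events, spec.tau_decay_ms)
    if spec.kinetic_jitter > 0:
        j2 = np.log1p(spec.kinetic_jitter**2)
        for i in range(n_events):
            while True:
                r = spec.tau_rise_ms * rng.lognormal(-j2 / 2, np.sqrt(j2))
                d = spec.tau_decay_ms * rng.lognormal(-j2 / 2, np.sqrt(j2))
                if r < d:
                    tau_r[i], tau_d[i] = r, d
                    break

    peak_s = np.empty(n_events)
    for i in range(n_events):
        wave = analytic_event(amps[i], tau_r[i], tau_d[i], fs)
        i0 = int(round(onsets[i] * fs))
        seg = wave[: max(0, n - i0)]
        trace[i0 : i0 + seg.size] += seg
        peak_s[i] = onsets[i] + biexp_peak_time(tau_r[i] * 1e-3, tau_d[i] * 1e-3)

    if spec.noise_sigma > 0:
        trace += spec.noise_sigma * rng.standard_normal(n)
    if spec.noise_lowpass_sigma > 0:
        trace += _band_limited_noise(
            n, spec.noise_lowpass_sigma, spec.noise_lowpass_hz, fs, rng
        )

    truth = GroundTruth(
        onset_s=onsets,
        peak_s=peak_s,
        amplitude_pA=amps,
        tau_rise_ms=tau_r,
        tau_decay_ms=tau_d,
    )
    return Trace(trace, fs, "raw"), truth
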
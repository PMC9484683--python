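"""Detected-event containers shared by all detectors."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["Event", "EventSet"]


@dataclass(frozen=True)
class Event:
    """One detected synaptic event.

    Indices are sample positions on the trace the detector ran on.
    ``end_index`` is absent (None) for detectors that cannot locate the end
    of an event.  ``amplitude`` is the positive magnitude of the downward
    (inward-current) deflection, in the units of the analysed trace.
    """

    peak_index: int
    start_index: Optional[int] = None
    end_index: Optional[int] = None
    start_value: Optional[float] = None
    amplitude: Optional[float] = None
    method_tag: str = ""

    def __post_init__(self) -> None:
        if self.start_index is not None and self.start_index > self.peak_index:
            raise ValueError("start_index must be <= peak_index")
        if self.end_index is not None and self.end_index < self.peak_index:
            raise ValueError("end_index must be >= peak_index")
        if self.amplitude is not None and self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def duration_ms(self, sampling_rate: float) -> Optional[float]:
        if self.start_index is None or self.end_index is None:
            return None
        return (self.end_index - self.start_index) / sampling_rate * 1e3


@dataclass
class EventSet:
    """Events of one detector run, sorted by peak position."""

    events: list[Event]
    sampling_rate: float
    method_tag: str = ""
    trace_id: str = ""
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.peak_index)
        peaks = [e.peak_index for e in self.events]
        if len(set(peaks)) != len(peaks):
            raise ValueError("duplicate peak_index in EventSet")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __getitem__(self, i: int) -> Event:
        return self.events[i]

    @property
    def peak_times(self) -> np.ndarray:
        """Peak positions in seconds."""
        return np.array([e.peak_index for e in self.events], dtype=float) / self.sampling_rate

    def to_dataframe(self) -> pd.DataFrame:
        fs = self.sampling_rate
        rows = []
        for e in self.events:
            rows.append(
                {
                    "trace_id": self.trace_id,
                    "method": e.method_tag or self.method_tag,
                    "start_s": None if e.start_index is None else e.start_index / fs,
                    "peak_s": e.peak_index / fs,
                    "end_s": None if e.end_index is None else e.end_index / fs,
                    "amplitude": e.amplitude,
                    "duration_ms": e.duration_ms(fs),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "trace_id",
                "method",
                "start_s",
                "peak_s",
                "end_s",
                "amplitude",
                "duration_ms",
            ],
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @staticmethod
    def from_peak_times(
        peak_times_s: Sequence[float], sampling_rate: float, method_tag: str = ""
    ) -> "EventSet":
        """Build a minimal EventSet from peak times in seconds."""
        events = [
            Event(peak_index=int(round(t * sampling_rate)), method_tag=method_tag)
            for t in peak_times_s
        ]
        return EventSet(events=events, sampling_rate=sampling_rate, method_tag=method_tag)
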
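"""Trace ingestion and export.

Supported formats: single-column or two-column (time, current) CSV/TSV, and
HDF5 containers with a ``current`` dataset plus a ``sampling_rate_hz``
attribute.  Every ingested trace carries an explicit sampling rate.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .trace import Trace

__all__ = ["read_trace", "write_trace", "read_trace_csv", "read_trace_hdf5"]


def read_trace_csv(path, sampling_rate: float | None = None) -> Trace:
    """Read a trace from CSV/TSV.

    One column: current only (``sampling_rate`` required).  Two columns:
    time in seconds and current; the rate is inferred from the time column
    unless given explicitly.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    if df.shape[1] == 1:
        if sampling_rate is None:
            raise ValueError("single-column trace file needs an explicit sampling_rate")
        return Trace(df.iloc[:, 0].to_numpy(float), sampling_rate)
    if df.shape[1] >= 2:
        t = df.iloc[:, 0].to_numpy(float)
        y = df.iloc[:, 1].to_numpy(float)
        if sampling_rate is None:
            dts = np.diff(t)
            if dts.size == 0 or not np.allclose(dts, dts[0], rtol=1e-6):
                raise ValueError("time column is not uniformly sampled")
            sampling_rate = 1.0 / dts[0]
        return Trace(y, sampling_rate)
    raise ValueError(f"cannot interpret trace file {path}")


def read_trace_hdf5(path) -> Trace:
    import h5py

    with h5py.File(path, "r") as f:
        if "current" not in f:
            raise ValueError(f"{path} has no 'current' dataset")
        ds = f["current"]
        rate = ds.attrs.get("sampling_rate_hz", f.attrs.get("sampling_rate_hz"))
        if rate is None:
            raise ValueError(f"{path} carries no sampling_rate_hz attribute")
        return Trace(ds[...], float(rate))


def read_trace(path, sampling_rate: float | None = None) -> Trace:
    """Dispatch on file suffix (.csv/.tsv/.txt vs .h5/.hdf5)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return read_trace_hdf5(path)
    return read_trace_csv(path, sampling_rate)


def write_trace(trace: Trace, path) -> None:
    """Write a trace as two-column CSV (time_s, current_pA) or HDF5."""
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            ds = f.create_dataset("current", data=trace.samples)
            ds.attrs["sampling_rate_hz"] = trace.sampling_rate
        return
    pd.DataFrame(
        {"time_s": trace.times, "current_pA": trace.samples}
    ).to_csv(path, index=False)
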
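"""Plain-text readers/writers for traces, heart-rate series and counts."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cardiac import CardiacTrace, HeartRateSeries

__all__ = [
    "write_trace_csv", "read_trace_csv",
    "write_series_csv", "read_series_csv",
]


def write_trace_csv(trace: CardiacTrace, path) -> None:
    df = pd.DataFrame({"time_s": trace.time_s, "temp_C": trace.temp_C,
                       "signal": trace.signal})
    if trace.window_flag is not None:
        df["window_flag"] = trace.window_flag.astype(int)
    df.to_csv(path, index=False)


def read_trace_csv(path) -> CardiacTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "temp_C"):
        if col not in df.columns:
            raise ValueError(f"trace file {path} missing column {col!r}")
    if "signal" in df.columns:
        sig = df["signal"].to_numpy(float)
    elif "hr_bpm" in df.columns:
        sig = df["hr_bpm"].to_numpy(float)
    else:
        raise ValueError(f"trace file {path} needs a 'signal' or 'hr_bpm' column")
    flag = None
    if "window_flag" in df.columns:
        flag = df["window_flag"].to_numpy().astype(bool)
    return CardiacTrace(df["time_s"].to_numpy(float),
                        df["temp_C"].to_numpy(float), sig, window_flag=flag)


def write_series_csv(series: HeartRateSeries, path) -> None:
    df = pd.DataFrame({"temp_C": series.temp_C, "hr_bpm": series.hr_bpm})
    if series.arrhythmic is not None:
        df["window_flag"] = series.arrhythmic.astype(int)
    df.to_csv(path, index=False)


def read_series_csv(path) -> HeartRateSeries:
    df = pd.read_csv(path)
    for col in ("temp_C", "hr_bpm"):
        if col not in df.columns:
            raise ValueError(f"series file {path} missing column {col!r}")
    flags = None
    if "window_flag" in df.columns:
        flags = df["window_flag"].to_numpy().astype(bool)
    order = np.argsort(df["temp_C"].to_numpy(), kind="stable")
    return HeartRateSeries(df["temp_C"].to_numpy(float)[order],
                           df["hr_bpm"].to_numpy(float)[order],
                           arrhythmic=None if flags is None else flags[order])
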
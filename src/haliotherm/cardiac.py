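"""Cardiac performance analysis: beat detection, heart-rate windowing,
Arrhenius transformation, and breakpoint (ABT) estimation.

The Arrhenius breakpoint temperature (ABT) is the temperature at which the
slope of ln(heart rate) against inverse absolute temperature changes
abruptly — the standard non-invasive proxy for the upper thermal limit of
cardiac function in gastropods.  The estimator fits two independent
ordinary-least-squares lines on either side of every admissible split of
the Arrhenius-transformed series and keeps the split with the smallest
total residual sum of squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

KELVIN_OFFSET = 273.15

__all__ = [
    "CardiacTrace",
    "HeartRateSeries",
    "ArrheniusSeries",
    "BrokenStickFit",
    "MaxHeartRate",
    "celsius_to_arrhenius_x",
    "arrhenius_x_to_celsius",
    "detect_beats",
    "heart_rate_by_temperature",
    "arrhenius_transform",
    "fit_broken_stick",
    "max_heart_rate",
    "estimate_abt",
]


def celsius_to_arrhenius_x(temp_c):
    """Arrhenius abscissa 1000/K with K = degC + 273.15."""
    return 1000.0 / (np.asarray(temp_c, dtype=float) + KELVIN_OFFSET)


def arrhenius_x_to_celsius(x):
    return 1000.0 / np.asarray(x, dtype=float) - KELVIN_OFFSET


@dataclass
class CardiacTrace:
    """Raw (or simulated) sensor recording along a temperature ramp.

    ``signal`` holds arbitrary sensor units with one pulse per heart beat;
    ``window_flag`` marks samples inside corrupted (arrhythmic) windows.
    ``beat_times`` is optional ground truth carried by the simulator.
    """

    time_s: np.ndarray
    temp_C: np.ndarray
    signal: np.ndarray
    window_flag: np.ndarray | None = None
    sampling_hz: float | None = None
    beat_times: np.ndarray | None = None

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.temp_C = np.asarray(self.temp_C, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_s.ndim != 1 or len(self.time_s) != len(self.temp_C):
            raise ValueError("time_s and temp_C must be 1-d and equal length")
        if len(self.signal) != len(self.time_s):
            raise ValueError("signal length must match time_s")
        if len(self.time_s) > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time_s must be strictly increasing")
        if np.any((self.temp_C <= -5) | (self.temp_C >= 50)):
            raise ValueError("temp_C outside plausible range (-5, 50)")
        if self.window_flag is not None:
            self.window_flag = np.asarray(self.window_flag, dtype=bool)
            if len(self.window_flag) != len(self.time_s):
                raise ValueError("window_flag length must match time_s")
        if self.sampling_hz is None and len(self.time_s) > 1:
            dt = np.diff(self.time_s)
            if np.allclose(dt, dt[0], rtol=1e-6):
                self.sampling_hz = 1.0 / dt[0]


@dataclass
class HeartRateSeries:
    """Windowed heart rate (beats per minute) along the temperature ramp."""

    temp_C: np.ndarray
    hr_bpm: np.ndarray
    n_beats: np.ndarray | None = None
    arrhythmic: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.temp_C = np.asarray(self.temp_C, dtype=float)
        self.hr_bpm = np.asarray(self.hr_bpm, dtype=float)
        if len(self.temp_C) != len(self.hr_bpm):
            raise ValueError("temp_C and hr_bpm must have equal length")
        if len(self.temp_C) > 1 and np.any(np.diff(self.temp_C) < 0):
            raise ValueError("temp_C must be non-decreasing")
        if self.n_beats is not None:
            self.n_beats = np.asarray(self.n_beats)
        if self.arrhythmic is not None:
            self.arrhythmic = np.asarray(self.arrhythmic, dtype=bool)

    def retained(self) -> "HeartRateSeries":
        """Series restricted to non-arrhythmic windows."""
        if self.arrhythmic is None:
            return self
        keep = ~self.arrhythmic
        return HeartRateSeries(
            self.temp_C[keep],
            self.hr_bpm[keep],
            None if self.n_beats is None else self.n_beats[keep],
            diagnostics=dict(self.diagnostics),
        )

    def __len__(self):
        return len(self.temp_C)


@dataclass
class ArrheniusSeries:
    """ln(heart rate) against 1000/K; x decreases as temperature rises."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")

    def __len__(self):
        return len(self.x)


@dataclass
class BrokenStickFit:
    """Two independent OLS segments with the RSS-optimal split.

    ``pre`` refers to the segment below the breakpoint temperature (large x),
    ``post`` to the segment above it.  ``no_distinct_breakpoint`` is set when
    the two-segment fit reduces the single-line RSS by less than 5%.
    """

    slope_pre: float
    intercept_pre: float
    slope_post: float
    intercept_post: float
    x_break: float
    abt_C: float
    rss_total: float
    n_pre: int
    n_post: int
    rss_single_line: float
    no_distinct_breakpoint: bool
    convention: str = "intersection"


@dataclass
class MaxHeartRate:
    hr_bpm: float
    temp_C: float


def detect_beats(trace: CardiacTrace, min_prominence: float = 0.5,
                 refractory_s: float = 0.2) -> np.ndarray:
    """Locate heart beats as prominent peaks in the pulse signal.

    Returns strictly increasing beat times (seconds).  A flat signal yields
    an empty array with a warning rather than an exception.
    """
    if refractory_s <= 0:
        raise ValueError("refractory_s must be > 0")
    if trace.sampling_hz is None:
        raise ValueError("trace must be uniformly sampled for beat detection")
    sig = trace.signal
    if np.ptp(sig) == 0:
        warnings.warn("flat signal: no beats detected", stacklevel=2)
        return np.empty(0)
    distance = max(1, int(round(refractory_s * trace.sampling_hz)))
    peaks, _ = _signal.find_peaks(sig, prominence=min_prominence,
                                  distance=distance)
    if len(peaks) == 0:
        warnings.warn("no peaks above prominence threshold", stacklevel=2)
    return trace.time_s[peaks]


def heart_rate_by_temperature(beats: np.ndarray, trace: CardiacTrace,
                              window_C: float = 0.5) -> HeartRateSeries:
    """Average heart rate in successive temperature windows of the ramp.

    Each window [T, T + window_C) contributes one record with
    hr_bpm = 60 * n_beats / window duration in seconds.  Windows overlapping
    arrhythmia-flagged samples are excluded, as are windows with fewer than
    two beats; exclusion counts are recorded in ``diagnostics``.
    """
    if window_C <= 0:
        raise ValueError("window_C must be > 0")
    beats = np.asarray(beats, dtype=float)
    t0, t1 = trace.temp_C.min(), trace.temp_C.max()
    edges = np.arange(t0, t1 + window_C, window_C)
    # temperature at each beat, from the ramp record
    beat_temp = np.interp(beats, trace.time_s, trace.temp_C)

    temps, rates, counts = [], [], []
    n_arrhythmic = n_sparse = 0
    for lo in edges[:-1]:
        hi = lo + window_C
        in_win = (trace.temp_C >= lo) & (trace.temp_C < hi)
        if not np.any(in_win):
            continue
        if trace.window_flag is not None and np.any(trace.window_flag[in_win]):
            n_arrhythmic += 1
            continue
        duration = trace.time_s[in_win].max() - trace.time_s[in_win].min()
        if duration <= 0:
            continue
        n = int(np.sum((beat_temp >= lo) & (beat_temp < hi)))
        if n < 2:
            n_sparse += 1
            continue
        temps.append(lo + window_C / 2.0)
        rates.append(60.0 * n / duration)
        counts.append(n)
    return HeartRateSeries(
        np.array(temps), np.array(rates), np.array(counts),
        diagnostics={"excluded_arrhythmic": n_arrhythmic,
                     "excluded_sparse": n_sparse},
    )


def arrhenius_transform(series: HeartRateSeries) -> ArrheniusSeries:
    """Map (temp_C, hr_bpm) to (1000/K, ln hr).  Requires hr_bpm > 0."""
    bad = np.flatnonzero(series.hr_bpm <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive heart rate at record {bad[0]} "
            f"(temp {series.temp_C[bad[0]]:.2f} degC)"
        )
    return ArrheniusSeries(celsius_to_arrhenius_x(series.temp_C),
                           np.log(series.hr_bpm))


def _ols_rss(x, y):
    """Slope, intercept, RSS of an OLS line through (x, y)."""
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise ValueError("degenerate segment: zero variance in x")
    sxy = np.sum((x - xm) * (y - ym))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    return slope, intercept, float(np.sum(resid ** 2))


def fit_broken_stick(aseries: ArrheniusSeries, min_seg: int = 4,
                     convention: str = "intersection") -> BrokenStickFit:
    """Exhaustive broken-stick regression in Arrhenius coordinates.

    Every split of the x-sorted data into a low-x (high-temperature, post-
    breakpoint) and a high-x (low-temperature, pre-breakpoint) segment with
    at least ``min_seg`` points each is evaluated; the two segments are fit
    independently by OLS and the split minimising total RSS is returned.
    RSS ties are broken toward the split with more pre-breakpoint points,
    then toward the lower breakpoint temperature.

    ``convention`` selects how the breakpoint is located inside the
    bracketing interval: ``"intersection"`` uses the crossing point of the
    two fitted lines when it falls between the bracketing data points
    (midpoint otherwise); ``"split-midpoint"`` always uses the midpoint.
    """
    if convention not in ("intersection", "split-midpoint"):
        raise ValueError(f"unknown break convention: {convention!r}")
    n = len(aseries)
    if n < 2 * min_seg:
        raise ValueError(
            f"need at least {2 * min_seg} points for min_seg={min_seg}, got {n}"
        )
    order = np.argsort(aseries.x)
    x, y = aseries.x[order], aseries.y[order]
    if np.any(np.diff(x) == 0):
        raise ValueError("x values must be distinct")

    # exact fits leave only rounding noise in the RSS: snap those to zero so
    # the documented tie-break (largest pre segment, then lowest ABT) applies
    tss = float(np.sum((y - y.mean()) ** 2))
    snap = 1e-12 * max(tss, 1.0)

    best = None  # ((rss_key, -n_pre, abt), fit_tuple)
    for k in range(min_seg, n - min_seg + 1):
        # low-x head = post-breakpoint segment, high-x tail = pre-breakpoint
        m_post, b_post, rss_post = _ols_rss(x[:k], y[:k])
        m_pre, b_pre, rss_pre = _ols_rss(x[k:], y[k:])
        rss = rss_pre + rss_post

        x_lo, x_hi = x[k - 1], x[k]
        xb = 0.5 * (x_lo + x_hi)
        if convention == "intersection" and m_pre != m_post:
            xi = (b_post - b_pre) / (m_pre - m_post)
            if x_lo <= xi <= x_hi:
                xb = xi
        abt = float(arrhenius_x_to_celsius(xb))
        key = (rss if rss > snap else 0.0, -(n - k), abt)
        if best is None or key < best[0]:
            best = (key, (m_pre, b_pre, m_post, b_post, xb, abt, rss, n - k, k))

    m_pre, b_pre, m_post, b_post, xb, abt, rss, n_pre, n_post = best[1]
    _, _, rss_single = _ols_rss(x, y)
    no_break = rss_single <= snap or (rss_single - rss) < 0.05 * rss_single
    return BrokenStickFit(
        slope_pre=m_pre, intercept_pre=b_pre,
        slope_post=m_post, intercept_post=b_post,
        x_break=float(xb), abt_C=abt, rss_total=float(rss),
        n_pre=n_pre, n_post=n_post,
        rss_single_line=float(rss_single),
        no_distinct_breakpoint=bool(no_break),
        convention=convention,
    )


def max_heart_rate(series: HeartRateSeries) -> MaxHeartRate:
    """Maximum heart rate over retained windows, with its temperature.

    Ties resolve to the first (lowest-temperature) occurrence.
    """
    kept = series.retained()
    if len(kept) == 0:
        raise ValueError("empty heart-rate series")
    i = int(np.argmax(kept.hr_bpm))
    return MaxHeartRate(float(kept.hr_bpm[i]), float(kept.temp_C[i]))


def estimate_abt(series: HeartRateSeries, min_seg: int = 4,
                 convention: str = "intersection") -> BrokenStickFit:
    """Convenience wrapper: exclude arrhythmic windows, Arrhenius-transform,
    and fit the broken stick."""
    return fit_broken_stick(arrhenius_transform(series.retained()),
                            min_seg=min_seg, convention=convention)
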
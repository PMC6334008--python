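"""Synthetic data generators for the heat-tolerance analysis.

Two generators mirror the study design: (1) two-phase Arrhenius heart-rate
curves along a 0.1 degC/min temperature ramp, with line-specific
breakpoints and optional arrhythmic windows, both as windowed heart-rate
series and as raw pulse-sensor traces; (2) negative-binomial RNA-seq count
matrices for a 2-line x 2-condition x 3-replicate design with spiked
heat-response fold changes, more numerous in the sensitive line, plus the
ground-truth fold changes per contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cardiac import (
    CardiacTrace,
    HeartRateSeries,
    celsius_to_arrhenius_x,
)
from .de import CountMatrix

__all__ = [
    "CardiacSimParams",
    "CountSimParams",
    "simulate_heart_rate_series",
    "simulate_pulse_trace",
    "simulate_count_matrix",
]


@dataclass
class CardiacSimParams:
    """Parameters of the two-phase Arrhenius heart-rate model.

    In Arrhenius coordinates (x = 1000/K, y = ln beats/min) the noiseless
    curve is two line segments meeting at x_b = 1000/(abt_true + 273.15):
    slope_pre below the breakpoint temperature (x > x_b, typically
    negative: rate rises with temperature) and slope_post above it
    (typically large positive: cardiac collapse).  The curve is anchored
    so the heart rate at 20 degC equals hr_at_20C.
    """

    abt_true: float = 30.0          # degC
    slope_pre: float = -7.0         # d(ln hr)/d(1000/K), below breakpoint
    slope_post: float = 40.0        # same units, above breakpoint
    hr_at_20C: float = 30.0         # beats/min
    ramp_rate: float = 0.1          # degC per minute
    temp_range: tuple[float, float] = (20.0, 34.0)
    noise_sd: float = 0.05          # sd of ln(hr) noise
    arrhythmia_prob: float = 0.0    # probability a window is corrupted
    n_points: int = 60              # observations along the ramp
    seed: int | None = None

    def __post_init__(self):
        lo, hi = self.temp_range
        if not (lo < self.abt_true < hi):
            raise ValueError("abt_true must lie strictly inside temp_range")
        if self.hr_at_20C <= 0:
            raise ValueError("hr_at_20C must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.arrhythmia_prob < 1):
            raise ValueError("arrhythmia_prob must be in [0, 1)")
        if self.ramp_rate <= 0:
            raise ValueError("ramp_rate must be > 0")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    def mean_log_hr(self, temp_c):
        """Noiseless ln(heart rate) at the given temperatures."""
        x = celsius_to_arrhenius_x(temp_c)
        xb = float(celsius_to_arrhenius_x(self.abt_true))
        x20 = float(celsius_to_arrhenius_x(20.0))
        y20 = np.log(self.hr_at_20C)
        yb = y20 + self.slope_pre * (xb - x20)
        return np.where(x >= xb,
                        y20 + self.slope_pre * (x - x20),
                        yb + self.slope_post * (x - xb))


def simulate_heart_rate_series(params: CardiacSimParams) -> HeartRateSeries:
    """Windowed heart-rate observations along the ramp.

    Points are evenly spaced in temperature over ``temp_range``; ln(hr)
    noise is Gaussian with sd ``noise_sd``; each point is independently
    flagged arrhythmic with probability ``arrhythmia_prob``.
    """
    rng = np.random.default_rng(params.seed)
    temps = np.linspace(*params.temp_range, params.n_points)
    y = params.mean_log_hr(temps)
    if params.noise_sd > 0:
        y = y + rng.normal(0.0, params.noise_sd, params.n_points)
    flags = rng.random(params.n_points) < params.arrhythmia_prob
    return HeartRateSeries(temps, np.exp(y), arrhythmic=flags)


def simulate_pulse_trace(params: CardiacSimParams,
                         sampling_hz: float = 20.0,
                         pulse_width_s: float = 0.15,
                         arrhythmia_window_s: float = 30.0) -> CardiacTrace:
    """Raw pulse-sensor trace with one pulse per beat.

    Beat times follow the integrated instantaneous rate of the two-phase
    model; the signal is a train of raised-cosine pulses.  Windows of
    ``arrhythmia_window_s`` seconds are independently corrupted (beats
    removed, samples flagged) with probability ``arrhythmia_prob``.  The
    generator's beat times are stored on the trace for round-trip checks.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.temp_range
    duration_s = (hi - lo) / params.ramp_rate * 60.0
    max_rate_hz = float(np.exp(params.mean_log_hr(
        np.linspace(lo, hi, 512)).max())) / 60.0
    if sampling_hz < 10.0 * max_rate_hz:
        raise ValueError(
            f"sampling_hz={sampling_hz} undersamples the pulse train; "
            f"use at least {10.0 * max_rate_hz:.1f} Hz"
        )
    n = int(np.floor(duration_s * sampling_hz)) + 1
    t = np.arange(n) / sampling_hz
    temp = lo + params.ramp_rate / 60.0 * t

    # integrate the instantaneous rate (Hz) to get beat times
    rate_hz = np.exp(params.mean_log_hr(temp)) / 60.0
    phase = np.concatenate([[0.0], np.cumsum(
        0.5 * (rate_hz[1:] + rate_hz[:-1]) / sampling_hz)])
    n_beats = int(np.floor(phase[-1]))
    beat_times = np.interp(np.arange(1, n_beats + 1), phase, t)

    window_flag = np.zeros(n, dtype=bool)
    if params.arrhythmia_prob > 0:
        n_win = int(np.ceil(duration_s / arrhythmia_window_s))
        corrupted = rng.random(n_win) < params.arrhythmia_prob
        win_idx = np.minimum((t / arrhythmia_window_s).astype(int), n_win - 1)
        window_flag = corrupted[win_idx]
        beat_win = np.minimum((beat_times / arrhythmia_window_s).astype(int),
                              n_win - 1)
        beat_times = beat_times[~corrupted[beat_win]]

    sig = np.zeros(n)
    half = pulse_width_s / 2.0
    for bt in beat_times:
        i0 = max(0, int(np.ceil((bt - half) * sampling_hz)))
        i1 = min(n - 1, int(np.floor((bt + half) * sampling_hz)))
        if i1 >= i0:
            u = (t[i0:i1 + 1] - bt) / half
            sig[i0:i1 + 1] += 0.5 * (1.0 + np.cos(np.pi * np.clip(u, -1, 1)))

    return CardiacTrace(time_s=t, temp_C=temp, signal=sig,
                        window_flag=window_flag, sampling_hz=sampling_hz,
                        beat_times=beat_times)


@dataclass
class CountSimParams:
    """Parameters of the negative-binomial count simulator.

    The default design matches the study: sensitive and tolerant lines,
    control and heat conditions, three replicates each.  Gene baseline
    means are log-normal; dispersion follows the decreasing trend
    alpha(mu) = a0 + a1/mu; heat-response fold changes are spiked into a
    larger fraction of genes in the sensitive line, with log2 magnitudes
    1.6 + Exponential(scale 1.5) truncated at 11.9 (the span observed for
    the heat-shock-protein family).  A smaller set of constitutive
    between-line differences feeds the line contrasts.
    """

    n_genes: int = 10000
    design: tuple = (("sensitive", "control", 3), ("sensitive", "heat", 3),
                     ("tolerant", "control", 3), ("tolerant", "heat", 3))
    mean_log_expression: tuple[float, float] = (5.0, 1.5)  # ln-scale mu, sd
    dispersion_coef: tuple[float, float] = (0.05, 2.0)     # a0, a1 in a0+a1/mu
    de_fraction: dict = field(default_factory=lambda: {"sensitive": 0.10,
                                                       "tolerant": 0.04})
    shared_de_fraction: float = 0.75   # of tolerant-line DEGs also DE in sensitive
    up_fraction: dict = field(default_factory=lambda: {"sensitive": 0.66,
                                                       "tolerant": 0.83})
    lfc_magnitude: tuple[float, float, float] = (1.6, 1.5, 11.9)  # min, exp scale, max
    line_de_fraction: float = 0.03     # constitutive between-line differences
    lib_size_factors: tuple | None = None
    gene_length_log: tuple[float, float] = (7.3, 0.8)  # ln-scale mu, sd (bp)
    seed: int | None = None

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError("n_genes must be > 0")
        for line, cond, n in self.design:
            if n < 2:
                raise ValueError(
                    f"design cell ({line}, {cond}) needs >= 2 replicates")
        for k, f in self.de_fraction.items():
            if not 0 <= f <= 1:
                raise ValueError(f"de_fraction[{k!r}] must be in [0, 1]")
        if self.lib_size_factors is not None:
            if np.any(np.asarray(self.lib_size_factors) <= 0):
                raise ValueError("lib_size_factors must be > 0")

    @property
    def n_samples(self):
        return sum(n for _, _, n in self.design)


def _draw_lfc(rng, size, up_prob, magnitude):
    lo, scale, hi = magnitude
    mag = np.minimum(lo + rng.exponential(scale, size), hi)
    sign = np.where(rng.random(size) < up_prob, 1.0, -1.0)
    return sign * mag


def simulate_count_matrix(params: CountSimParams) -> tuple[CountMatrix, pd.DataFrame]:
    """Integer NB counts plus the per-contrast ground-truth log2 FC table.

    Returns ``(CountMatrix, truth)`` where ``truth`` has one row per gene
    with columns ``lfc_I`` .. ``lfc_IV`` (same orientation as the analysis
    contrasts: I/II sensitive over tolerant, III/IV heat over control).
    """
    rng = np.random.default_rng(params.seed)
    G = params.n_genes
    mu_base = rng.lognormal(*params.mean_log_expression, G)
    a0, a1 = params.dispersion_coef
    alpha = a0 + a1 / mu_base

    f_s = params.de_fraction.get("sensitive", 0.0)
    f_t = params.de_fraction.get("tolerant", 0.0)
    n_s = int(round(f_s * G))
    n_t = int(round(f_t * G))
    perm = rng.permutation(G)
    sens_de = perm[:n_s]
    n_shared = min(int(round(params.shared_de_fraction * n_t)), n_s)
    tol_de = np.concatenate([
        rng.choice(sens_de, n_shared, replace=False) if n_shared else [],
        perm[n_s:n_s + (n_t - n_shared)],
    ]).astype(int)

    lfc_heat_s = np.zeros(G)
    lfc_heat_t = np.zeros(G)
    lfc_heat_s[sens_de] = _draw_lfc(rng, n_s, params.up_fraction["sensitive"],
                                    params.lfc_magnitude)
    # genes responding in both lines keep the same direction, usually with a
    # somewhat larger magnitude in the tolerant line; tolerant-only genes
    # get independent draws
    shared_mask = np.isin(tol_de, sens_de)
    shared = tol_de[shared_mask]
    lfc_heat_t[shared] = lfc_heat_s[shared] * np.clip(
        rng.normal(1.15, 0.2, len(shared)), 0.3, 2.0)
    tol_only = tol_de[~shared_mask]
    lfc_heat_t[tol_only] = _draw_lfc(rng, len(tol_only),
                                     params.up_fraction["tolerant"],
                                     params.lfc_magnitude)

    n_line = int(round(params.line_de_fraction * G))
    line_de = rng.permutation(G)[:n_line]
    lfc_line = np.zeros(G)  # log2(sensitive / tolerant), constitutive
    if n_line:
        lfc_line[line_de] = _draw_lfc(rng, n_line, 0.5,
                                      (params.lfc_magnitude[0], 1.0, 6.0))

    sample_ids, lines, conds, reps = [], [], [], []
    for line, cond, n in params.design:
        for r in range(1, n + 1):
            sample_ids.append(f"{line[:4]}_{cond}_{r}")
            lines.append(line)
            conds.append(cond)
            reps.append(r)
    S = len(sample_ids)
    sf = (np.ones(S) if params.lib_size_factors is None
          else np.asarray(params.lib_size_factors, dtype=float))
    if len(sf) != S:
        raise ValueError(f"lib_size_factors must have length {S}")

    # per-gene mean for each sample; tolerant line carries the baseline
    counts = np.empty((G, S), dtype=np.int64)
    for j, (line, cond) in enumerate(zip(lines, conds)):
        mu = mu_base.copy()
        if line == "sensitive":
            mu = mu * 2.0 ** lfc_line
        if cond == "heat":
            mu = mu * 2.0 ** (lfc_heat_s if line == "sensitive" else lfc_heat_t)
        mu = mu * sf[j]
        r = 1.0 / alpha
        counts[:, j] = rng.negative_binomial(r, r / (r + mu))

    genes = pd.Index([f"g{i:05d}" for i in range(G)], name="gene_id")
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
        samples=pd.DataFrame({"line": lines, "condition": conds,
                              "replicate": reps},
                             index=pd.Index(sample_ids, name="sample_id")),
        gene_lengths=pd.Series(
            np.maximum(rng.lognormal(*params.gene_length_log, G), 201.0)
            .round().astype(int),
            index=genes, name="length_bp"),
    )
    truth = pd.DataFrame(
        {
            "lfc_I": lfc_line,
            "lfc_II": lfc_line + lfc_heat_s - lfc_heat_t,
            "lfc_III": lfc_heat_s,
            "lfc_IV": lfc_heat_t,
        },
        index=genes,
    )
    return cm, truth
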
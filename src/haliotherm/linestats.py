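"""Between-line comparison of thermal phenotypes.

One-way ANOVA across selective lines, Duncan's multiple range test on the
ordered group means, and the compact letter display used to annotate bar
charts (groups sharing a letter are not significantly different).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats


@lru_cache(maxsize=4096)
def _q_crit(alpha_p: float, p_len: int, df: int) -> float:
    """Upper studentized-range quantile q(alpha_p, p_len, df) (cached: the
    quantile is recomputed constantly across Duncan stretches)."""
    return float(stats.studentized_range.ppf(1.0 - alpha_p, p_len, df))

__all__ = [
    "LinePhenotypes",
    "AnovaResult",
    "DuncanGroups",
    "one_way_anova",
    "duncan_mrt",
    "summarize_lines",
    "identify_extreme_lines",
]


@dataclass
class LinePhenotypes:
    """Per-individual measurements (ABT degC or max heart rate) for one line."""

    line_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in line {self.line_id!r}")

    @property
    def n(self):
        return len(self.values)


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    ms_within: float
    group_means: pd.Series = field(default_factory=pd.Series)
    group_sds: pd.Series = field(default_factory=pd.Series)
    diagnostic: str | None = None


@dataclass
class DuncanGroups:
    """Ordered means, pairwise significance, and significance letters."""

    means: pd.Series                 # sorted descending
    significant: pd.DataFrame        # bool, symmetric, lines x lines
    letters: dict[str, str]
    alpha: float
    ms_within: float
    df_within: int


def _as_groups(groups) -> list[LinePhenotypes]:
    out = []
    for g in groups:
        if isinstance(g, LinePhenotypes):
            out.append(g)
        else:
            line_id, values = g
            out.append(LinePhenotypes(line_id, values))
    return out


def one_way_anova(groups) -> AnovaResult:
    """Standard one-way ANOVA: F = MS_between / MS_within.

    ``groups`` is a sequence of LinePhenotypes (or (label, values) pairs),
    each with at least two observations.
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for g in gs:
        if g.n < 2:
            raise ValueError(f"group {g.line_id!r} needs at least 2 values")
    allv = np.concatenate([g.values for g in gs])
    grand = allv.mean()
    k, N = len(gs), len(allv)
    ssb = sum(g.n * (g.values.mean() - grand) ** 2 for g in gs)
    ssw = sum(np.sum((g.values - g.values.mean()) ** 2) for g in gs)
    dfb, dfw = k - 1, N - k
    msw = ssw / dfw
    means = pd.Series({g.line_id: g.values.mean() for g in gs})
    sds = pd.Series({g.line_id: g.values.std(ddof=1) for g in gs})
    if ssw == 0:
        if ssb == 0:
            return AnovaResult(np.nan, dfb, dfw, np.nan, 0.0, means, sds,
                               diagnostic="zero variance within and between "
                                          "groups: F undefined")
        return AnovaResult(np.inf, dfb, dfw, 0.0, 0.0, means, sds,
                           diagnostic="zero within-group variance")
    f = (ssb / dfb) / msw
    p = float(stats.f.sf(f, dfb, dfw))
    return AnovaResult(float(f), dfb, dfw, p, float(msw), means, sds)


def _letters_from_nonsig(order: list[str], nonsig: np.ndarray) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    ``order`` lists group labels by descending mean; ``nonsig[i, j]`` is
    True when groups i and j are NOT significantly different.  Maximal
    runs of mutually non-significant adjacent groups each receive one
    letter; runs contained in a larger run are absorbed.
    """
    k = len(order)
    runs = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i, i:j + 2].all() and \
                all(nonsig[a, b] for a in range(i, j + 2) for b in range(i, j + 2)):
            j += 1
        runs.append((i, j))
    # keep maximal runs only
    maximal = [r for r in runs
               if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)]
    maximal = sorted(set(maximal))
    letters = {g: "" for g in order}
    for letter_i, (i, j) in enumerate(maximal):
        ch = chr(ord("a") + letter_i)
        for idx in range(i, j + 1):
            letters[order[idx]] += ch
    return letters


def duncan_mrt(groups, alpha: float = 0.05) -> DuncanGroups:
    """Duncan's multiple range test with significance letters.

    Means are ordered; a stretch of p adjacent ordered means is declared
    non-significant when its range does not exceed
    q(alpha_p, p, df_within) * sqrt(MS_within / n_h), with protection
    level alpha_p = 1 - (1 - alpha)^(p-1) and n_h the harmonic mean group
    size.  A pair inside a non-significant stretch is itself
    non-significant (the usual containment protection).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    gs = _as_groups(groups)
    an = one_way_anova(gs)
    if an.ms_within == 0:
        # all groups internally constant: direct mean comparison
        order = sorted(gs, key=lambda g: (-g.values.mean(), g.line_id))
        labels = [g.line_id for g in order]
        mvals = np.array([g.values.mean() for g in order])
        sig = np.not_equal.outer(mvals, mvals)
        letters = _letters_from_nonsig(labels, ~sig)
        return DuncanGroups(pd.Series(mvals, index=labels), pd.DataFrame(
            sig, index=labels, columns=labels), letters, alpha, 0.0,
            an.df_within)

    sizes = np.array([g.n for g in gs])
    if len(set(sizes)) > 1:
        warnings.warn("unbalanced groups: using harmonic mean group size",
                      stacklevel=2)
    n_h = len(sizes) / np.sum(1.0 / sizes)

    order = sorted(gs, key=lambda g: (-g.values.mean(), g.line_id))
    labels = [g.line_id for g in order]
    mvals = np.array([g.values.mean() for g in order])
    k = len(labels)

    # stretch test: range of means i..j vs Duncan critical range
    nonsig = np.eye(k, dtype=bool)
    sig = np.zeros((k, k), dtype=bool)
    se = np.sqrt(an.ms_within / n_h)
    for span in range(k - 1, 0, -1):       # longest stretches first
        p_len = span + 1
        alpha_p = 1.0 - (1.0 - alpha) ** (p_len - 1)
        crit = _q_crit(alpha_p, p_len, an.df_within) * se
        for i in range(0, k - span):
            j = i + span
            if nonsig[i, j]:
                continue  # protected by a containing non-significant stretch
            if mvals[i] - mvals[j] <= crit:
                nonsig[i:j + 1, i:j + 1] = True
            else:
                sig[i, j] = sig[j, i] = True
    sig[nonsig] = False
    letters = _letters_from_nonsig(labels, ~sig)
    return DuncanGroups(
        means=pd.Series(mvals, index=labels),
        significant=pd.DataFrame(sig, index=labels, columns=labels),
        letters=letters,
        alpha=alpha, ms_within=an.ms_within, df_within=an.df_within,
    )


def summarize_lines(groups, alpha: float = 0.05,
                    with_letters: bool = True) -> pd.DataFrame:
    """Per-line mean +/- sample sd table, joined with Duncan letters.

    The spread is the sample standard deviation across individuals
    (ddof=1); lines with a single individual report NaN sd.  With a
    single line (or ``with_letters=False``) no letters are attached.
    """
    gs = _as_groups(groups)
    if not gs:
        raise ValueError("no groups given")
    rows = []
    for g in gs:
        rows.append({
            "line": g.line_id,
            "n": g.n,
            "mean": g.values.mean(),
            "sd": g.values.std(ddof=1) if g.n > 1 else np.nan,
        })
    table = pd.DataFrame(rows).set_index("line")
    table = table.sort_values("mean", ascending=False)
    if with_letters and len(gs) >= 2 and all(g.n >= 2 for g in gs):
        letters = duncan_mrt(gs, alpha=alpha).letters
        table["letters"] = [letters[l] for l in table.index]
    return table


def identify_extreme_lines(groups) -> dict[str, str]:
    """Most heat-tolerant (highest mean) and most heat-sensitive (lowest
    mean) lines by sample mean."""
    gs = _as_groups(groups)
    means = {g.line_id: g.values.mean() for g in gs}
    return {
        "most_tolerant": max(means, key=means.get),
        "most_sensitive": min(means, key=means.get),
    }
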
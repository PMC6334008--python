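import numpy as np
import pandas as pd
import pytest

from haliotherm.de import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_count_matrix():
    """2 lines x 2 conditions x 3 replicates, 8 genes, hand-sized."""
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(8)]
    samples = []
    lines, conds, reps = [], [], []
    for line in ("sensitive", "tolerant"):
        for cond in ("control", "heat"):
            for r in (1, 2, 3):
                samples.append(f"{line[:4]}_{cond}_{r}")
                lines.append(line)
                conds.append(cond)
                reps.append(r)
    counts = pd.DataFrame(rng.poisson(100, size=(8, 12)),
                          index=genes, columns=samples)
    meta = pd.DataFrame({"line": lines, "condition": conds, "replicate": reps},
                        index=pd.Index(samples, name="sample_id"))
    lengths = pd.Series(rng.integers(300, 5000, 8), index=genes,
                        name="length_bp")
    return CountMatrix(counts, meta, lengths)


def brute_force_broken_stick_rss(x, y, min_seg=4):
    """Independent enumeration oracle: min total RSS over all admissible
    splits of the x-sorted data, each side fit with numpy.polyfit."""
    order = np.argsort(x)
    x, y = np.asarray(x)[order], np.asarray(y)[order]
    n = len(x)
    best = np.inf
    best_k = None
    for k in range(min_seg, n - min_seg + 1):
        rss = 0.0
        for xs, ys in ((x[:k], y[:k]), (x[k:], y[k:])):
            coef = np.polyfit(xs, ys, 1)
            rss += float(np.sum((ys - np.polyval(coef, xs)) ** 2))
        if rss < best:
            best, best_k = rss, k
    return best, best_k
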
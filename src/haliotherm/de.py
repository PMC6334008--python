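"""Negative-binomial differential expression from first principles.

Median-of-ratios normalization, method-of-moments dispersion estimation
with a fitted 1/mu trend, a per-gene Wald test on the difference of log
normalized means, the strict DEG filter (p < 0.05 and |log2 FC| > 1), the
four line x condition contrasts, and the Venn partition of DEG sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "DispersionFit",
    "ContrastResult",
    "DEGPartition",
    "size_factors",
    "log2_fold_change",
    "estimate_dispersions",
    "nb_test",
    "run_contrasts",
    "venn_partition",
    "fpkm",
    "CONTRAST_DEFS",
]

#: Default DEG filter, as used throughout the analysis.
P_THRESHOLD = 0.05
LFC_THRESHOLD = 1.0


@dataclass
class CountMatrix:
    """Gene x sample integer counts with sample metadata.

    ``samples`` is indexed by sample id and must provide ``line`` and
    ``condition`` columns; ``gene_lengths`` (bp) is optional and only
    needed for FPKM and length-aware enrichment.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    gene_lengths: pd.Series | None = None

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples metadata missing for: {sorted(missing)}")
        for col in ("line", "condition"):
            if col not in self.samples.columns:
                raise ValueError(f"samples metadata must have a {col!r} column")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)

    @property
    def genes(self):
        return self.counts.index

    def group_samples(self, line: str, condition: str) -> list[str]:
        m = self.samples
        sel = m.index[(m["line"] == line) & (m["condition"] == condition)]
        return [s for s in self.counts.columns if s in set(sel)]

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("gene_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, samples_path, lengths_path=None) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        lengths = None
        if lengths_path is not None:
            lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
        return cls(counts, samples, lengths)


@dataclass
class DispersionFit:
    """Per-gene NB dispersion with the fitted mean trend alpha(mu)=a0+a1/mu."""

    dispersion: pd.Series
    mom: pd.Series
    trend_coef: tuple[float, float]

    def trend(self, mu):
        a0, a1 = self.trend_coef
        return np.maximum(a0 + a1 / np.maximum(np.asarray(mu, float), 1e-12), 1e-8)


@dataclass
class ContrastResult:
    """Per-gene test result for one contrast (log2 FC of group_b over group_a)."""

    name: str
    group_a: str
    group_b: str
    table: pd.DataFrame
    p_threshold: float = P_THRESHOLD
    lfc_threshold: float = LFC_THRESHOLD

    @property
    def de_genes(self) -> set:
        t = self.table
        return set(t.index[t["de_flag"]])

    def directions(self) -> pd.Series:
        return self.table["direction"]

    @property
    def n_up(self) -> int:
        return int((self.table["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["direction"] == "down").sum())


@dataclass
class DEGPartition:
    """Venn decomposition of two DEG sets with up/down tallies."""

    common: set
    only_a: set
    only_b: set
    up_down_a: tuple[int, int] | None = None
    up_down_b: tuple[int, int] | None = None
    discordant: set = field(default_factory=set)


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios sample scale factors.

    s_j = median over genes with all-positive counts of
    counts[g, j] / geometric_mean_g(counts[g, :]).
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "filter the matrix before computing size factors"
        )
    logs = np.log(mat[all_pos])
    log_geo = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - log_geo, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def log2_fold_change(mean_control: float, mean_heat: float) -> tuple[float, bool]:
    """log2(mean_heat / mean_control) with symmetric pseudocount handling.

    If either mean is zero, 1 is added to both and the result is flagged;
    if both are zero the ratio is undefined (NaN, flagged).
    """
    if mean_control < 0 or mean_heat < 0:
        raise ValueError("means must be non-negative")
    if mean_control == 0 and mean_heat == 0:
        return float("nan"), True
    flagged = False
    if mean_control == 0 or mean_heat == 0:
        mean_control += 1.0
        mean_heat += 1.0
        flagged = True
    return float(np.log2(mean_heat / mean_control)), flagged


def _grouped_normalized(cm: CountMatrix, sf: pd.Series):
    return cm.counts.div(sf, axis=1)


def estimate_dispersions(cm: CountMatrix, sf: pd.Series | None = None) -> DispersionFit:
    """Method-of-moments NB dispersions with a conservative trend floor.

    Per gene, alpha_hat = max(0, (s2 - mu) / mu^2) from normalized counts,
    with s2 the within-(line, condition) pooled sample variance.  A trend
    alpha(mu) = a0 + a1/mu is fit by least squares to the positive
    estimates and the final dispersion is max(alpha_hat, trend(mu)).
    """
    if sf is None:
        sf = size_factors(cm)
    norm = _grouped_normalized(cm, sf).to_numpy(dtype=float)
    groups = []
    for (_, _), sub in cm.samples.groupby(["line", "condition"], sort=False):
        idx = [cm.counts.columns.get_loc(s) for s in sub.index
               if s in cm.counts.columns]
        if len(idx) >= 2:
            groups.append(idx)
    if not groups:
        raise ValueError("need at least 2 replicates in some (line, condition) cell")

    mu = norm.mean(axis=1)
    ss = np.zeros(len(mu))
    dof = 0
    for idx in groups:
        sub = norm[:, idx]
        gm = sub.mean(axis=1, keepdims=True)
        ss += ((sub - gm) ** 2).sum(axis=1)
        dof += len(idx) - 1
    s2 = ss / dof

    with np.errstate(divide="ignore", invalid="ignore"):
        mom = np.maximum(0.0, (s2 - mu) / np.maximum(mu, 1e-12) ** 2)
    mom[mu == 0] = np.nan

    use = np.isfinite(mom) & (mom > 0) & (mu > 1)
    if use.sum() >= 10:
        X = np.column_stack([np.ones(use.sum()), 1.0 / mu[use]])
        coef, *_ = np.linalg.lstsq(X, mom[use], rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
    else:  # too few informative genes: flat fallback
        a0, a1 = float(np.nanmedian(mom[use])) if use.any() else 0.01, 0.0
    a0 = max(a0, 0.0)
    a1 = max(a1, 0.0)
    trend = np.maximum(a0 + a1 / np.maximum(mu, 1e-12), 1e-8)
    final = np.where(np.isnan(mom), np.nan, np.maximum(mom, trend))
    genes = cm.genes
    return DispersionFit(
        dispersion=pd.Series(final, index=genes, name="dispersion"),
        mom=pd.Series(mom, index=genes, name="dispersion_mom"),
        trend_coef=(a0, a1),
    )


def nb_test(cm: CountMatrix, contrast, sf: pd.Series | None = None,
            dispersions: DispersionFit | None = None,
            p_threshold: float = P_THRESHOLD,
            lfc_threshold: float = LFC_THRESHOLD,
            name: str | None = None) -> ContrastResult:
    """Wald test for equal NB means between two sample groups.

    ``contrast`` is a pair of (line, condition) tuples or of explicit
    sample-id lists: (group_a, group_b).  The reported log2 FC is
    log2(mean_b / mean_a).  The SE of the log-mean difference comes from
    the delta method with Var(K_ij/s_j) = mu/s_j + alpha mu^2.  Genes with
    zero total count across the compared samples are excluded from the
    tested universe (NaN results, de_flag False).
    """
    ga, gb = contrast
    if isinstance(ga, tuple):
        ga = cm.group_samples(*ga)
    if isinstance(gb, tuple):
        gb = cm.group_samples(*gb)
    ga, gb = list(ga), list(gb)
    if set(ga) & set(gb):
        raise ValueError("contrast groups must be disjoint")
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each contrast group needs at least 2 samples")

    if sf is None:
        sf = size_factors(cm)
    if dispersions is None:
        dispersions = estimate_dispersions(cm, sf)

    norm = _grouped_normalized(cm, sf)
    A = norm[ga].to_numpy(float)
    B = norm[gb].to_numpy(float)
    mA, mB = A.mean(axis=1), B.mean(axis=1)
    raw_total = cm.counts[ga + gb].to_numpy(float).sum(axis=1)
    in_universe = raw_total > 0

    disp = dispersions.dispersion.to_numpy(float)
    disp = np.where(np.isfinite(disp), disp, 0.0)

    sfa = sf[ga].to_numpy(float)
    sfb = sf[gb].to_numpy(float)
    # Var(mean of normalized counts) per group, delta method on the log
    vA = (mA[:, None] / sfa[None, :] + disp[:, None] * mA[:, None] ** 2).sum(1) / len(ga) ** 2
    vB = (mB[:, None] / sfb[None, :] + disp[:, None] * mB[:, None] ** 2).sum(1) / len(gb) ** 2

    lfc = np.full(len(mA), np.nan)
    pseudo = np.zeros(len(mA), dtype=bool)
    p = np.full(len(mA), np.nan)
    both_pos = in_universe & (mA > 0) & (mB > 0)
    either_zero = in_universe & ~both_pos

    lfc[both_pos] = np.log2(mB[both_pos] / mA[both_pos])
    # symmetric pseudocount when one mean is zero
    lfc[either_zero] = np.log2((mB[either_zero] + 1) / (mA[either_zero] + 1))
    pseudo[either_zero] = True

    se2 = np.full(len(mA), np.nan)
    se2[both_pos] = vA[both_pos] / mA[both_pos] ** 2 + vB[both_pos] / mB[both_pos] ** 2
    mAp, mBp = mA + 1, mB + 1
    se2[either_zero] = (vA[either_zero] + 1e-12) / mAp[either_zero] ** 2 \
        + (vB[either_zero] + 1e-12) / mBp[either_zero] ** 2
    dlog = np.where(pseudo, np.log(mBp) - np.log(mAp),
                    np.log(np.maximum(mB, 1e-300)) - np.log(np.maximum(mA, 1e-300)))
    valid = in_universe & (se2 > 0)
    z = np.zeros(len(mA))
    z[valid] = dlog[valid] / np.sqrt(se2[valid])
    p[valid] = 2.0 * stats.norm.sf(np.abs(z[valid]))
    # identical data in both groups: difference exactly zero -> p = 1
    p[valid & (dlog == 0)] = 1.0

    de = valid & (p < p_threshold) & (np.abs(lfc) > lfc_threshold)
    direction = np.where(de & (lfc > 0), "up", np.where(de & (lfc < 0), "down", "ns"))

    padj = np.full(len(p), np.nan)
    if valid.any():
        padj[valid] = stats.false_discovery_control(p[valid], method="bh")

    table = pd.DataFrame(
        {
            "base_mean_a": mA,
            "base_mean_b": mB,
            "log2_fc": lfc,
            "p_value": p,
            "padj": padj,
            "de_flag": de,
            "direction": direction,
            "pseudocount": pseudo,
            "in_universe": in_universe,
        },
        index=cm.genes,
    )
    return ContrastResult(
        name=name or "contrast",
        group_a=",".join(map(str, ga)),
        group_b=",".join(map(str, gb)),
        table=table,
        p_threshold=p_threshold,
        lfc_threshold=lfc_threshold,
    )


#: The four standard contrasts: (name, group_a, group_b); log2 FC = b over a.
CONTRAST_DEFS = (
    ("I", ("tolerant", "control"), ("sensitive", "control")),
    ("II", ("tolerant", "heat"), ("sensitive", "heat")),
    ("III", ("sensitive", "control"), ("sensitive", "heat")),
    ("IV", ("tolerant", "control"), ("tolerant", "heat")),
)


def run_contrasts(cm: CountMatrix, sensitive: str = "sensitive",
                  tolerant: str = "tolerant", control: str = "control",
                  heat: str = "heat", **test_kwargs) -> dict[str, ContrastResult]:
    """The four line x condition contrasts over a shared gene universe.

    I: sensitive vs tolerant at control; II: the same under heat stress;
    III: heat vs control within the sensitive line; IV: within the
    tolerant line.  Returns {"I": ..., "II": ..., "III": ..., "IV": ...}.
    """
    roles = {"sensitive": sensitive, "tolerant": tolerant,
             "control": control, "heat": heat}
    for line in (sensitive, tolerant):
        for cond in (control, heat):
            if len(cm.group_samples(line, cond)) < 2:
                raise ValueError(
                    f"design cell (line={line!r}, condition={cond!r}) "
                    "is missing or has < 2 replicates"
                )
    sf = size_factors(cm)
    disp = estimate_dispersions(cm, sf)
    out = {}
    for cname, (la, ca), (lb, cb) in CONTRAST_DEFS:
        ga = (roles[la], roles[ca])
        gb = (roles[lb], roles[cb])
        out[cname] = nb_test(cm, (ga, gb), sf=sf, dispersions=disp,
                             name=cname, **test_kwargs)
    return out


def venn_partition(deg_a, deg_b) -> DEGPartition:
    """Partition two DEG sets into common / A-only / B-only.

    Accepts plain gene sets or ContrastResults; with ContrastResults the
    up/down tallies are included and common genes with opposite directions
    in the two contrasts are flagged discordant (kept, not dropped).
    """
    dir_a = dir_b = None
    if isinstance(deg_a, ContrastResult):
        dir_a = deg_a.directions()
        set_a = deg_a.de_genes
    else:
        set_a = set(deg_a)
    if isinstance(deg_b, ContrastResult):
        dir_b = deg_b.directions()
        set_b = deg_b.de_genes
    else:
        set_b = set(deg_b)

    common = set_a & set_b
    part = DEGPartition(common=common, only_a=set_a - set_b, only_b=set_b - set_a)
    if dir_a is not None:
        part.up_down_a = (int((dir_a.loc[list(set_a)] == "up").sum()),
                          int((dir_a.loc[list(set_a)] == "down").sum()))
    if dir_b is not None:
        part.up_down_b = (int((dir_b.loc[list(set_b)] == "up").sum()),
                          int((dir_b.loc[list(set_b)] == "down").sum()))
    if dir_a is not None and dir_b is not None and common:
        cl = sorted(common)
        da, db = dir_a.loc[cl], dir_b.loc[cl]
        part.discordant = set(np.array(cl)[(da.values != db.values)])
        if part.discordant:
            warnings.warn(
                f"{len(part.discordant)} common DEGs have discordant "
                "direction between the two contrasts", stacklevel=2,
            )
    return part


def fpkm(cm: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM[g, j] = counts[g, j] * 1e9 / (length_bp[g] * total_counts[j]).
    """
    if cm.gene_lengths is None:
        raise ValueError("gene_lengths required for FPKM")
    lengths = cm.gene_lengths.to_numpy(float)
    if np.any(~np.isfinite(lengths)) or np.any(lengths <= 0):
        raise ValueError("gene_lengths must be positive for all genes")
    totals = cm.counts.sum(axis=0).to_numpy(float)
    vals = cm.counts.to_numpy(float) * 1e9 / (lengths[:, None] * totals[None, :])
    return pd.DataFrame(vals, index=cm.genes, columns=cm.counts.columns)
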
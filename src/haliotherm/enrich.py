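"""Category enrichment and family/pathway summary tables.

GO-style enrichment corrects for gene-length bias: longer transcripts
accumulate more reads and are detected as DE more readily, so the
detection probability is modelled as a monotone function of length (the
probability weighting function, PWF) and category enrichment is tested
under the Wallenius non-central hypergeometric distribution with the
category's mean weight as the odds.  KEGG-style enrichment uses the
central hypergeometric.  Family/pathway summaries reproduce the layout of
the study's HSP (Table 1) and cell-cycle/DNA-replication (Table 2) tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .de import ContrastResult
from .fixtures import FixtureTable, table2_pathway_sets

__all__ = [
    "Annotation",
    "fit_pwf",
    "wallenius_enrichment",
    "hypergeom_enrichment",
    "family_summary",
    "pathway_updown_counts",
    "family_summary_from_table",
    "pathway_updown_counts_from_table",
]

_WEIGHT_CLIP = (1e-6, 1.0 - 1e-6)


@dataclass
class Annotation:
    """Gene annotation: flat category sets, family labels, lengths (bp)."""

    categories: dict[str, set] = field(default_factory=dict)  # gene -> categories
    families: pd.Series | None = None                          # gene -> family
    lengths: pd.Series | None = None                           # gene -> bp

    def __post_init__(self):
        if self.lengths is not None and (self.lengths.dropna() <= 0).any():
            raise ValueError("gene lengths must be positive")

    def category_map(self) -> dict[str, set]:
        """Invert to category -> gene set."""
        out: dict[str, set] = {}
        for g, cats in self.categories.items():
            for c in cats:
                out.setdefault(c, set()).add(g)
        return out


def fit_pwf(de_flags: pd.Series, lengths: pd.Series,
            n_bins: int = 30) -> pd.Series:
    """Monotone probability-weighting function P(DE | length).

    Genes are split into equal-count length bins; the per-bin DE
    proportion is smoothed by increasing isotonic regression on the bin
    median lengths and interpolated back to each gene.  Weights are
    clipped to (1e-6, 1 - 1e-6).
    """
    common = de_flags.index.intersection(lengths.dropna().index)
    if len(common) < 50:
        raise ValueError("need at least 50 genes with lengths to fit the PWF")
    de = de_flags.loc[common].astype(bool)
    ln = lengths.loc[common].astype(float)
    frac = de.mean()
    if frac in (0.0, 1.0):
        warnings.warn("all genes share DE status: flat weights", stacklevel=2)
        w = np.clip(frac if frac > 0 else 1.0 / len(common), *_WEIGHT_CLIP)
        return pd.Series(w, index=de_flags.index, name="pwf")

    order = ln.sort_values().index
    bins = np.array_split(np.arange(len(order)), min(n_bins, len(order) // 5))
    bx, by = [], []
    for b in bins:
        idx = order[b]
        bx.append(float(ln.loc[idx].median()))
        by.append(float(de.loc[idx].mean()))
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(bx, by)
    w = np.clip(iso.predict(ln.loc[de_flags.index].fillna(ln.median())),
                *_WEIGHT_CLIP)
    return pd.Series(w, index=de_flags.index, name="pwf")


def _counts_frame(category_map, universe, de_set):
    rows = []
    for cat, genes in category_map.items():
        members = set(genes) & universe
        if not members:
            warnings.warn(f"category {cat!r} disjoint from universe; skipped",
                          stacklevel=3)
            continue
        rows.append((cat, members))
    return rows


def wallenius_enrichment(de_set, category_map: dict, weights: pd.Series,
                         ) -> pd.DataFrame:
    """Length-bias-aware enrichment under the Wallenius distribution.

    For each category, odds = mean PWF weight inside / mean weight
    outside, and p = P(X >= n_de_in_cat) for X ~ Wallenius NCHG with
    population (n_cat, n_universe - n_cat), n_de draws and that odds.
    The universe is the index of ``weights``.
    """
    universe = set(weights.index)
    de_set = set(de_set) & universe
    n_uni, n_de = len(universe), len(de_set)
    rows = []
    for cat, members in _counts_frame(category_map, universe, de_set):
        n_cat = len(members)
        k = len(members & de_set)
        w_in = float(weights.loc[sorted(members)].mean())
        outside = universe - members
        if outside:
            w_out = float(weights.loc[sorted(outside)].mean())
            odds = w_in / w_out
        else:
            odds = 1.0
        if n_cat == n_uni:
            p = 1.0
        else:
            p = float(stats.nchypergeom_wallenius.sf(
                k - 1, n_uni, n_cat, n_de, odds))
        rows.append({"category": cat, "n_de_in_cat": k, "n_cat": n_cat,
                     "n_de": n_de, "n_universe": n_uni, "odds": odds,
                     "p_wallenius": min(max(p, 0.0), 1.0)})
    cols = ["category", "n_de_in_cat", "n_cat", "n_de", "n_universe",
            "odds", "p_wallenius"]
    return pd.DataFrame(rows, columns=cols).set_index("category")\
        .sort_values("p_wallenius")


def hypergeom_enrichment(de_set, category_map: dict, universe,
                         adjust: bool = True) -> pd.DataFrame:
    """Central hypergeometric (KEGG-style) enrichment with optional BH
    adjustment across categories."""
    universe = set(universe)
    de_set = set(de_set) & universe
    n_uni, n_de = len(universe), len(de_set)
    rows = []
    for cat, members in _counts_frame(category_map, universe, de_set):
        n_cat = len(members)
        k = len(members & de_set)
        p = float(stats.hypergeom.sf(k - 1, n_uni, n_cat, n_de))
        rows.append({"category": cat, "n_de_in_cat": k, "n_cat": n_cat,
                     "n_de": n_de, "n_universe": n_uni,
                     "p_hypergeom": min(max(p, 0.0), 1.0)})
    cols = ["category", "n_de_in_cat", "n_cat", "n_de", "n_universe",
            "p_hypergeom"]
    out = pd.DataFrame(rows, columns=cols).set_index("category")
    if adjust and len(out):
        out["padj"] = stats.false_discovery_control(
            out["p_hypergeom"].to_numpy(), method="bh")
    return out.sort_values("p_hypergeom")


def _member_lfc(contrast: ContrastResult, genes):
    t = contrast.table
    de = t["de_flag"].reindex(genes, fill_value=False)
    lfc = t["log2_fc"].reindex(genes)
    return de, lfc


def family_summary(contrast_a: ContrastResult, contrast_b: ContrastResult,
                   annotation: Annotation, family: str) -> dict:
    """Partition a gene family's DEGs between two contrasts.

    Members are split into both / a_only / b_only by DE status; each
    line's mean log2 FC is taken over that line's own DE family members
    (signed; set ``absolute=True`` on the caller side by passing |lfc| if
    needed).  Returns a dict with the member table, partition counts and
    per-contrast means.
    """
    if annotation.families is None:
        raise ValueError("annotation has no family labels")
    members = list(annotation.families.index[annotation.families == family])
    if not members:
        warnings.warn(f"family {family!r} absent from annotation", stacklevel=2)
        return {"table": pd.DataFrame(), "counts": {"both": 0, "a_only": 0,
                "b_only": 0}, "mean_log2fc": {}}
    de_a, lfc_a = _member_lfc(contrast_a, members)
    de_b, lfc_b = _member_lfc(contrast_b, members)
    membership = np.select(
        [de_a & de_b, de_a & ~de_b, ~de_a & de_b],
        ["both", "a_only", "b_only"], default="ns")
    table = pd.DataFrame({
        "membership": membership,
        f"log2fc_{contrast_a.name}": lfc_a.values,
        f"log2fc_{contrast_b.name}": lfc_b.values,
    }, index=pd.Index(members, name="gene_id"))
    table = table[table["membership"] != "ns"]
    counts = {k: int((table["membership"] == k).sum())
              for k in ("both", "a_only", "b_only")}
    return {
        "table": table,
        "counts": counts,
        "mean_log2fc": {
            contrast_a.name: float(lfc_a[de_a].mean()) if de_a.any() else np.nan,
            contrast_b.name: float(lfc_b[de_b].mean()) if de_b.any() else np.nan,
        },
    }


def pathway_updown_counts(contrast_a: ContrastResult,
                          contrast_b: ContrastResult,
                          annotation: Annotation, pathway: str,
                          direction: str = "down") -> dict[str, int]:
    """Count pathway members DE in the given direction, per contrast."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    key = pathway.strip().lower()
    members = [g for g, cats in annotation.categories.items()
               if key in {c.strip().lower() for c in cats}]
    if not members:
        warnings.warn(f"pathway {pathway!r} absent from annotation",
                      stacklevel=2)
        return {contrast_a.name: 0, contrast_b.name: 0}
    out = {}
    for c in (contrast_a, contrast_b):
        d = c.directions().reindex(members, fill_value="ns")
        out[c.name] = int((d == direction).sum())
    return out


def family_summary_from_table(table1: FixtureTable) -> dict:
    """Partition counts and per-line mean log2 FC from the packaged HSP
    table (each line averaged over its own DE members)."""
    df = table1.frame
    counts = table1.membership_counts()
    return {
        "counts": counts,
        "mean_log2fc": {
            "RL": float(df["log2fc_RL"].dropna().mean()),
            "YL": float(df["log2fc_YL"].dropna().mean()),
        },
        "n_de": {
            "RL": int(df["log2fc_RL"].notna().sum()),
            "YL": int(df["log2fc_YL"].notna().sum()),
        },
    }


def pathway_updown_counts_from_table(table2: FixtureTable, pathway: str,
                                     direction: str = "down") -> dict[str, int]:
    """Per-line directional DE counts for one pathway of the packaged
    cell-cycle / DNA-replication table."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    sets = table2_pathway_sets(table2)
    key = pathway.strip().lower()
    members = sets.index[sets.map(lambda s: key in s)]
    df = table2.frame.set_index("gene_id").loc[members]
    out = {}
    for line in ("RL", "YL"):
        lfc = df[f"log2fc_{line}"].dropna()
        out[line] = int((lfc < 0).sum() if direction == "down"
                        else (lfc > 0).sum())
    return out
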
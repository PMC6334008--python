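"""Length-bias weighting, Wallenius and hypergeometric enrichment (with
exact enumeration oracles), and the family/pathway summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from haliotherm.de import ContrastResult
from haliotherm.enrich import (
    Annotation,
    family_summary,
    family_summary_from_table,
    fit_pwf,
    hypergeom_enrichment,
    pathway_updown_counts,
    pathway_updown_counts_from_table,
    wallenius_enrichment,
)
from haliotherm.fixtures import load_fixture


def wallenius_tail_enumeration(k, n_cat, n_out, n_draws, odds):
    """Exact upper tail by summing over every ordered sequence of draws
    from a two-weight urn (category weight ``odds``, others 1)."""
    items = ["c"] * n_cat + ["o"] * n_out
    total = 0.0
    for seq in itertools.permutations(range(len(items)), n_draws):
        prob = 1.0
        w_left = odds * n_cat + n_out
        x = 0
        for i in seq:
            w = odds if items[i] == "c" else 1.0
            prob *= w / w_left
            w_left -= w
            if items[i] == "c":
                x += 1
        if x >= k:
            total += prob
    return total


class TestPWF:
    def _lengths(self, rng, n=400):
        return pd.Series(rng.integers(200, 10000, n),
                         index=[f"g{i}" for i in range(n)], dtype=float)

    def test_null_bias_flat_weights(self, rng):
        lengths = self._lengths(rng)
        de = pd.Series(rng.random(len(lengths)) < 0.2, index=lengths.index)
        w = fit_pwf(de, lengths)
        assert w.std() < 0.1
        assert w.mean() == pytest.approx(de.mean(), abs=0.05)

    def test_constructed_bias_recovered(self):
        """P(DE) doubles across the length range; the fitted weights are
        monotone with about that end-to-end ratio."""
        rng = np.random.default_rng(12)
        n = 4000
        lengths = pd.Series(np.linspace(500, 8000, n),
                            index=[f"g{i}" for i in range(n)])
        p = 0.1 * (1 + (lengths - 500) / 7500)   # 0.1 -> 0.2
        de = pd.Series(rng.random(n) < p.values, index=lengths.index)
        w = fit_pwf(de, lengths)
        by_len = w.groupby(pd.qcut(lengths, 4, labels=False)).mean()
        assert by_len.iloc[-1] / by_len.iloc[0] == pytest.approx(2.0, rel=0.3)

    def test_monotone_in_length(self, rng):
        lengths = self._lengths(rng)
        de = pd.Series(rng.random(len(lengths)) < 0.15, index=lengths.index)
        w = fit_pwf(de, lengths)
        order = lengths.sort_values().index
        assert (np.diff(w.loc[order]) >= -1e-12).all()

    def test_degenerate_de_status_warns(self, rng):
        lengths = self._lengths(rng, 100)
        de = pd.Series(False, index=lengths.index)
        with pytest.warns(UserWarning, match="flat"):
            w = fit_pwf(de, lengths)
        assert w.nunique() == 1

    def test_too_few_genes_rejected(self):
        lengths = pd.Series([100.0] * 10, index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError, match="50"):
            fit_pwf(pd.Series(True, index=lengths.index), lengths)


class TestWallenius:
    def test_equal_weights_reduce_to_hypergeometric(self, rng):
        genes = [f"g{i}" for i in range(60)]
        weights = pd.Series(0.25, index=genes)
        for _ in range(20):
            cat = set(rng.choice(genes, rng.integers(3, 30), replace=False))
            de = set(rng.choice(genes, rng.integers(3, 30), replace=False))
            w = wallenius_enrichment(de, {"c": cat}, weights)
            h = hypergeom_enrichment(de, {"c": cat}, set(genes), adjust=False)
            assert w.loc["c", "p_wallenius"] == pytest.approx(
                h.loc["c", "p_hypergeom"], abs=1e-6)

    def test_tiny_instance_matches_enumeration(self):
        """Universe of 6, category of 3, 3 draws: the Wallenius tail
        equals exhaustive enumeration over weighted ordered draws."""
        genes = [f"g{i}" for i in range(6)]
        cat = set(genes[:3])
        for odds in (0.5, 1.0, 2.0, 3.0):
            weights = pd.Series([0.2 * odds] * 3 + [0.2] * 3, index=genes)
            de = set(genes[1:4])   # 2 in category
            w = wallenius_enrichment(de, {"c": cat}, weights)
            # odds recomputed from weights must equal the construction
            assert w.loc["c", "odds"] == pytest.approx(odds)
            expect = wallenius_tail_enumeration(2, 3, 3, 3, odds)
            assert w.loc["c", "p_wallenius"] == pytest.approx(expect, abs=1e-8)

    def test_tail_p_increases_with_odds(self):
        # a higher category weight makes large DE counts in the category
        # less surprising under the null, so the upper-tail p grows
        ps = [float(stats.nchypergeom_wallenius.sf(4, 100, 20, 30, o))
              for o in (0.5, 1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(ps, ps[1:]))

    def test_minimal_p_when_all_category_de(self, rng):
        genes = [f"g{i}" for i in range(40)]
        weights = pd.Series(0.3, index=genes)
        cat = set(genes[:8])
        p_all = wallenius_enrichment(cat, {"c": cat}, weights)
        for _ in range(10):
            de = set(rng.choice(genes, 8, replace=False))
            p = wallenius_enrichment(de, {"c": cat}, weights)
            assert p_all.loc["c", "p_wallenius"] <= \
                p.loc["c", "p_wallenius"] + 1e-12

    def test_disjoint_category_skipped(self, rng):
        genes = [f"g{i}" for i in range(20)]
        weights = pd.Series(0.5, index=genes)
        with pytest.warns(UserWarning, match="disjoint"):
            out = wallenius_enrichment({genes[0]}, {"gone": {"zz"}}, weights)
        assert len(out) == 0


class TestHypergeom:
    def test_category_equals_universe(self):
        genes = [f"g{i}" for i in range(10)]
        out = hypergeom_enrichment(set(genes[:3]), {"all": set(genes)},
                                   set(genes), adjust=False)
        assert out.loc["all", "p_hypergeom"] == pytest.approx(1.0)

    def test_direct_summation_oracle(self):
        # 100 genes, 10 DE; category of 10 with 5 DE
        p = hypergeom_enrichment(
            {f"g{i}" for i in range(10)},
            {"c": {f"g{i}" for i in range(5)} | {f"x{i}" for i in range(5)}},
            {f"g{i}" for i in range(10)} | {f"x{i}" for i in range(90)},
            adjust=False).loc["c", "p_hypergeom"]
        direct = sum(stats.hypergeom.pmf(k, 100, 10, 10) for k in range(5, 11))
        assert p == pytest.approx(direct, abs=1e-12)

    def test_relabeling_invariance(self, rng):
        genes = [f"g{i}" for i in range(30)]
        cat = set(genes[:10])
        de = set(genes[5:15])
        p1 = hypergeom_enrichment(de, {"c": cat}, set(genes), adjust=False)
        relabel = {g: f"r{i}" for i, g in enumerate(genes)}
        p2 = hypergeom_enrichment({relabel[g] for g in de},
                                  {"c": {relabel[g] for g in cat}},
                                  set(relabel.values()), adjust=False)
        assert p1.loc["c", "p_hypergeom"] == p2.loc["c", "p_hypergeom"]


def _contrast_from(genes, de, lfc, name):
    de = pd.Series(de, index=genes)
    table = pd.DataFrame({
        "base_mean_a": 100.0, "base_mean_b": 100.0,
        "log2_fc": pd.Series(lfc, index=genes),
        "p_value": np.where(de, 1e-4, 0.5),
        "de_flag": de,
        "direction": np.select([de & (pd.Series(lfc, index=genes) > 0),
                                de & (pd.Series(lfc, index=genes) < 0)],
                               ["up", "down"], default="ns"),
        "in_universe": True,
    }, index=pd.Index(genes, name="gene_id"))
    return ContrastResult(name=name, group_a="a", group_b="b", table=table)


class TestFamilyAndPathwaySummaries:
    def test_fixture_partition_and_means(self):
        t1 = load_fixture("table1")
        out = family_summary_from_table(t1)
        assert out["counts"] == {"both": 20, "RL_only": 11, "YL_only": 4}
        assert out["n_de"] == {"RL": 31, "YL": 24}
        # each line's average over its own DE members, vs the reported
        # rounded values
        assert out["mean_log2fc"]["YL"] == pytest.approx(7.0, abs=0.2)
        assert out["mean_log2fc"]["RL"] == pytest.approx(5.4, abs=0.2)

    def test_fixture_mean_matches_hand_computation(self):
        df = load_fixture("table1").frame
        hand = df["log2fc_RL"].dropna().sum() / df["log2fc_RL"].notna().sum()
        assert family_summary_from_table(
            load_fixture("table1"))["mean_log2fc"]["RL"] == pytest.approx(hand)

    def test_cell_cycle_downregulation_counts(self):
        t2 = load_fixture("table2")
        assert pathway_updown_counts_from_table(t2, "cell cycle", "down") \
            == {"RL": 9, "YL": 5}
        assert pathway_updown_counts_from_table(t2, "cell cycle", "up") \
            == {"RL": 0, "YL": 0}

    def test_contrast_family_partition(self):
        genes = ["h1", "h2", "h3", "x1"]
        a = _contrast_from(genes, [True, True, False, False],
                           [2.0, 3.0, 0.0, 0.0], "III")
        b = _contrast_from(genes, [True, False, True, False],
                           [2.5, 0.0, -1.5, 0.0], "IV")
        ann = Annotation(families=pd.Series(
            {"h1": "HSP", "h2": "HSP", "h3": "HSP", "x1": "other"}))
        out = family_summary(a, b, ann, "HSP")
        assert out["counts"] == {"both": 1, "a_only": 1, "b_only": 1}
        assert out["mean_log2fc"]["III"] == pytest.approx(2.5)

    def test_one_gene_family_in_both(self):
        genes = ["h1"]
        a = _contrast_from(genes, [True], [2.0], "III")
        b = _contrast_from(genes, [True], [2.0], "IV")
        ann = Annotation(families=pd.Series({"h1": "HSP"}))
        assert family_summary(a, b, ann, "HSP")["counts"] == \
            {"both": 1, "a_only": 0, "b_only": 0}

    def test_absent_family_warns_empty(self):
        genes = ["g1"]
        a = _contrast_from(genes, [True], [2.0], "III")
        b = _contrast_from(genes, [False], [0.0], "IV")
        ann = Annotation(families=pd.Series({"g1": "HSP"}))
        with pytest.warns(UserWarning, match="absent"):
            out = family_summary(a, b, ann, "nope")
        assert out["table"].empty

    def test_pathway_counts_from_contrasts(self):
        genes = ["c1", "c2", "c3"]
        a = _contrast_from(genes, [True, True, False], [-2, -3, 0], "III")
        b = _contrast_from(genes, [True, False, False], [-2, 0, 0], "IV")
        ann = Annotation(categories={"c1": {"Cell cycle"},
                                     "c2": {"Cell cycle", "DNA replication"},
                                     "c3": {"DNA replication"}})
        out = pathway_updown_counts(a, b, ann, "cell cycle", "down")
        assert out == {"III": 2, "IV": 1}
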
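"""Evaluation statistics: eFDR, agreement, top-N concordance, truth metrics,
two-way ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from debench.evaluation import (
    ComparisonCounts,
    agreement,
    anova_sensitivity,
    efdr,
    run_comparisons,
    topn_agreement,
    truth_metrics,
)
from debench.filters import CallSet, FilterSpec
from tests.conftest import make_de_table


def cs(label, **genes):
    return CallSet(label=label, genes=genes)


class TestEFDR:
    def test_printed_formula(self):
        value, defined = efdr(ComparisonCounts(("1", "2"), 100, 100, 1000, 1000))
        assert defined and value == pytest.approx(0.1)

    def test_perfect_specificity(self):
        value, defined = efdr(ComparisonCounts(("1", "2"), 0, 0, 500, 300))
        assert defined and value == 0.0

    def test_zero_denominator_flagged(self):
        value, defined = efdr(ComparisonCounts(("1", "2"), 50, 70, 0, 0))
        assert not defined and np.isnan(value)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ComparisonCounts(("1", "2"), -1, 0, 0, 0)


class TestAgreement:
    def test_identical_sets(self):
        s = cs("x", g1="up", g2="down")
        assert agreement(s, s).agreement == 1.0

    def test_disjoint_sets(self):
        assert agreement(cs("a", g1="up"), cs("b", g2="up")).agreement == 0.0

    def test_direction_rule_enumeration(self):
        """g3 is called in both lists with opposite directions: it stays in
        the union (4 genes) but not the intersection ({g2}) -> 0.25."""
        s1 = cs("a", g1="up", g2="up", g3="up")
        s2 = cs("b", g2="up", g3="down", g4="up")
        res = agreement(s1, s2)
        assert res.n_union == 4
        assert res.n_consistent_intersection == 1
        assert res.agreement == pytest.approx(0.25)

    def test_both_empty_is_perfect(self):
        assert agreement(cs("a"), cs("b")).agreement == 1.0

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        genes1 = {f"g{i}": rng.choice(["up", "down"]) for i in rng.integers(0, 50, 20)}
        genes2 = {f"g{i}": rng.choice(["up", "down"]) for i in rng.integers(0, 50, 20)}
        a = agreement(CallSet("a", genes1), CallSet("b", genes2))
        b = agreement(CallSet("b", genes2), CallSet("a", genes1))
        assert a.agreement == b.agreement


class TestTopN:
    def _table(self, gene_lfc):
        genes = list(gene_lfc)
        return make_de_table(
            genes,
            log2fc=[gene_lfc[g] for g in genes],
            qvalue=[0.001] * len(genes),
            ave_expr=list(range(len(genes))),
        )

    def test_identical_lists(self):
        t = self._table({"a": -5, "b": -4, "c": -3})
        res = topn_agreement(t, t, FilterSpec(), 3)
        assert res.agreement == 1.0

    def test_enumerated_top3(self):
        """Top-3 lists (g5,g2,g9) vs (g2,g9,g7), all concordant -> 2/3."""
        t1 = self._table({"g5": -8, "g2": -7, "g9": -6, "g7": -2})
        t2 = self._table({"g2": -9, "g9": -8, "g7": -7, "g5": -2})
        res = topn_agreement(t1, t2, FilterSpec(), 3)
        assert res.agreement == pytest.approx(2 / 3)

    def test_empty_second_list(self):
        t1 = self._table({"a": -5})
        t2 = make_de_table(["a"], [-5.0], [0.9])  # fails the q filter
        assert topn_agreement(t1, t2, FilterSpec(), 5).agreement == 0.0

    def test_short_lists_divided_by_n(self):
        t = self._table({"a": -5, "b": -4})
        assert topn_agreement(t, t, FilterSpec(), 4).agreement == pytest.approx(0.5)

    def test_discordant_direction_excluded(self):
        t1 = self._table({"a": -5, "b": -4})
        t2 = self._table({"a": 5, "b": -4})
        assert topn_agreement(t1, t2, FilterSpec(), 2).agreement == pytest.approx(0.5)

    def test_deterministic_tie_break(self):
        t = make_de_table(
            ["z", "y", "x"], [-2.0, -2.0, -2.0], [0.001] * 3, ave_expr=[1.0, 1.0, 5.0]
        )
        res = topn_agreement(t, t, FilterSpec(), 2)
        assert res.agreement == 1.0

    def test_n_validation(self):
        t = self._table({"a": -5})
        with pytest.raises(ValueError):
            topn_agreement(t, t, FilterSpec(), 0)

    def test_range_invariant(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            t1 = self._table({f"g{i}": -rng.random() * 5 for i in range(20)})
            t2 = self._table({f"g{i}": -rng.random() * 5 for i in range(20)})
            for n in (1, 5, 50):
                assert 0.0 <= topn_agreement(t1, t2, FilterSpec(), n).agreement <= 1.0


class TestRunComparisons:
    def _callsets(self, sites, per_comparison):
        sets = {}
        for s in sites:
            sets[("intra", s)] = per_comparison.get(("intra", s), cs(f"i{s}"))
        for s1, s2 in itertools.combinations(sites, 2):
            for key in [(s1, "A", s2, "A"), (s1, "C", s2, "C"),
                        (s1, "A", s2, "C"), (s2, "A", s1, "C")]:
                sets[key] = per_comparison.get(key, cs(str(key)))
        return sets

    def test_six_sites_give_15_pairs(self):
        sites = [str(i) for i in range(1, 7)]
        pair_df, intra_df = run_comparisons(self._callsets(sites, {}), sites)
        assert len(pair_df) == 15
        assert len(intra_df) == 6

    def test_two_site_manual_tally(self):
        sites = ["1", "2"]
        special = {
            ("1", "A", "2", "A"): cs("aa", g1="up", g2="down"),
            ("1", "C", "2", "C"): cs("cc", g3="up"),
            ("1", "A", "2", "C"): cs("ac", **{f"g{i}": "down" for i in range(10)}),
            ("2", "A", "1", "C"): cs("ca", **{f"g{i}": "down" for i in range(20)}),
            ("intra", "1"): cs("i1", g1="down"),
        }
        pair_df, intra_df = run_comparisons(self._callsets(sites, special), sites)
        row = pair_df.iloc[0]
        assert (row["a1_vs_a2"], row["c1_vs_c2"], row["a1_vs_c2"], row["a2_vs_c1"]) == (2, 1, 10, 20)
        assert row["efdr"] == pytest.approx(3 / 30)
        assert intra_df.set_index("site").loc["1", "n_calls"] == 1

    def test_symmetric_site_copies(self):
        sites = ["1", "2"]
        same = cs("x", **{f"g{i}": "down" for i in range(7)})
        special = {("1", "A", "2", "C"): same, ("2", "A", "1", "C"): same}
        pair_df, _ = run_comparisons(self._callsets(sites, special), sites)
        assert pair_df.iloc[0]["a1_vs_c2"] == pair_df.iloc[0]["a2_vs_c1"]

    def test_missing_comparison_named(self):
        sites = ["1", "2"]
        sets = self._callsets(sites, {})
        del sets[("1", "C", "2", "C")]
        with pytest.raises(KeyError, match="C"):
            run_comparisons(sets, sites)


class TestTruthMetrics:
    truth = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(20)],
            "true_log2fc": [-3.0] * 10 + [0.0] * 10,
            "is_de": [True] * 10 + [False] * 10,
        }
    )

    def test_perfect_calls(self):
        calls = cs("x", **{f"g{i}": "down" for i in range(10)})
        m = truth_metrics(calls, self.truth)
        assert m["fdr"] == 0.0
        assert m["sensitivity"] == 1.0

    def test_all_null_calls(self):
        calls = cs("x", **{f"g{i}": "down" for i in range(10, 20)})
        m = truth_metrics(calls, self.truth)
        assert m["fdr"] == 1.0
        assert m["sensitivity"] == 0.0

    def test_planted_fraction(self):
        genes = {f"g{i}": "down" for i in range(8)}
        genes.update({"g15": "down", "g16": "down"})  # 2 nulls among 10 calls
        m = truth_metrics(cs("x", **genes), self.truth)
        assert m["fdr"] == pytest.approx(0.2)

    def test_wrong_direction_not_sensitive(self):
        calls = cs("x", **{f"g{i}": "up" for i in range(10)})
        assert truth_metrics(calls, self.truth)["sensitivity"] == 0.0

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError, match="g99"):
            truth_metrics(cs("x", g99="down"), self.truth)


class TestAnova:
    def _table(self, fn):
        rows = []
        for v in ("v1", "v2"):
            for c in ("c1", "c2"):
                for s in ("1", "2", "3"):
                    rows.append({"variant": v, "caller": c, "site": s,
                                 "n_calls": fn(v, c, s)})
        return pd.DataFrame(rows)

    def test_constant_table_zero_ss(self):
        res = anova_sensitivity(self._table(lambda v, c, s: 100.0))
        assert res.loc["variant", "sum_sq"] == pytest.approx(0.0, abs=1e-8)
        assert res.loc["caller", "sum_sq"] == pytest.approx(0.0, abs=1e-8)

    def test_additive_fixture_matches_closed_form(self):
        """Balanced additive 2x2x3 layout: SS_A = r*b*sum_a (mean_a - mean)^2
        and symmetrically for B; residual SS = 0."""
        effects_v = {"v1": 0.0, "v2": 40.0}
        effects_c = {"c1": 0.0, "c2": 10.0}
        table = self._table(lambda v, c, s: 100.0 + effects_v[v] + effects_c[c])
        res = anova_sensitivity(table)
        # 3 sites x 2 caller levels replicate each variant level
        ss_v = 6 * sum((x - 20.0) ** 2 for x in effects_v.values())
        ss_c = 6 * sum((x - 5.0) ** 2 for x in effects_c.values())
        assert res.loc["variant", "sum_sq"] == pytest.approx(ss_v)
        assert res.loc["caller", "sum_sq"] == pytest.approx(ss_c)
        assert res.loc["residual", "sum_sq"] == pytest.approx(0.0, abs=1e-8)

    def test_caller_permutation_leaves_variant_ss(self):
        rng = np.random.default_rng(5)
        noise = {(v, c, s): rng.normal(0, 5) for v in ("v1", "v2")
                 for c in ("c1", "c2") for s in ("1", "2", "3")}
        table = self._table(lambda v, c, s: 100 + (30 if v == "v2" else 0) + noise[(v, c, s)])
        res1 = anova_sensitivity(table)
        swapped = table.assign(caller=table["caller"].map({"c1": "c2", "c2": "c1"}))
        res2 = anova_sensitivity(swapped)
        assert res1.loc["variant", "sum_sq"] == pytest.approx(res2.loc["variant", "sum_sq"])

    def test_incomplete_layout_rejected(self):
        table = self._table(lambda v, c, s: 1.0).iloc[:-2]
        with pytest.raises(ValueError, match="layout"):
            anova_sensitivity(table)
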
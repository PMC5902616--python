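"""Fisher enrichment, over-representation, occupation ratios and ECDFs."""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import pytest

from pancanhub import enrichment_stats as es
from pancanhub import hub_psg
from pancanhub.io_formats import ExpressionMatrix, GeneSetCollection
from pancanhub.ppi_network import Complex


def hypergeom_upper_tail_oracle(a, n_target, n_flag, n_universe):
    """Exact upper tail by full enumeration over feasible tables."""
    total = comb(n_universe, n_target)
    num = sum(
        comb(n_flag, x) * comb(n_universe - n_flag, n_target - x)
        for x in range(a, min(n_flag, n_target) + 1)
    )
    return num / total


class TestFisher:
    def test_matches_enumeration_oracle_exhaustively(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            n_universe = int(rng.integers(4, 61))
            n_target = int(rng.integers(1, n_universe))
            n_flag = int(rng.integers(1, n_universe))
            a_max = min(n_target, n_flag)
            a_min = max(0, n_target + n_flag - n_universe)
            a = int(rng.integers(a_min, a_max + 1))
            res = es.fisher_from_counts(a, n_target, n_flag, n_universe)
            expected = hypergeom_upper_tail_oracle(a, n_target, n_flag, n_universe)
            assert res.p_one_tailed == pytest.approx(expected, rel=1e-9, abs=1e-300)

    def test_empty_flag_overlap_gives_p_one(self):
        res = es.fisher_enrichment({"A", "B"}, set(), {"A", "B", "C", "D"})
        assert res.a == 0
        assert res.p_one_tailed == pytest.approx(1.0)

    def test_small_table_hand_value(self):
        # (a,b,c,d) = (3,2,1,4): universe 10, target 5, flag 4
        res = es.fisher_from_counts(3, 5, 4, 10)
        expected = hypergeom_upper_tail_oracle(3, 5, 4, 10)
        assert res.p_one_tailed == pytest.approx(expected, rel=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            es.fisher_from_counts(0, 0, 0, 0)

    def test_odds_ratio_infinite_when_flag_exhausted(self):
        res = es.fisher_from_counts(3, 3, 3, 10)
        assert np.isinf(res.odds_ratio)


class TestEnrichmentBattery:
    @staticmethod
    def _toy_setup(flag_genes, n_network=60, n_universe=200):
        import networkx as nx

        from pancanhub.ppi_network import PPINetwork

        genes = [f"G{i:03d}" for i in range(n_universe)]
        g = nx.Graph()
        for i in range(n_network - 1):
            g.add_edge(genes[i], genes[i + 1], score=950)
        net = PPINetwork(g, set(genes[:20]), set(genes[20:n_network]))
        cx1 = Complex("s", frozenset(genes[:15]), frozenset(), 1.0, 10)
        cx2 = Complex("s2", frozenset(genes[30:45]), frozenset(), 1.0, 10)
        flags = GeneSetCollection({"FLAG": frozenset(flag_genes)})
        return [cx1, cx2], net, set(genes[:30]), set(genes), flags

    def test_flags_planted_in_one_complex_enrich_only_it(self):
        cxs, net, psgs, universe, flags = self._toy_setup(
            [f"G{i:03d}" for i in range(12)]
        )
        table = es.enrichment_battery(cxs, net, psgs, universe, flags)
        c1 = table[table["comparison"] == "complex_1_vs_network"].iloc[0]
        c2 = table[table["comparison"] == "complex_2_vs_network"].iloc[0]
        assert c1["enriched"] and not c2["enriched"]

    def test_empty_flag_set_gives_all_p_one(self):
        cxs, net, psgs, universe, _ = self._toy_setup([])
        flags = GeneSetCollection({"EMPTY": frozenset()})
        table = es.enrichment_battery(cxs, net, psgs, universe, flags)
        assert np.allclose(table["p"], 1.0)

    def test_uniform_flags_false_enrichment_rate_bounded(self):
        # flags planted uniformly at random: the one-tailed test at alpha
        # should flag at most ~alpha of comparisons (discreteness makes the
        # exact test conservative)
        rng = np.random.default_rng(29)
        genes = [f"G{i:03d}" for i in range(400)]
        n_false = 0
        n_tests = 0
        for _ in range(200):
            flag = set(rng.choice(genes, size=40, replace=False))
            target = set(rng.choice(genes, size=80, replace=False))
            res = es.fisher_enrichment(target, flag, set(genes), alpha=0.05)
            n_false += res.enriched
            n_tests += 1
        assert n_false / n_tests <= 0.07


class TestOverRepresentation:
    def test_single_term_equal_to_query_unadjusted(self):
        coll = GeneSetCollection({"T": frozenset({"A", "B"})})
        out = es.over_representation({"A", "B"}, coll, {"A", "B", "C", "D"})
        assert len(out) == 1
        assert out["p_adjusted"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_planted_term_ranks_first_and_significant(self):
        rng = np.random.default_rng(31)
        background = {f"G{i:04d}" for i in range(1000)}
        term = set(sorted(background)[:40])
        query = set(sorted(term)[:20]) | set(
            rng.choice(sorted(background - term), size=10, replace=False)
        )
        decoys = {
            f"D{j}": frozenset(rng.choice(sorted(background), size=40, replace=False))
            for j in range(10)
        }
        coll = GeneSetCollection({"PLANTED": frozenset(term), **decoys})
        out = es.over_representation(query, coll, background)
        assert out["term"].iloc[0] == "PLANTED"
        assert out["p_adjusted"].iloc[0] < 0.05
        oracle = hypergeom_upper_tail_oracle(20, 30, 40, 1000)
        assert out["p"].iloc[0] == pytest.approx(oracle, rel=1e-9)

    def test_bonferroni_factor_counts_reported_terms(self):
        sets = {f"T{i}": frozenset({"A", "B"}) for i in range(20)}
        coll = GeneSetCollection(sets)
        out = es.over_representation({"A", "B"}, coll, {"A", "B", "C", "D", "E"})
        assert len(out) == 20
        np.testing.assert_allclose(
            out["p_adjusted"], np.minimum(1.0, out["p"] * 20)
        )
        assert (out["p_adjusted"] >= out["p"]).all()


class TestOccupation:
    @staticmethod
    def _psgs():
        return hub_psg.integrate_psgs(
            {"D1": {"A", "B", "S"}, "D2": {"C", "S"}, "D3": {"Z"}}
        )

    def test_single_dataset_complex_ratio_one(self):
        psgs = self._psgs()
        cx = Complex("s", frozenset({"A", "B"}), frozenset(), 1.0, 10)
        occ = es.occupation_ratios([cx], psgs)
        assert occ.at["complex_1", "D1"] == pytest.approx(1.0)
        assert occ.loc["complex_1"].sum() == pytest.approx(1.0)

    def test_shared_gene_contributes_half_to_each(self):
        psgs = self._psgs()
        # complex holds A (D1 only), C (D2 only), S (shared by D1, D2)
        cx = Complex("s", frozenset({"A", "C", "S"}), frozenset(), 1.0, 10)
        occ = es.occupation_ratios([cx], psgs)
        assert occ.at["complex_1", "D1"] == pytest.approx((1 + 0.5) / 3)
        assert occ.at["complex_1", "D2"] == pytest.approx((1 + 0.5) / 3)
        assert occ.at["complex_1", "D3"] == 0.0

    def test_rows_sum_to_one_within_tolerance(self, clique_cohort):
        rng = np.random.default_rng(37)
        _, edges, truth = clique_cohort
        from pancanhub import ppi_network as ppin

        g = ppin.threshold_edges(edges)
        cxs = ppin.mcode_complexes(g, fluff=False, kcore_filter=10)
        all_members = sorted(set().union(*(c.members for c in cxs)))
        per_ds = {
            f"D{j}": set(rng.choice(all_members, size=20, replace=False))
            for j in range(4)
        }
        psgs = hub_psg.integrate_psgs(per_ds)
        occ = es.occupation_ratios(cxs, psgs)
        sums = occ.sum(axis=1)
        for name, s in sums.items():
            has_psg = bool(
                set(cxs[int(name.split("_")[1]) - 1].members) & psgs.union
            )
            if has_psg:
                assert abs(s - 1.0) <= 1e-9
            else:
                assert s == 0.0

    def test_no_psg_member_gives_zero_row(self, caplog):
        psgs = self._psgs()
        cx = Complex("s", frozenset({"X", "Y"}), frozenset(), 1.0, 10)
        with caplog.at_level("WARNING"):
            occ = es.occupation_ratios([cx], psgs)
        assert occ.loc["complex_1"].sum() == 0.0


class TestExpressionGroups:
    @staticmethod
    def _matrix(shift_group=None, dataset="DS"):
        rng = np.random.default_rng(41)
        genes = [f"G{i:02d}" for i in range(60)]
        vals = rng.lognormal(0, 1, size=(60, 10))
        groups = {g: ("representor" if i < 20 else "interactor" if i < 40 else "other")
                  for i, g in enumerate(genes)}
        if shift_group:
            mask = [groups[g] == shift_group for g in genes]
            vals[mask] *= 10.0  # +1 in log10
        df = pd.DataFrame(vals, index=genes, columns=[f"S{j}" for j in range(10)])
        return ExpressionMatrix(dataset, df, {}), groups

    def test_identical_groups_ks_zero(self):
        em, groups = self._matrix()
        em.values.iloc[:, :] = 1.0
        out = es.expression_group_summary([em], groups)
        ks_rows = out[out["group"].str.startswith("KS(")]
        assert np.allclose(ks_rows["median_log10"], 0.0)

    def test_shifted_group_dominates(self):
        em, groups = self._matrix(shift_group="representor")
        out = es.expression_group_summary([em], groups)
        med = out.set_index("group")["median_log10"]
        assert med["representor"] > med["interactor"]
        ks = out[out["group"] == "KS(interactor,representor)"]["median_log10"].iloc[0]
        assert ks > 0.8

    def test_pseudo_count_keeps_zeros_finite(self):
        em, groups = self._matrix()
        em.values.iloc[0, :] = 0.0
        out = es.expression_group_summary([em], groups, pseudo=1e-3)
        assert np.isfinite(out["median_log10"]).all()


def test_ecdf_definition():
    x, y = es.ecdf([3.0, 1.0, 2.0])
    np.testing.assert_array_equal(x, [1.0, 2.0, 3.0])
    np.testing.assert_allclose(y, [1 / 3, 2 / 3, 1.0])
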
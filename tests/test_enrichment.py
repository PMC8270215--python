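import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netindic import enrichment
from netindic.disease_module import ExpansionTrace

from conftest import make_catalog, make_entry, subnet
from helpers import hyper_tail_exact


class TestOverlapPvalue:
    def test_disjoint_sets_p_one(self):
        t, d = subnet({"a", "b"}), subnet({"c", "d"})
        assert enrichment.overlap_pvalue(t, d, 20) == pytest.approx(1.0)

    def test_hand_enumeration(self):
        # universe 20, |target| 5, |disease| 4, overlap 3
        t = subnet({"t1", "t2", "t3", "x1", "x2"})
        d = subnet({"t1", "t2", "t3", "y"})
        p = enrichment.overlap_pvalue(t, d, 20)
        assert p == pytest.approx(155 / 4845)

    def test_target_whole_universe_p_one(self):
        t = subnet({f"n{i}" for i in range(10)})
        d = subnet({"n1", "n2"})
        assert enrichment.overlap_pvalue(t, d, 10) == pytest.approx(1.0)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            enrichment.overlap_pvalue(subnet(set()), subnet({"a"}), 10)

    def test_universe_too_small_errors(self):
        with pytest.raises(ValueError):
            enrichment.overlap_pvalue(subnet({"a", "b"}), subnet({"c"}), 2)

    def test_nonincreasing_in_overlap(self):
        universe = 30
        prev = 1.1
        for k in range(6):
            t = {f"t{i}" for i in range(5)}
            d = {f"t{i}" for i in range(k)} | {f"d{i}" for i in range(6 - k)}
            p = enrichment.overlap_pvalue(subnet(t), subnet(d), universe)
            assert p <= prev + 1e-12
            prev = p


class TestWeightedOverlapPvalue:
    def test_no_seeds_reduces_to_plain(self):
        t, d = subnet({"a", "b", "c"}), subnet({"b", "c", "x"})
        assert enrichment.weighted_overlap_pvalue(t, d, 25) == pytest.approx(
            enrichment.overlap_pvalue(t, d, 25)
        )

    def test_seed_hits_more_extreme(self):
        t = subnet({"a", "b", "c", "d", "e"})
        hit_seeds = subnet({"a", "b", "x", "y", "z", "w"}, origins={"a", "b"})
        hit_others = subnet({"a", "b", "x", "y", "z", "w"}, origins={"x", "y"})
        universe = 30
        assert enrichment.weighted_overlap_pvalue(
            t, hit_seeds, universe
        ) < enrichment.weighted_overlap_pvalue(t, hit_others, universe)

    def test_hand_enumeration_with_duplicated_seeds(self):
        # universe 20, disease of 4 with 2 seeds, target 5, overlap 3 incl. both
        # seeds -> draws 6, overlap 5, universe 22, marked 5
        t = subnet({"s1", "s2", "o1", "t4", "t5"})
        d = subnet({"s1", "s2", "o1", "d4"}, origins={"s1", "s2"})
        p = enrichment.weighted_overlap_pvalue(t, d, 20)
        assert p == pytest.approx(hyper_tail_exact(5, 22, 5, 6))


class TestHolmAdjust:
    def test_hand_step_down(self):
        assert enrichment.holm_adjust([0.01, 0.02, 0.04]) == pytest.approx(
            [0.03, 0.04, 0.04]
        )

    def test_single_value_unchanged(self):
        assert enrichment.holm_adjust([0.3]) == pytest.approx([0.3])

    def test_all_ones_capped(self):
        assert enrichment.holm_adjust([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            enrichment.holm_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_monotone_preserving(self, pvals):
        adjusted = enrichment.holm_adjust(pvals)
        order = np.argsort(pvals, kind="stable")
        ranked = [adjusted[i] for i in order]
        assert all(a <= b + 1e-12 for a, b in zip(ranked, ranked[1:]))
        assert all(a <= b for a, b in zip(pvals, adjusted))


class TestRankingMetric:
    def test_p_one_branch(self):
        for n in (1, 7, 100):
            assert enrichment.ranking_metric(1.0, n) == 1.0

    def test_identity_denominator(self):
        assert enrichment.ranking_metric(0.37, 1) == pytest.approx(0.37)

    def test_log_adjustment(self):
        assert enrichment.ranking_metric(0.05, 7) == pytest.approx(0.05 / 3)

    def test_zero_seeds_rejected(self):
        with pytest.raises(ValueError):
            enrichment.ranking_metric(0.5, 0)

    def test_decreasing_in_seed_count(self):
        values = [enrichment.ranking_metric(0.2, n) for n in (1, 3, 15, 100)]
        assert values == sorted(values, reverse=True)


def toy_network(n=40):
    return nx.path_graph([f"P{i:02d}" for i in range(n)])


def fixed_modules(catalog, nodes_by_id):
    """Hand-built expansion traces standing in for DIAMOnD output."""
    return {
        did: ExpansionTrace(
            added=[],
            subnetwork=subnet(nodes, origins=catalog[did].seed_genes & set(nodes)),
        )
        for did, nodes in nodes_by_id.items()
    }


class TestRankIndications:
    def test_single_disease_rank_one(self):
        g = toy_network()
        catalog = make_catalog(make_entry("D1", {"P05", "P06"}))
        frame = enrichment.rank_indications(
            g, subnet({"P00", "P01"}, origins={"P00"}, construction="target"),
            catalog, module_iterations=3,
        )
        assert len(frame) == 1
        assert frame.loc[0, "rank"] == 1 and frame.loc[0, "score"] == 1.0

    def test_larger_seed_count_wins_at_equal_p(self):
        g = toy_network()
        seeds_small = {f"S{i}" for i in range(3)}
        seeds_big = {f"B{i}" for i in range(15)}
        catalog = make_catalog(
            make_entry("Dsmall", seeds_small), make_entry("Dbig", seeds_big)
        )
        shared = {"P10", "P11", "P12"}
        modules = fixed_modules(catalog, {"Dsmall": shared, "Dbig": shared})
        target = subnet({"P10", "P11", "P20"}, origins={"P20"}, construction="target")
        frame = enrichment.rank_indications(g, target, catalog, modules=modules)
        assert frame.loc[0, "disease_id"] == "Dbig"
        assert frame.loc[0, "metric"] < frame.loc[1, "metric"]
        assert frame.loc[0, "pvalue"] == pytest.approx(frame.loc[1, "pvalue"])

    def test_scores_sum_to_harmonic_number(self):
        g = toy_network()
        catalog = make_catalog(*[
            make_entry(f"D{i}", {f"P{2 * i:02d}", f"P{2 * i + 1:02d}"})
            for i in range(6)
        ])
        target = subnet({"P00", "P01", "P02"}, origins={"P00"}, construction="target")
        frame = enrichment.rank_indications(g, target, catalog, module_iterations=2)
        expected = sum(1 / k for k in range(1, 7))
        assert frame["score"].sum() == pytest.approx(expected)

    def test_metric_nondecreasing_and_ranks_dense(self):
        g = toy_network()
        catalog = make_catalog(*[
            make_entry(f"D{i}", {f"P{3 * i:02d}"}) for i in range(8)
        ])
        target = subnet(set(list(g.nodes)[:10]), origins={"P00"}, construction="target")
        frame = enrichment.rank_indications(g, target, catalog, module_iterations=2)
        assert list(frame["rank"]) == list(range(1, len(frame) + 1))
        assert frame["metric"].is_monotonic_increasing
        assert (frame["score"] == 1.0 / frame["rank"]).all()

    def test_mesh_dedup_applied_last(self):
        g = toy_network()
        catalog = make_catalog(
            make_entry("Da", {"P01", "P02"}, mesh="M1"),
            make_entry("Db", {"P30", "P31"}, mesh="M1"),
            make_entry("Dc", {"P20", "P21"}, mesh="M2"),
        )
        target = subnet({"P00", "P01", "P02", "P03"}, origins={"P00"},
                        construction="target")
        deduped = enrichment.rank_indications(g, target, catalog, module_iterations=2)
        full = enrichment.rank_indications(
            g, target, catalog, module_iterations=2, deduplicate=False
        )
        assert len(full) == 3 and len(deduped) == 2
        assert set(deduped["mesh_id"]) == {"M1", "M2"}

    def test_empty_catalog_errors(self):
        with pytest.raises(ValueError):
            enrichment.rank_indications(
                toy_network(), subnet({"P00"}, origins={"P00"}, construction="target"),
                make_catalog(),
            )

    def test_weighted_variant_uses_seed_duplication(self):
        g = toy_network()
        catalog = make_catalog(make_entry("D1", {"P05"}), make_entry("D2", {"P30"}))
        target = subnet({"P04", "P05", "P06"}, origins={"P04"}, construction="target")
        plain = enrichment.rank_indications(
            g, target, catalog, variant="plain", module_iterations=2
        )
        weighted = enrichment.rank_indications(
            g, target, catalog, variant="weighted", module_iterations=2
        )
        p_plain = plain.set_index("disease_id").loc["D1", "pvalue"]
        p_weighted = weighted.set_index("disease_id").loc["D1", "pvalue"]
        assert p_weighted < p_plain
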
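import math

import networkx as nx
import numpy as np
import pytest

from netindic import baselines

from conftest import make_catalog, make_entry
from helpers import bfs_distances, random_graph


class TestDistancesHandCases:
    def test_closest_two_targets(self, path4):
        assert baselines.closest_distance(path4, {"a", "b"}, {"c", "d"}) == 1.5

    def test_closest_single_target(self, path4):
        assert baselines.closest_distance(path4, {"a"}, {"c", "d"}) == 2.5

    def test_shortest_all_pairs(self, path4):
        assert baselines.shortest_distance(path4, {"a", "b"}, {"c", "d"}) == 2.0

    def test_self_distance_zero(self, path4):
        assert baselines.closest_distance(path4, {"a", "b"}, {"a", "b"}) == 0.0
        assert baselines.shortest_distance(path4, {"c"}, {"c"}) == 0.0

    def test_singleton_closest_equals_shortest(self, path4):
        c = baselines.closest_distance(path4, {"a"}, {"b", "d"})
        s = baselines.shortest_distance(path4, {"a"}, {"b", "d"})
        assert c == s

    def test_kernel_path_case(self):
        g = nx.path_graph(["a", "b", "c"])
        assert baselines.kernel_distance(g, {"a", "c"}, {"b"}) == pytest.approx(2.0)

    def test_kernel_singletons_distance_plus_one(self, path4):
        # singleton sets at hop distance d give exactly d + 1
        assert baselines.kernel_distance(path4, {"a"}, {"d"}) == pytest.approx(4.0)
        assert baselines.kernel_distance(path4, {"a"}, {"a"}) == pytest.approx(1.0)

    def test_unreachable_pair_errors(self):
        g = nx.union(nx.path_graph(["a", "b"]), nx.path_graph(["x", "y"]))
        for fn in (baselines.closest_distance, baselines.shortest_distance,
                   baselines.kernel_distance):
            with pytest.raises(ValueError):
                fn(g, {"a"}, {"x"})

    def test_unreachable_gene_excluded(self):
        g = nx.union(nx.path_graph(["a", "b", "c"]), nx.path_graph(["x", "y"]))
        assert baselines.closest_distance(g, {"a"}, {"b", "x"}) == 1.0


class TestDistancesProperties:
    def test_closest_le_shortest(self):
        rng = np.random.default_rng(4)
        for seed in range(15):
            g = random_graph(60, 0.08, seed=seed)
            g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
            nodes = sorted(g.nodes)
            targets = set(rng.choice(nodes, size=4, replace=False))
            disease = set(rng.choice(nodes, size=5, replace=False))
            assert baselines.closest_distance(g, targets, disease) <= \
                baselines.shortest_distance(g, targets, disease) + 1e-12

    def test_label_permutation_invariance(self):
        g = random_graph(30, 0.15, seed=20)
        mapping = {v: f"X{v}" for v in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        nodes = sorted(g.nodes)
        targets, disease = set(nodes[:3]), set(nodes[10:14])
        for fn in (baselines.closest_distance, baselines.shortest_distance,
                   baselines.kernel_distance):
            assert fn(g, targets, disease) == pytest.approx(
                fn(h, {mapping[v] for v in targets}, {mapping[v] for v in disease})
            )

    def test_against_bruteforce_bfs(self):
        rng = np.random.default_rng(5)
        for seed in range(10):
            g = random_graph(80, 0.06, seed=40 + seed)
            g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
            nodes = sorted(g.nodes)
            targets = set(rng.choice(nodes, size=3, replace=False))
            disease = set(rng.choice(nodes, size=4, replace=False))
            dists = {s: bfs_distances(g, s) for s in targets}
            closest = np.mean([min(dists[s][t] for s in targets) for t in disease])
            shortest = np.mean([dists[s][t] for s in targets for t in disease])
            kernel = -np.mean([
                math.log(np.mean([math.exp(-(dists[s][t] + 1)) for s in targets]))
                for t in disease
            ])
            assert baselines.closest_distance(g, targets, disease) == pytest.approx(closest)
            assert baselines.shortest_distance(g, targets, disease) == pytest.approx(shortest)
            assert baselines.kernel_distance(g, targets, disease) == pytest.approx(kernel)


class TestGeneticAssociationRank:
    @pytest.fixture
    def catalog(self):
        return make_catalog(
            make_entry("D1", {"T", "G1"}, scores={"T": 0.7, "G1": 0.2}),
            make_entry("D2", {"T", "G2"}, scores={"T": 0.3, "G2": 0.9}),
            make_entry("D3", {"G3"}, scores={"G3": 0.5}),
        )

    def test_direct_sort(self, catalog):
        frame = baselines.genetic_association_rank(catalog, "T")
        assert list(frame["disease_id"]) == ["D1", "D2", "D3"]
        assert list(frame["assoc_score"]) == [0.7, 0.3, 0.0]

    def test_unassociated_target_lexicographic(self, catalog):
        frame = baselines.genetic_association_rank(catalog, "ZZ")
        assert list(frame["disease_id"]) == ["D1", "D2", "D3"]
        assert (frame["assoc_score"] == 0).all()

    def test_multi_target_max_matches_bruteforce(self, catalog):
        targets = ["T", "G2"]
        frame = baselines.genetic_association_rank(catalog, targets)
        per_target = {
            d: max(catalog[d].gene_scores.get(t, 0.0) for t in targets)
            for d in catalog.entries
        }
        got = dict(zip(frame["disease_id"], frame["assoc_score"]))
        assert got == per_target


class TestProximityZscore:
    def test_deterministic_given_seed(self):
        g = random_graph(60, 0.1, seed=30)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        nodes = sorted(g.nodes)
        kw = dict(measure="closest", n_random=25, seed=9, min_bin=10)
        r1 = baselines.proximity_zscore(g, nodes[:2], nodes[5:9], **kw)
        r2 = baselines.proximity_zscore(g, nodes[:2], nodes[5:9], **kw)
        assert r1 == r2

    def test_n_random_validated(self, path4):
        with pytest.raises(ValueError):
            baselines.proximity_zscore(path4, {"a"}, {"c"}, n_random=1)

    def test_background_size_and_degree_matching(self):
        g = random_graph(80, 0.08, seed=31)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        bins = baselines._degree_bins(g, min_bin=10)
        for d, members in bins.items():
            assert len(members) >= min(10, g.number_of_nodes())
        rng = np.random.default_rng(0)
        ref = sorted(g.nodes)[:5]
        sample = baselines._degree_matched_sample(g, ref, rng, bins)
        assert len(sample) == len(ref)
        assert sample <= set(g.nodes)

    def test_planted_disease_most_proximal(self):
        import netindic
        hits = 0
        for seed in range(5):
            bench = netindic.generate_benchmark(seed=seed, n_nodes=300)
            pos = next(iter(bench.positives))
            zs = {}
            for entry in bench.catalog:
                zs[entry.disease_id] = baselines.proximity_zscore(
                    bench.network, bench.targets, entry.seed_genes,
                    measure="closest", n_random=30, seed=seed,
                ).zscore
            others = [z for d, z in zs.items() if d != pos]
            hits += zs[pos] < min(others)
        assert hits >= 4


def test_rank_by_proximity_orders_by_zscore():
    import netindic
    bench = netindic.generate_benchmark(seed=3, n_nodes=300)
    frame = baselines.rank_by_proximity(
        bench.network, bench.catalog, bench.targets,
        measure="closest", n_random=30, seed=1,
    )
    assert list(frame["rank"]) == list(range(1, len(frame) + 1))
    assert frame["zscore"].is_monotonic_increasing
    assert frame.loc[0, "disease_id"] in bench.positives
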
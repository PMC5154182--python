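"""The detection algorithm: initialization, criterion, propagation, levels."""

import itertools

import numpy as np
import pytest

from metalp.benchmarks import ring_of_cliques
from metalp.detector import (
    DetectorConfig,
    detect_communities,
    initialize_labels,
    propagate_labels,
    satisfies_criterion,
    sweep_lambda,
)
from metalp.graph import Graph, Partition
from metalp.similarity import similarity_map

from conftest import build_graph


def two_macro_graph(self_a, self_b, w):
    g = Graph()
    g.add_edge("A", "B", w)
    if self_a:
        g.add_self_loop("A", self_a)
    if self_b:
        g.add_self_loop("B", self_b)
    return g


class TestCriterion:
    def test_collapsed_triangle_beats_unit_bridge(self):
        g = two_macro_graph(3.0, 0.0, 1.0)
        assert satisfies_criterion(g, "A", 1.0) is True

    def test_zero_lambda_fails_with_any_neighbor(self):
        g = two_macro_graph(3.0, 3.0, 1.0)
        assert satisfies_criterion(g, "A", 0.0) is False

    def test_exact_tie_fails_strictly(self):
        g = two_macro_graph(1.0, 1.0, 1.0)
        assert satisfies_criterion(g, "A", 1.0) is False

    def test_no_neighbors_is_vacuously_true(self):
        g = Graph()
        g.add_self_loop("A", 2.0)
        assert satisfies_criterion(g, "A", 1.0) is True
        assert satisfies_criterion(g, "A", 0.0) is True

    def test_unknown_node_raises(self):
        g = two_macro_graph(1.0, 1.0, 1.0)
        with pytest.raises(KeyError, match="unknown"):
            satisfies_criterion(g, "Z", 1.0)


class TestInitialization:
    def test_single_edge_collapses_to_one_label(self):
        g = build_graph([("a", "b")])
        for seed in range(10):
            part = initialize_labels(g, similarity_map(g), DetectorConfig(seed=seed))
            assert part.n_communities == 1

    def test_isolated_clique_shares_one_label(self):
        g = Graph()
        for u, v in itertools.combinations(range(6), 2):
            g.add_edge(u, v)
        sims = similarity_map(g)
        for seed in range(10):
            part = initialize_labels(g, sims, DetectorConfig(seed=seed))
            assert part.n_communities == 1

    def test_bridged_triangles_form_two_meta_communities(self):
        g = build_graph(
            [("a", "b"), ("b", "c"), ("a", "c"),
             ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")]
        )
        sims = similarity_map(g)
        triangles = Partition({"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1})
        for seed in range(25):
            part = initialize_labels(g, sims, DetectorConfig(seed=seed))
            assert part == triangles

    def test_fixed_point_labels_are_locally_most_similar(self, karate):
        sims = similarity_map(karate)
        part = initialize_labels(karate, sims, DetectorConfig(seed=3))
        for u in karate.nodes():
            aff = {}
            for v in karate.neighbors(u):
                aff[part[v]] = aff.get(part[v], 0.0) + sims(u, v)
            assert aff[part[u]] == max(aff.values())


class TestPropagation:
    def test_mutually_cohesive_macros_stay_separate(self):
        g = two_macro_graph(3.0, 3.0, 1.0)
        part = propagate_labels(g, DetectorConfig(lam=1.0, seed=0))
        assert part.n_communities == 2

    def test_weak_macro_merges_into_strong(self):
        g = two_macro_graph(1.0, 3.0, 2.0)
        for seed in range(10):
            part = propagate_labels(g, DetectorConfig(lam=1.0, seed=seed))
            assert part.n_communities == 1

    def test_zero_lambda_merges_connected_components(self):
        g = Graph()
        g.add_edge("A", "B", 1.0)
        g.add_edge("B", "C", 1.0)
        g.add_edge("D", "E", 1.0)
        for u in g.nodes():
            g.add_self_loop(u, 10.0)
        part = propagate_labels(g, DetectorConfig(lam=0.0, seed=1))
        assert part.n_communities == 2
        assert part.same_block("A", "C") and not part.same_block("A", "D")


class TestDetect:
    def test_ring_of_cliques_recovers_cliques(self):
        inst = ring_of_cliques(5, 4)
        result = detect_communities(inst.graph, lam=1.0, seed=0)
        assert result.partition == inst.planted
        assert result.criterion_satisfied

    def test_zero_lambda_yields_one_community(self, karate):
        result = detect_communities(karate, lam=0.0, seed=0)
        assert result.n_communities == 1

    def test_single_clique_is_one_community(self):
        g = Graph()
        for u, v in itertools.combinations(range(5), 2):
            g.add_edge(u, v)
        result = detect_communities(g, lam=1.0, seed=0)
        assert result.n_communities == 1

    def test_isolated_node_becomes_singleton_community(self):
        g = build_graph([("a", "b"), ("b", "c"), ("a", "c")], extra_nodes=["x"])
        result = detect_communities(g, lam=1.0, seed=0)
        assert result.partition.blocks()[result.partition["x"]] == {"x"}
        assert result.n_communities == 2

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_communities(Graph(), lam=1.0)

    def test_seeded_reproducibility(self, karate):
        a = detect_communities(karate, lam=1.0, seed=42)
        b = detect_communities(karate, lam=1.0, seed=42)
        assert a.partition == b.partition
        assert [d.n_meta for d in a.diagnostics] == [d.n_meta for d in b.diagnostics]

    def test_meta_count_strictly_decreases_across_levels(self, karate):
        for seed in range(5):
            result = detect_communities(karate, lam=1.0, seed=seed)
            counts = [d.n_meta for d in result.diagnostics]
            assert all(a > b for a, b in zip(counts, counts[1:]))
            assert result.converged

    def test_final_communities_satisfy_criterion(self, karate):
        for lam in (0.4, 0.8, 1.0, 1.5):
            result = detect_communities(karate, lam=lam, seed=7)
            assert result.criterion_satisfied
            for i in result.final_collapsed.nodes():
                assert satisfies_criterion(result.final_collapsed, i, lam)

    def test_config_and_kwargs_are_exclusive(self, karate):
        with pytest.raises(TypeError):
            detect_communities(karate, DetectorConfig(), lam=1.0)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            DetectorConfig(lam=-0.1)
        with pytest.raises(ValueError):
            DetectorConfig(max_levels=0)


class TestSweep:
    def test_zero_lambda_grid_on_connected_graph(self, karate):
        results = sweep_lambda(karate, [0.0], seed=0)
        assert [r.n_communities for r in results] == [1]

    def test_repeated_lambda_same_seed_identical(self):
        inst = ring_of_cliques(6, 4)
        results = sweep_lambda(inst.graph, [1.0, 1.0], seed=5)
        assert results[0].partition == results[1].partition

    def test_empty_grid_rejected(self, karate):
        with pytest.raises(ValueError, match="nonempty"):
            sweep_lambda(karate, [], seed=0)

    def test_mean_community_count_nondecreasing_in_lambda(self, karate):
        """Larger λ yields (on average) at least as many communities."""
        grid = [0.0, 0.3, 0.6, 1.0]
        means = []
        for lam in grid:
            counts = [
                detect_communities(karate, lam=lam, seed=s).n_communities
                for s in range(20)
            ]
            means.append(np.mean(counts))
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))
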
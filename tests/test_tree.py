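"""Spanning-tree construction and topology metrics.

The Kruskal implementation is checked against two independent oracles:
exhaustive enumeration of all labelled trees on 5 nodes (via Prüfer
sequences decoded by networkx) and networkx's own maximum spanning tree.
Metric values are checked against hand-derived results on the canonical
star, path and two-hub topologies.
"""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eegmst as em
from eegmst.montage import CHANNELS_19

from conftest import spec_to_spanning_tree


def random_matrix(n, rng, labels=None):
    v = rng.uniform(0.01, 0.99, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    labels = labels or [f"n{k}" for k in range(n)]
    return em.ConnectivityMatrix(v, labels)


def enumerate_max_tree_weight(mat):
    """Brute-force maximum spanning-tree weight via all Prüfer sequences."""
    n = mat.n
    best = -np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        g = nx.from_prufer_sequence(list(seq))
        w = sum(mat.values[i, j] for i, j in g.edges)
        best = max(best, w)
    return best


class TestKruskal:
    def test_weight_matches_exhaustive_enumeration(self, rng):
        for _ in range(25):
            mat = random_matrix(5, rng)
            tree = em.max_spanning_tree(mat)
            assert tree.total_weight == pytest.approx(
                enumerate_max_tree_weight(mat))

    def test_matches_networkx_maximum_spanning_tree(self, rng):
        for _ in range(10):
            mat = random_matrix(8, rng)
            tree = em.max_spanning_tree(mat)
            g = nx.from_numpy_array(mat.values)
            nx_weight = nx.maximum_spanning_tree(g).size(weight="weight")
            assert tree.total_weight == pytest.approx(nx_weight)

    def test_nineteen_nodes_eighteen_edges(self, random_pli_matrix):
        tree = em.max_spanning_tree(random_pli_matrix)
        assert tree.n == 19
        assert len(tree.edges) == 18
        g = tree.to_networkx()
        assert nx.is_connected(g) and nx.is_tree(g)

    def test_two_node_matrix_gives_single_edge(self):
        mat = em.ConnectivityMatrix([[0, 0.5], [0.5, 0]], ["a", "b"])
        tree = em.max_spanning_tree(mat)
        assert tree.edges == [("a", "b", 0.5)]

    def test_duality_with_min_spanning_tree_on_complement(self, rng):
        mat = random_matrix(10, rng)
        tree = em.max_spanning_tree(mat)
        g = nx.from_numpy_array(1.0 - mat.values)
        min_tree = nx.minimum_spanning_tree(g, algorithm="kruskal")
        idx = {l: k for k, l in enumerate(mat.labels)}
        assert {frozenset((idx[a], idx[b])) for a, b, _ in tree.edges} == \
            {frozenset(e) for e in min_tree.edges}

    def test_tie_break_is_lexicographic_and_deterministic(self):
        v = np.full((4, 4), 0.5)
        np.fill_diagonal(v, 0)
        mat = em.ConnectivityMatrix(v, ["a", "b", "c", "d"])
        tree = em.max_spanning_tree(mat)
        assert [(e[0], e[1]) for e in tree.edges] == \
            [("a", "b"), ("a", "c"), ("a", "d")]

    def test_zero_matrix_rejected(self):
        mat = em.ConnectivityMatrix(np.zeros((3, 3)), ["a", "b", "c"])
        with pytest.raises(ValueError, match="disconnected"):
            em.max_spanning_tree(mat)


class TestMetrics:
    def test_star_metrics(self, star19):
        tree = spec_to_spanning_tree(star19)
        _, max_deg = em.degree_metrics(tree)
        leaves, leaf_frac = em.leaf_metrics(tree)
        assert max_deg == 18
        assert (leaves, leaf_frac) == (18, 1.0)
        assert em.diameter(tree) == 2  # d_max = m - L + 2 = 18 - 18 + 2
        bc, bc_max, _ = em.betweenness(tree)
        hub = tree.nodes[0]
        assert bc[hub] == pytest.approx(1.0)
        assert all(bc[n] == 0 for n in tree.nodes if n != hub)
        assert bc_max == pytest.approx(1.0)
        assert em.degree_correlation(tree) == pytest.approx(-1.0)

    def test_path_metrics(self, path19):
        tree = spec_to_spanning_tree(path19)
        _, max_deg = em.degree_metrics(tree)
        leaves, _ = em.leaf_metrics(tree)
        assert max_deg == 2
        assert leaves == 2
        assert em.diameter(tree) == 18

    def test_two_hub_five_node_tree(self):
        # two directly-connected hubs A-B; leaves C (on A), D, E (on B)
        tree = em.SpanningTree(["A", "B", "C", "D", "E"],
                               [("A", "B", 1.0), ("A", "C", 1.0),
                                ("B", "D", 1.0), ("B", "E", 1.0)])
        leaves, leaf_frac = em.leaf_metrics(tree)
        assert (leaves, leaf_frac) == (3, 0.75)
        assert em.diameter(tree) == 3

    def test_path5_middle_betweenness(self):
        tree = spec_to_spanning_tree(em.make_reference_tree("path", 5),
                                     labels=list("abcde"))
        bc, _, _ = em.betweenness(tree)
        # pairs through "c": {a,b}x{d,e} = 4 of the C(4,2)=6 pairs
        assert bc["c"] == pytest.approx(4 / 6)

    def test_degree_sum_is_twice_edges(self, rng):
        mat = random_matrix(19, rng)
        degrees, _ = em.degree_metrics(em.max_spanning_tree(mat))
        assert sum(degrees.values()) == 36

    def test_assortative_by_construction(self):
        # degree-2 backbone nodes mostly attach to each other, leaves to
        # low-degree ends: endpoint degrees correlate positively
        edges = [(0, 4), (0, 10), (1, 6), (1, 9), (2, 5), (2, 6), (2, 10),
                 (3, 8), (4, 11), (5, 7), (8, 10)]
        labels = [f"n{k}" for k in range(12)]
        tree = em.SpanningTree(
            labels, [(labels[i], labels[j], 1.0) for i, j in edges])
        r = em.degree_correlation(tree)
        assert r > 0
        # cross-check against the standard assortativity implementation
        assert r == pytest.approx(
            nx.degree_assortativity_coefficient(tree.to_networkx()))

    def test_degree_correlation_undefined_for_single_edge(self):
        tree = em.SpanningTree(["a", "b"], [("a", "b", 0.4)])
        assert np.isnan(em.degree_correlation(tree))

    def test_random_trees_satisfy_metric_bounds(self, rng):
        for seed in range(100):
            spec = em.make_reference_tree("random", 19, seed=seed)
            tree = spec_to_spanning_tree(spec)
            leaves, leaf_frac = em.leaf_metrics(tree)
            d = em.diameter(tree)
            _, bc_max, bc_global = em.betweenness(tree)
            r = em.degree_correlation(tree)
            assert 2 <= leaves <= 18
            assert 2 <= d <= 18
            assert d <= 18 - leaves + 2
            assert 0 <= bc_global <= bc_max <= 1
            assert -1 <= r <= 1


class TestRegionalBC:
    def test_star_hub_at_posterior_electrode(self):
        labels = ["T6"] + [c for c in CHANNELS_19 if c != "T6"]
        tree = spec_to_spanning_tree(em.make_reference_tree("star", 19),
                                     labels=labels)
        ant, post = em.regional_bc(tree)
        assert post == pytest.approx(1.0 / 7)
        assert ant == pytest.approx(0.0)

    def test_posterior_hub_beats_anterior(self):
        labels = ["T6"] + [c for c in CHANNELS_19 if c != "T6"]
        tree = spec_to_spanning_tree(em.make_reference_tree("star", 19),
                                     labels=labels)
        ant, post = em.regional_bc(tree)
        assert post > ant

    def test_unknown_region_label_rejected(self):
        tree = em.SpanningTree(["a", "b"], [("a", "b", 0.4)])
        with pytest.raises(ValueError, match="unknown nodes"):
            em.regional_bc(tree, em.RegionConfig(frozenset({"a"}),
                                                 frozenset({"zz"}),
                                                 frozenset()))

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            em.RegionConfig(frozenset({"a"}), frozenset({"a"}), frozenset())


class TestSubjectBandMetrics:
    def test_identical_epochs_equal_single_epoch_metrics(self, star19):
        cfg = em.CouplingConfig(noise_sd=0.0, seed=4)
        rec = em.simulate_coupled_eeg(star19, cfg)
        epochs = em.EpochSet(np.repeat(rec.samples[None], 3, axis=0),
                             rec.labels, cfg.rate)
        multi = em.subject_band_metrics(epochs)
        single = em.subject_band_metrics(
            em.EpochSet(rec.samples[None], rec.labels, cfg.rate))
        assert multi.as_dict() == pytest.approx(single.as_dict())

    def test_alternating_star_path_metrics_are_midpoints(self, star19, path19):
        """Epochs alternating between a perfect star and a perfect path
        average to the midpoint of each metric (e.g. mean leaf number 10)."""
        star_rec = em.simulate_coupled_eeg(
            star19, em.CouplingConfig(noise_sd=0.0, seed=5))
        path_rec = em.simulate_coupled_eeg(
            path19, em.CouplingConfig(noise_sd=0.0, seed=6))
        epochs = em.EpochSet(
            np.stack([star_rec.samples, path_rec.samples]),
            star_rec.labels, 500.0)
        m = em.subject_band_metrics(epochs)
        assert m.leaf_number == pytest.approx((18 + 2) / 2)
        assert m.diameter == pytest.approx((2 + 18) / 2)
        assert m.max_degree == pytest.approx((18 + 2) / 2)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_property_random_tree_leaf_diameter_bound(seed):
    """d <= m - L + 2 on uniformly random labelled trees."""
    spec = em.make_reference_tree("random", 12, seed=seed)
    tree = spec_to_spanning_tree(spec)
    leaves, _ = em.leaf_metrics(tree)
    assert em.diameter(tree) <= (tree.n - 1) - leaves + 2
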
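"""Seed nets, Steiner simplification, topology stats, null validation."""

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import make_background
from crosstalk.core_network import (build_seed_net, build_tissue_network,
                                    network_stats, randomize_validate,
                                    steiner_simplify, _exact_steiner)


def brute_force_steiner_size(graph, terminals):
    """Oracle: smallest edge count of a connected subgraph spanning the
    terminals, by exhaustive search over connector subsets."""
    terminals = set(terminals)
    non_terminals = sorted(set(graph.nodes) - terminals)
    for extra in range(len(non_terminals) + 1):
        for combo in itertools.combinations(non_terminals, extra):
            sub = graph.subgraph(terminals | set(combo))
            if sub.number_of_nodes() and nx.is_connected(sub):
                return len(terminals | set(combo)) - 1
    raise AssertionError("terminals are disconnected")


# ---------------------------------------------------------------------------
# seed nets
# ---------------------------------------------------------------------------


def test_seed_net_is_seed_plus_neighbors():
    bg = make_background([("A", "B"), ("B", "C")])
    g = build_seed_net({"A"}, bg)
    assert set(g.nodes) == {"A", "B"}
    assert set(map(frozenset, g.edges)) == {frozenset({"A", "B"})}


def test_seed_net_induces_all_edges_between_retained_nodes():
    bg = make_background([("A", "B"), ("B", "C")])
    g = build_seed_net({"A", "C"}, bg)
    assert set(g.nodes) == {"A", "B", "C"}
    assert g.number_of_edges() == 2


def test_seed_net_ignores_direction():
    bg = make_background([("B", "A")])
    assert set(build_seed_net({"A"}, bg).nodes) == {"A", "B"}


def test_seed_net_empty_seeds_empty_graph():
    bg = make_background([("A", "B")])
    assert build_seed_net(set(), bg).number_of_nodes() == 0


def test_seed_net_counts_unmapped_seeds():
    bg = make_background([("A", "B")])
    g = build_seed_net({"A", "NOPE"}, bg)
    assert g.graph["n_unmapped_seeds"] == 1


def test_seed_net_requires_background():
    from crosstalk.knowledge_io import BackgroundNetwork
    with pytest.raises(ValueError, match="empty"):
        build_seed_net({"A"}, BackgroundNetwork())


# ---------------------------------------------------------------------------
# Steiner simplification
# ---------------------------------------------------------------------------


def test_pendant_non_terminal_is_pruned():
    """Path A-B-C with pendant D on B, terminals {A, C}: the tree is the
    path and D disappears (exhaustive optimum on 4 nodes)."""
    g = nx.Graph([("A", "B"), ("B", "C"), ("B", "D")])
    tree = steiner_simplify(g, {"A", "C"})
    assert set(tree.nodes) == {"A", "B", "C"}
    assert tree.number_of_edges() == brute_force_steiner_size(g, {"A", "C"})


def test_all_terminal_tree_returned_unchanged():
    g = nx.random_labeled_tree(9, seed=5)
    tree = steiner_simplify(g, set(g.nodes))
    assert set(tree.edges) == set(g.edges)


def test_components_are_traversed_independently():
    g = nx.Graph([("A", "B"), ("C", "D"), ("E", "F")])
    tree = steiner_simplify(g, {"A", "B", "C", "D"})
    assert set(tree.nodes) == {"A", "B", "C", "D"}  # E-F dropped: no terminal
    assert nx.number_connected_components(tree) == 2


def test_single_terminal_component_keeps_bare_terminal():
    g = nx.Graph([("A", "B")])
    tree = steiner_simplify(g, {"A"})
    assert set(tree.nodes) == {"A"} and tree.number_of_edges() == 0


def test_steiner_output_spans_terminals_and_is_acyclic():
    rng = np.random.default_rng(3)
    for _ in range(20):
        g = nx.gnp_random_graph(12, 0.25, seed=int(rng.integers(2**31)))
        terminals = set(rng.choice(12, size=4, replace=False).tolist())
        tree = steiner_simplify(g, terminals)
        present = terminals & set(g.nodes)
        for comp in nx.connected_components(g):
            comp_terms = present & comp
            if not comp_terms:
                continue
            # all of this component's terminals sit in one tree component
            tree_comp = next(c for c in nx.connected_components(tree)
                             if comp_terms & c)
            assert comp_terms <= tree_comp
        assert nx.is_forest(tree)


def test_two_terminals_give_exact_shortest_path():
    rng = np.random.default_rng(11)
    for _ in range(20):
        g = nx.gnp_random_graph(10, 0.3, seed=int(rng.integers(2**31)))
        nodes = sorted(g.nodes)
        a, b = rng.choice(nodes, size=2, replace=False).tolist()
        if not nx.has_path(g, a, b):
            continue
        tree = steiner_simplify(g, {a, b})
        assert tree.number_of_edges() == nx.shortest_path_length(g, a, b)


def test_exact_solver_matches_brute_force():
    rng = np.random.default_rng(29)
    for _ in range(15):
        g = nx.gnp_random_graph(9, 0.35, seed=int(rng.integers(2**31)))
        comps = [c for c in nx.connected_components(g) if len(c) >= 4]
        if not comps:
            continue
        comp = g.subgraph(max(comps, key=len))
        terminals = set(list(sorted(comp.nodes))[:3])
        tree = _exact_steiner(comp, terminals)
        assert tree.number_of_edges() == brute_force_steiner_size(
            comp, terminals)


def test_approximation_within_factor_two_of_optimum():
    rng = np.random.default_rng(47)
    checked = 0
    for _ in range(30):
        g = nx.gnp_random_graph(9, 0.3, seed=int(rng.integers(2**31)))
        if not nx.is_connected(g):
            continue
        terminals = set(rng.choice(9, size=4, replace=False).tolist())
        approx = steiner_simplify(g, terminals).number_of_edges()
        optimum = brute_force_steiner_size(g, terminals)
        assert approx <= 2 * optimum
        checked += 1
    assert checked >= 10


# ---------------------------------------------------------------------------
# stats
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("edges,expected", [
    ([("A", "B"), ("B", "C")],
     {"connected_nodes": 3, "edges": 2, "density": 2 * 2 / (3 * 2)}),
    (list(itertools.combinations("ABCD", 2)),
     {"connected_nodes": 4, "edges": 6, "density": 1.0}),
    ([], {"connected_nodes": 0, "edges": 0, "density": 0.0}),
])
def test_network_stats(edges, expected):
    stats = network_stats(nx.Graph(edges))
    assert stats == pytest.approx(expected)


def test_network_stats_ignores_isolated_nodes():
    g = nx.Graph([("A", "B")])
    g.add_node("LONER")
    assert network_stats(g)["connected_nodes"] == 2


def test_network_stats_literal_density_variant():
    g = nx.Graph([("A", "B"), ("B", "C"), ("C", "D")])
    stats = network_stats(g, literal_density=True)
    assert stats["density"] == pytest.approx(3 / (3 * 2 / 2))


# ---------------------------------------------------------------------------
# randomization
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def clique_background():
    """ER background with a planted 15-clique whose members double as a
    dense seed set."""
    rng = np.random.default_rng(0)
    n = 120
    nodes = [f"N{i:03d}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in rng.choice(n, size=3, replace=False):
            if i != j:
                edges.append((nodes[i], nodes[int(j)]))
    clique = nodes[:15]
    for a, b in itertools.combinations(clique, 2):
        edges.append((a, b))
    return make_background(edges, nodes=nodes), set(clique)


def test_randomization_is_seed_reproducible(clique_background):
    bg, clique = clique_background
    net = build_tissue_network("t", clique, bg)
    r1 = randomize_validate(net, bg, n_seeds=len(clique), n_null=20,
                            rng_seed=123)
    r2 = randomize_validate(net, bg, n_seeds=len(clique), n_null=20,
                            rng_seed=123)
    assert r1.to_dict() == r2.to_dict()


def test_planted_dense_seed_set_deviates_from_null(clique_background):
    bg, clique = clique_background
    net = build_tissue_network("t", clique, bg)
    report = randomize_validate(net, bg, n_seeds=len(clique), n_null=50,
                                rng_seed=7)
    assert report.passed
    for metric in ("connected_nodes", "edges", "density"):
        assert abs(report.metrics[metric]["z"]) > 2.33


def test_observed_equal_to_null_mean_fails(clique_background):
    bg, _ = clique_background
    rng = np.random.default_rng(5)
    sample = set(rng.choice(sorted(bg.nodes), size=15, replace=False))
    net = build_tissue_network("t", sample, bg)
    report = randomize_validate(net, bg, n_seeds=15, n_null=60, rng_seed=9)
    # a typical random seed set sits inside its own null distribution
    assert not report.passed


def test_zero_null_sd_reported_as_undefined():
    bg = make_background([("A", "B")])
    net = build_tissue_network("t", {"A"}, bg)
    report = randomize_validate(net, bg, n_seeds=2, n_null=5, rng_seed=1)
    assert not report.passed and "z undefined" in report.reason


def test_n_seeds_cannot_exceed_background():
    bg = make_background([("A", "B")])
    net = build_tissue_network("t", {"A"}, bg)
    with pytest.raises(ValueError):
        randomize_validate(net, bg, n_seeds=99)
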
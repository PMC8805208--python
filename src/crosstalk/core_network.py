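"""Tissue-specific core-network construction and null-model validation.

Each tissue's differential proteins are seed nodes.  The *seed net* is the
subgraph of the (undirected view of the) background network induced by the
seeds plus their direct neighbors.  Every connected component holding at
least one seed is then simplified to an approximate minimum Steiner tree
over that component's seeds (unit edge weights), which cuts branches made
of non-differential proteins while keeping the connectors that bridge
seeds.  The union of these trees is the tissue-specific core network.

Construction quality is assessed against a null model: seed sets of the
same size resampled uniformly from the background, pushed through the
identical pipeline, with a Z-score per topology metric (connected nodes,
edges, density).  A network passes when |Z| exceeds the threshold (default
2.33) on all three metrics.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from networkx.algorithms.approximation import steiner_tree as _nx_steiner

from .knowledge_io import BackgroundNetwork

Z_THRESHOLD_DEFAULT = 2.33
N_NULL_DEFAULT = 100
EXACT_COMPONENT_LIMIT = 12


@dataclass
class TissueNetwork:
    """One tissue's core network: union of per-component Steiner trees."""

    tissue: str
    graph: nx.Graph
    seeds: set                    # DEP terminals present in the graph
    steiner_nodes: set            # non-seed connectors retained
    stats: dict = field(default_factory=dict)

    def __contains__(self, protein: str) -> bool:
        return protein in self.graph

    def to_graphml(self, path, roles: dict | None = None) -> None:
        g = nx.Graph()
        for node in self.graph.nodes:
            attrs = {"is_seed": node in self.seeds}
            if roles is not None and node in roles:
                attrs["role"] = roles[node].role
            g.add_node(node, **attrs)
        g.add_edges_from(self.graph.edges)
        nx.write_graphml(g, os.fspath(path))

    def to_edge_list(self, dest) -> None:
        handle, close = (dest, False) if hasattr(dest, "write") else (
            open(os.fspath(dest), "w", encoding="utf-8"), True)
        try:
            handle.write("# node_a\tnode_b\n")
            for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges):
                handle.write(f"{u}\t{v}\n")
        finally:
            if close:
                handle.close()


@dataclass
class RandomizationReport:
    """Observed vs null topology for one tissue network."""

    metrics: dict                 # metric -> {observed, null_mean, null_sd, z}
    n_null: int
    z_threshold: float
    passed: bool
    reason: str = ""

    def to_dict(self) -> dict:
        return {"metrics": self.metrics, "n_null": self.n_null,
                "z_threshold": self.z_threshold, "passed": self.passed,
                "reason": self.reason}


def build_seed_net(seeds: set, background: BackgroundNetwork) -> nx.Graph:
    """Seed net: seeds plus their background neighbors (direction ignored)
    with every background edge between retained nodes, undirected.

    Seeds absent from the background are dropped with a warning count
    attached to the returned graph (``graph.graph['n_unmapped_seeds']``).
    """
    if background.graph.number_of_nodes() == 0:
        raise ValueError("background network is empty")
    mapped = set(seeds) & background.nodes
    unmapped = len(set(seeds)) - len(mapped)
    nodes = set(mapped)
    for s in mapped:
        nodes |= background.neighbors(s)
    und = background.undirected()
    g = nx.Graph(und.subgraph(nodes).copy())
    g.graph["n_unmapped_seeds"] = unmapped
    return g


def _exact_steiner(component: nx.Graph, terminals: set) -> nx.Graph:
    """Exact minimum Steiner tree by exhaustive connector-subset search.

    With unit weights the optimum tree minimizes edge count = node count -
    1, so it suffices to find the smallest set of non-terminal nodes whose
    union with the terminals induces a connected subgraph.  Exponential in
    component size; callers gate on EXACT_COMPONENT_LIMIT.
    """
    non_terminals = sorted(set(component.nodes) - terminals)
    for size in range(len(non_terminals) + 1):
        for extra in itertools.combinations(non_terminals, size):
            nodes = terminals | set(extra)
            sub = component.subgraph(nodes)
            if nx.is_connected(sub):
                return nx.minimum_spanning_tree(sub)
    raise AssertionError("terminals not connected within their component")


def _approx_steiner(component: nx.Graph, terminals: set) -> nx.Graph:
    """Metric-closure 2-approximation (Kou-Markowsky-Berman style) on a
    lexicographically ordered copy, so shortest-path and MST tie-breaks are
    deterministic."""
    ordered = nx.Graph()
    ordered.add_nodes_from(sorted(component.nodes))
    ordered.add_edges_from(sorted(tuple(sorted(e)) for e in component.edges))
    tree = _nx_steiner(ordered, sorted(terminals), method="kou")
    return nx.Graph(tree)


def steiner_simplify(seed_net: nx.Graph, terminals: set,
                     exact_small: bool = False) -> nx.Graph:
    """Union of per-component Steiner trees over the terminals.

    Every connected component holding at least one terminal contributes
    one tree spanning that component's terminals; components without
    terminals are dropped.  A single-terminal component contributes the
    bare terminal node.  With ``exact_small=True`` components of at most
    EXACT_COMPONENT_LIMIT nodes are solved exactly instead of by the
    2-approximation.
    """
    terminals = set(terminals) & set(seed_net.nodes)
    result = nx.Graph()
    for comp_nodes in nx.connected_components(seed_net):
        comp_terminals = terminals & comp_nodes
        if not comp_terminals:
            continue
        if len(comp_terminals) == 1:
            result.add_node(next(iter(comp_terminals)))
            continue
        component = seed_net.subgraph(comp_nodes)
        if exact_small and len(comp_nodes) <= EXACT_COMPONENT_LIMIT:
            tree = _exact_steiner(component, comp_terminals)
        else:
            tree = _approx_steiner(component, comp_terminals)
        result.add_nodes_from(tree.nodes)
        result.add_edges_from(tree.edges)
    return result


def network_stats(graph: nx.Graph, literal_density: bool = False) -> dict:
    """Topology summary: connected nodes (degree >= 1), edge count, and
    density 2E / (N(N-1)) over connected nodes (0 when N < 2).

    ``literal_density=True`` switches to the edge-based variant
    E / (E(E-1)/2), kept for auditability only.
    """
    connected = sum(1 for _, d in graph.degree() if d >= 1)
    edges = graph.number_of_edges()
    if literal_density:
        density = edges / (edges * (edges - 1) / 2) if edges >= 2 else 0.0
    else:
        density = (2 * edges / (connected * (connected - 1))
                   if connected >= 2 else 0.0)
    return {"connected_nodes": connected, "edges": edges, "density": density}


def build_tissue_network(tissue: str, seeds: set,
                         background: BackgroundNetwork,
                         exact_small: bool = False) -> TissueNetwork:
    """Full per-tissue construction: seed net -> Steiner trees -> stats."""
    seed_net = build_seed_net(seeds, background)
    core = steiner_simplify(seed_net, seeds, exact_small=exact_small)
    present_seeds = set(seeds) & set(core.nodes)
    return TissueNetwork(
        tissue=tissue, graph=core, seeds=present_seeds,
        steiner_nodes=set(core.nodes) - present_seeds,
        stats=network_stats(core),
    )


def randomize_validate(observed: TissueNetwork,
                       background: BackgroundNetwork,
                       n_seeds: int,
                       n_null: int = N_NULL_DEFAULT,
                       z_threshold: float = Z_THRESHOLD_DEFAULT,
                       rng_seed: int = 0,
                       keep_null_draws: bool = False) -> RandomizationReport:
    """Compare observed topology to seed-resampling nulls.

    Each null draw samples ``n_seeds`` background nodes uniformly without
    replacement and runs the full pipeline (seed net, Steiner
    simplification, stats).  Z = (observed - null mean) / null sd per
    metric (sample sd, ddof=1); the network passes when |Z| > threshold on
    all metrics.  Fully reproducible from ``rng_seed``.
    """
    pool = sorted(background.nodes)
    if n_seeds > len(pool):
        raise ValueError("n_seeds exceeds background node count")
    rng = np.random.default_rng(rng_seed)
    draws = {"connected_nodes": [], "edges": [], "density": []}
    for _ in range(n_null):
        sample = set(rng.choice(pool, size=n_seeds, replace=False))
        net = steiner_simplify(build_seed_net(sample, background), sample)
        stats_ = network_stats(net)
        for m in draws:
            draws[m].append(stats_[m])

    metrics = {}
    passed = True
    reason = ""
    for m, values in draws.items():
        arr = np.asarray(values, dtype=float)
        mean, sd = float(arr.mean()), float(arr.std(ddof=1))
        obs = float(observed.stats[m])
        entry = {"observed": obs, "null_mean": mean, "null_sd": sd}
        if sd > 0:
            entry["z"] = (obs - mean) / sd
            if abs(entry["z"]) <= z_threshold:
                passed = False
        else:
            entry["z"] = None
            passed = False
            reason = f"null sd is 0 for metric {m!r}; z undefined"
        metrics[m] = entry
        if keep_null_draws:
            entry["null_draws"] = values
    return RandomizationReport(metrics=metrics, n_null=n_null,
                               z_threshold=z_threshold, passed=passed,
                               reason=reason)
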
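"""Cross-tissue interface construction.

Secreted differential proteins (ligands) of a source tissue reach
non-secreted proteins (receptors) in another tissue's core network through
directed background edges ligand -> receptor.  Around these inter-tissue
edges the interface keeps the intra-tissue regulatory context: upstream
pairs (regulator DEP -> ligand) in the source tissue and downstream pairs
(receptor -> effector DEP) in the target tissue.

Before emitting edges, each tissue's ligand candidates pass a
tissue-specificity filter: a protein expressed more than `fold` (default
10) times lower in this tissue than in some other atlas tissue is treated
as low-expressed there and excluded, so crosstalk is not attributed to a
tissue that barely expresses the ligand.  Proteins missing from the atlas
are retained (unknown is not low).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx

from .differential import DepTable
from .core_network import TissueNetwork
from .knowledge_io import (BackgroundNetwork, ExpressionAtlas, SecretedCatalog)

logger = logging.getLogger(__name__)

FOLD_DEFAULT = 10.0


class CrossTissueEdge(NamedTuple):
    source_tissue: str
    ligand: str
    target_tissue: str
    receptor: str


@dataclass
class CrosstalkInterface:
    """Inter-tissue edges plus their intra-tissue up/downstream context."""

    cross_edges: list = field(default_factory=list)
    # source tissue -> set of (regulator DEP, ligand) pairs
    upstream_pairs: dict = field(default_factory=dict)
    # target tissue -> set of (receptor, downstream DEP) pairs
    downstream_pairs: dict = field(default_factory=dict)

    def ligands_of(self, tissue: str) -> set:
        return {e.ligand for e in self.cross_edges if e.source_tissue == tissue}

    def receptors_of(self, tissue: str) -> set:
        return {e.receptor for e in self.cross_edges if e.target_tissue == tissue}

    def upstream_regulators_of(self, tissue: str) -> set:
        return {u for u, _ in self.upstream_pairs.get(tissue, ())}

    def downstream_effectors_of(self, tissue: str) -> set:
        return {d for _, d in self.downstream_pairs.get(tissue, ())}

    def tissue_pairs(self) -> list:
        return sorted({(e.source_tissue, e.target_tissue)
                       for e in self.cross_edges})

    def to_tsv(self, dest) -> None:
        """Flat export: role in {cross, upstream, downstream} with source
        and target tissue/protein columns."""
        handle, close = (dest, False) if hasattr(dest, "write") else (
            open(os.fspath(dest), "w", encoding="utf-8"), True)
        try:
            handle.write("role\tsource_tissue\tsource_protein\t"
                         "target_tissue\ttarget_protein\n")
            for e in self.cross_edges:
                handle.write(f"cross\t{e.source_tissue}\t{e.ligand}\t"
                             f"{e.target_tissue}\t{e.receptor}\n")
            for tissue in sorted(self.upstream_pairs):
                for u, s in sorted(self.upstream_pairs[tissue]):
                    handle.write(f"upstream\t{tissue}\t{u}\t{tissue}\t{s}\n")
            for tissue in sorted(self.downstream_pairs):
                for r, d in sorted(self.downstream_pairs[tissue]):
                    handle.write(f"downstream\t{tissue}\t{r}\t{tissue}\t{d}\n")
        finally:
            if close:
                handle.close()

    def to_graphml(self, path) -> None:
        g = nx.DiGraph()
        for e in self.cross_edges:
            g.add_node(f"{e.source_tissue}:{e.ligand}", tissue=e.source_tissue,
                       kind="ligand")
            g.add_node(f"{e.target_tissue}:{e.receptor}",
                       tissue=e.target_tissue, kind="receptor")
            g.add_edge(f"{e.source_tissue}:{e.ligand}",
                       f"{e.target_tissue}:{e.receptor}", role="cross")
        for tissue, pairs in self.upstream_pairs.items():
            for u, s in pairs:
                g.add_node(f"{tissue}:{u}", tissue=tissue, kind="upstream")
                g.add_edge(f"{tissue}:{u}", f"{tissue}:{s}", role="upstream")
        for tissue, pairs in self.downstream_pairs.items():
            for r, d in pairs:
                g.add_node(f"{tissue}:{d}", tissue=tissue, kind="downstream")
                g.add_edge(f"{tissue}:{r}", f"{tissue}:{d}", role="downstream")
        nx.write_graphml(g, os.fspath(path))


def filter_low_expression(candidates: set, tissue: str,
                          atlas: ExpressionAtlas,
                          fold: float = FOLD_DEFAULT) -> set:
    """Drop proteins low-expressed in *tissue* relative to the atlas.

    A protein is excluded when its expression in some other atlas tissue
    exceeds ``fold`` times its expression here (strict inequality, i.e.
    "more than fold times lower").  Missing atlas values exempt the
    protein from the filter.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    if tissue not in atlas.tissues:
        raise ValueError(f"tissue {tissue!r} not in the expression atlas")
    kept = set()
    for p in candidates:
        here = atlas.value(p, tissue)
        if here is None:
            logger.warning("protein %s missing from the atlas in %s; "
                           "retained (unknown is not low)", p, tissue)
            kept.add(p)
            continue
        others = [atlas.value(p, t) for t in atlas.tissues if t != tissue]
        others = [v for v in others if v is not None]
        if others and max(others) > fold * here:
            continue
        kept.add(p)
    return kept


def find_cross_edges(source_tissue: str, source_dep: DepTable,
                     targets: dict, background: BackgroundNetwork,
                     catalog: SecretedCatalog, atlas: ExpressionAtlas,
                     fold: float = FOLD_DEFAULT,
                     receptor_dep: bool = False,
                     dep_tables: dict | None = None) -> list:
    """Ligand -> receptor edges from one source tissue into target networks.

    Ligands are the source tissue's secreted DEPs surviving the
    low-expression filter.  For each directed background edge
    ligand -> r with r non-secreted, an edge is emitted to every target
    tissue whose core network contains r.  With ``receptor_dep=True``
    (stricter reading) r must additionally be a DEP of the target tissue;
    ``dep_tables`` is then required.
    """
    if source_tissue in targets:
        raise ValueError("source tissue must not appear among the targets")
    if receptor_dep and dep_tables is None:
        raise ValueError("receptor_dep=True requires dep_tables")
    secreted_deps = {p for p in source_dep.deps if p in catalog}
    ligands = filter_low_expression(secreted_deps, source_tissue, atlas,
                                    fold=fold)
    edges = []
    for ligand in sorted(ligands):
        for r in sorted(background.successors(ligand)):
            if r in catalog:
                continue
            for target_tissue in sorted(targets):
                if r not in targets[target_tissue]:
                    continue
                if receptor_dep and not dep_tables[target_tissue].is_dep(r):
                    continue
                edges.append(CrossTissueEdge(source_tissue, ligand,
                                             target_tissue, r))
    return edges


def upstream_pairs(ligands: set, source_dep: DepTable,
                   background: BackgroundNetwork) -> set:
    """(regulator DEP -> ligand) pairs within the source tissue, following
    the background edge direction."""
    pairs = set()
    for s in ligands:
        for u in background.predecessors(s):
            if u != s and source_dep.is_dep(u):
                pairs.add((u, s))
    return pairs


def downstream_pairs(receptors: set, tissue_dep: DepTable,
                     background: BackgroundNetwork) -> set:
    """(receptor -> downstream DEP) pairs within the receptor's tissue."""
    pairs = set()
    for r in receptors:
        for d in background.successors(r):
            if d != r and tissue_dep.is_dep(d):
                pairs.add((r, d))
    return pairs


def _check_invariants(interface: CrosstalkInterface,
                      background: BackgroundNetwork,
                      catalog: SecretedCatalog) -> None:
    for e in interface.cross_edges:
        assert e.source_tissue != e.target_tissue, e
        assert e.ligand in catalog, e
        assert e.receptor not in catalog, e
        assert (e.ligand, e.receptor) in background.directed_edges, e
    ligand_set = {e.ligand for e in interface.cross_edges}
    for tissue, pairs in interface.upstream_pairs.items():
        for u, s in pairs:
            assert s in ligand_set, (tissue, u, s)
            assert (u, s) in background.directed_edges, (tissue, u, s)
    receptor_set = {e.receptor for e in interface.cross_edges}
    for tissue, pairs in interface.downstream_pairs.items():
        for r, d in pairs:
            assert r in receptor_set, (tissue, r, d)
            assert (r, d) in background.directed_edges, (tissue, r, d)


def build_interface(dep_tables: dict, networks: dict,
                    background: BackgroundNetwork,
                    catalog: SecretedCatalog, atlas: ExpressionAtlas,
                    fold: float = FOLD_DEFAULT,
                    receptor_dep: bool = False) -> CrosstalkInterface:
    """Assemble the full interface over all ordered tissue pairs.

    Upstream pairs are kept only for ligands that actually emit at least
    one cross edge (the interface is defined around realized inter-tissue
    connections); downstream pairs are computed for every receptor in its
    receiving tissue.  Output ordering is deterministic.
    """
    tissues = sorted(dep_tables)
    if len(tissues) < 2:
        raise ValueError("need >=2 tissues to build an interface")
    cross: list[CrossTissueEdge] = []
    for source in tissues:
        targets = {t: networks[t] for t in tissues if t != source}
        cross.extend(find_cross_edges(
            source, dep_tables[source], targets, background, catalog, atlas,
            fold=fold, receptor_dep=receptor_dep, dep_tables=dep_tables))
    cross.sort()

    up: dict[str, set] = {}
    for source in tissues:
        ligands = {e.ligand for e in cross if e.source_tissue == source}
        pairs = upstream_pairs(ligands, dep_tables[source], background)
        if pairs:
            up[source] = pairs
    down: dict[str, set] = {}
    for target in tissues:
        receptors = {e.receptor for e in cross if e.target_tissue == target}
        pairs = downstream_pairs(receptors, dep_tables[target], background)
        if pairs:
            down[target] = pairs

    interface = CrosstalkInterface(cross_edges=cross, upstream_pairs=up,
                                   downstream_pairs=down)
    _check_invariants(interface, background, catalog)
    return interface
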
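"""Loaders, validators and serializers for the knowledge base.

Every external table or graph the pipeline consumes comes through this
module: the directed background regulatory network (TSV edge list or a
KGML-style pathway XML subset), pathway membership (GMT) with a category
table, the secreted-protein catalog, the tissue x protein expression
atlas, per-tissue abundance tables, and optional EC-number annotation.

All loaders are pure (same bytes in, same object out) and accept either a
filesystem path or an open text handle.  Identifiers are treated
case-sensitively; any symbol-casing normalization is the caller's job.
"""

from __future__ import annotations

import io
import logging
import os
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Union

import networkx as nx
import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

Source = Union[str, os.PathLike, IO[str]]

_EC_PATTERN = re.compile(r"^\d+\.[\dn-]+\.[\dn-]+\.[\dn-]+$|^\d+\.[\dn-]+\.[\dn-]+$")

PATHWAY_CLASSES = ("metabolic", "signaling", "other")


class KnowledgeError(ValueError):
    """Raised on malformed or inconsistent input data."""


def _open(source: Source):
    """Return (text handle, should_close) for a path or file-like source."""
    if hasattr(source, "read"):
        return source, False
    return open(os.fspath(source), "r", encoding="utf-8"), True


def _read_text(source: Source) -> str:
    handle, close = _open(source)
    try:
        return handle.read()
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Background regulatory network
# ---------------------------------------------------------------------------

@dataclass
class BackgroundNetwork:
    """Directed protein regulatory graph with per-edge pathway provenance.

    Edges point regulator -> target.  Self-loops are never stored; the
    number dropped at load time is kept for validation reports.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    n_self_loops_dropped: int = 0

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def directed_edges(self) -> set:
        return set(self.graph.edges)

    def edge_pathways(self, regulator: str, target: str) -> frozenset:
        return frozenset(self.graph.edges[regulator, target].get("pathways", ()))

    def successors(self, protein: str) -> set:
        if protein not in self.graph:
            return set()
        return set(self.graph.successors(protein))

    def predecessors(self, protein: str) -> set:
        if protein not in self.graph:
            return set()
        return set(self.graph.predecessors(protein))

    def neighbors(self, protein: str) -> set:
        """Direction-blind neighborhood (union of regulators and targets)."""
        return self.successors(protein) | self.predecessors(protein)

    def undirected(self) -> nx.Graph:
        """Undirected simple-graph view of the edge set."""
        return nx.Graph(self.graph)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        nodes: Iterable[str] = (),
    ) -> "BackgroundNetwork":
        """Build from (regulator, target[, pathway_id]) tuples, dropping
        self-loops and duplicate edges."""
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        dropped = 0
        for row in edges:
            u, v = row[0], row[1]
            pathway = row[2] if len(row) > 2 and row[2] else None
            if u == v:
                dropped += 1
                continue
            if g.has_edge(u, v):
                if pathway is not None:
                    g.edges[u, v].setdefault("pathways", set()).add(pathway)
                continue
            attrs = {"pathways": {pathway}} if pathway is not None else {}
            g.add_edge(u, v, **attrs)
        if dropped:
            logger.warning("dropped %d self-loop edge(s)", dropped)
        return cls(graph=g, n_self_loops_dropped=dropped)

    # -- serialization ------------------------------------------------------

    def to_edge_list(self, dest: Source) -> None:
        """Write a TSV edge list (regulator, target[, pathway_id])."""
        handle, close = (dest, False) if hasattr(dest, "write") else (
            open(os.fspath(dest), "w", encoding="utf-8"), True)
        try:
            handle.write("# regulator\ttarget\tpathway_id\n")
            for u, v in sorted(self.graph.edges):
                pathways = sorted(self.graph.edges[u, v].get("pathways", ()))
                if pathways:
                    for p in pathways:
                        handle.write(f"{u}\t{v}\t{p}\n")
                else:
                    handle.write(f"{u}\t{v}\n")
        finally:
            if close:
                handle.close()

    def to_graphml(self, path: Union[str, os.PathLike]) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.graph.nodes)
        for u, v, data in self.graph.edges(data=True):
            g.add_edge(u, v, pathways=";".join(sorted(data.get("pathways", ()))))
        nx.write_graphml(g, os.fspath(path))


def load_background(source: Source) -> BackgroundNetwork:
    """Load a directed edge list (TSV: regulator, target[, pathway_id]).

    Lines starting with ``#`` are comments.  Duplicate edges are merged,
    self-loops dropped (counted), and malformed rows raise
    :class:`KnowledgeError` naming the line number.
    """
    text = _read_text(source)
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split("\t")
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise KnowledgeError(
                f"malformed edge-list row at line {lineno}: {line!r}")
        rows.append(tuple(fields[:3]))
    if not rows:
        raise KnowledgeError("empty edge list: no edges found")
    return BackgroundNetwork.from_edges(rows)


def parse_kgml_subset(xml_source: Source) -> BackgroundNetwork:
    """Parse the pathway-XML dialect: ``entry`` elements (type protein or
    gene; ``name`` may hold several space-separated identifiers) and
    ``relation`` elements (entry1 -> entry2, direction kept, subtype
    ignored).

    Entries carrying several names are gene groups; each relation expands
    combinatorially into edges between all name pairs.  Relations touching
    non-protein entries (e.g. compounds) are skipped; relations naming an
    id with no entry at all raise :class:`KnowledgeError`.
    """
    text = _read_text(xml_source)
    try:
        root = etree.fromstring(text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise KnowledgeError(f"not parseable as XML: {exc}") from exc

    protein_names: dict[str, list[str]] = {}
    all_entry_ids = set()
    for entry in root.iter("entry"):
        eid = entry.get("id")
        if eid is None:
            continue
        all_entry_ids.add(eid)
        if entry.get("type") in ("protein", "gene"):
            names = (entry.get("name") or "").split()
            if names:
                protein_names[eid] = names

    g = nx.DiGraph()
    for names in protein_names.values():
        g.add_nodes_from(names)
    dropped = 0
    n_skipped = 0
    for i, rel in enumerate(root.iter("relation"), start=1):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        for eid in (e1, e2):
            if eid not in all_entry_ids:
                raise KnowledgeError(
                    f"relation #{i} references unknown entry id {eid!r}")
        if e1 not in protein_names or e2 not in protein_names:
            n_skipped += 1  # compound or other non-protein participant
            continue
        for u in protein_names[e1]:
            for v in protein_names[e2]:
                if u == v:
                    dropped += 1
                    continue
                g.add_edge(u, v)
    if n_skipped:
        logger.info("skipped %d relation(s) touching non-protein entries",
                    n_skipped)
    if dropped:
        logger.warning("dropped %d self-loop edge(s)", dropped)
    return BackgroundNetwork(graph=g, n_self_loops_dropped=dropped)


# ---------------------------------------------------------------------------
# Pathways
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pathway:
    id: str
    name: str
    members: frozenset
    pw_class: str          # one of PATHWAY_CLASSES
    subcategory: str
    excluded: bool         # disease pathway or global map


@dataclass
class PathwayCollection:
    """Gene-set collection with a metabolic/signaling/other class and a
    subcategory (e.g. "carbohydrate metabolism") per pathway, plus an
    exclusion flag for disease pathways and global maps."""

    pathways: dict[str, Pathway] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.values())

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self.pathways[pathway_id]

    def basic(self) -> list[Pathway]:
        """Non-excluded ("basic") pathways, the analysis universe."""
        return [p for p in self.pathways.values() if not p.excluded]

    def classes_of(self, protein: str) -> set:
        """Classes of the non-excluded pathways containing *protein*."""
        return {p.pw_class for p in self.basic() if protein in p.members}

    def membership(self, protein: str) -> list[Pathway]:
        return [p for p in self.basic() if protein in p.members]


def load_pathways(gmt_source: Source, category_source: Source) -> PathwayCollection:
    """Load a GMT gene-set file plus the pathway-category table.

    GMT lines are ``id<TAB>name<TAB>member...``.  The category table is a
    TSV with header ``pathway_id  class  subcategory  excluded``.  Pathways
    missing a category row default to class=other, excluded=false, with a
    warning; duplicate pathway ids are an error.
    """
    categories: dict[str, tuple[str, str, bool]] = {}
    cat_text = _read_text(category_source)
    lines = [l for l in cat_text.splitlines() if l.strip() and not l.startswith("#")]
    for line in lines[1:]:  # skip header
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 4:
            raise KnowledgeError(f"malformed category row: {line!r}")
        pid, pw_class, subcat, excluded = fields[0], fields[1], fields[2], fields[3]
        if pw_class not in PATHWAY_CLASSES:
            raise KnowledgeError(
                f"unknown pathway class {pw_class!r} for {pid} "
                f"(expected one of {PATHWAY_CLASSES})")
        categories[pid] = (pw_class, subcat,
                           excluded.strip().lower() in ("1", "true", "yes"))

    pathways: dict[str, Pathway] = {}
    for lineno, line in enumerate(_read_text(gmt_source).splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise KnowledgeError(
                f"GMT line {lineno} has fewer than 3 fields: {line!r}")
        pid, name, members = fields[0], fields[1], [m for m in fields[2:] if m]
        if pid in pathways:
            raise KnowledgeError(f"duplicate pathway id {pid!r} (GMT line {lineno})")
        if pid in categories:
            pw_class, subcat, excluded = categories[pid]
        else:
            logger.warning("pathway %s has no category row; defaulting to "
                           "class=other, excluded=false", pid)
            pw_class, subcat, excluded = "other", "", False
        if not members and not excluded:
            raise KnowledgeError(f"non-excluded pathway {pid!r} has no members")
        pathways[pid] = Pathway(pid, name, frozenset(members), pw_class,
                                subcat, excluded)
    return PathwayCollection(pathways)


def write_gmt(collection: PathwayCollection, dest: Source) -> None:
    handle, close = (dest, False) if hasattr(dest, "write") else (
        open(os.fspath(dest), "w", encoding="utf-8"), True)
    try:
        for p in sorted(collection, key=lambda p: p.id):
            handle.write("\t".join([p.id, p.name, *sorted(p.members)]) + "\n")
    finally:
        if close:
            handle.close()


def write_pathway_categories(collection: PathwayCollection, dest: Source) -> None:
    handle, close = (dest, False) if hasattr(dest, "write") else (
        open(os.fspath(dest), "w", encoding="utf-8"), True)
    try:
        handle.write("pathway_id\tclass\tsubcategory\texcluded\n")
        for p in sorted(collection, key=lambda p: p.id):
            handle.write(f"{p.id}\t{p.pw_class}\t{p.subcategory}\t"
                         f"{'true' if p.excluded else 'false'}\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Secreted-protein catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SecretedCatalog:
    """Set of proteins predicted to be secreted."""

    ids: frozenset

    def __contains__(self, protein: str) -> bool:
        return protein in self.ids

    def __len__(self) -> int:
        return len(self.ids)


def load_secreted(source: Source) -> SecretedCatalog:
    """Load the one-column secreted-protein TSV (header row required)."""
    lines = [l.strip() for l in _read_text(source).splitlines()
             if l.strip() and not l.startswith("#")]
    if not lines:
        raise KnowledgeError("empty secreted-protein catalog")
    ids = [l.split("\t")[0] for l in lines[1:]]
    return SecretedCatalog(ids=frozenset(ids))


def write_secreted(catalog: SecretedCatalog, dest: Source) -> None:
    handle, close = (dest, False) if hasattr(dest, "write") else (
        open(os.fspath(dest), "w", encoding="utf-8"), True)
    try:
        handle.write("protein\n")
        for p in sorted(catalog.ids):
            handle.write(p + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Expression atlas
# ---------------------------------------------------------------------------

@dataclass
class ExpressionAtlas:
    """Tissue x protein expression levels (e.g. median mRNA abundance).

    Missing cells are stored as NaN and reported as absent by
    :meth:`value`; they are never silently coerced to zero.
    """

    frame: pd.DataFrame  # index: proteins, columns: tissues, NaN = missing

    @property
    def tissues(self) -> list:
        return list(self.frame.columns)

    @property
    def proteins(self) -> set:
        return set(self.frame.index)

    def value(self, protein: str, tissue: str):
        """Expression of *protein* in *tissue*, or None if missing."""
        if protein not in self.frame.index or tissue not in self.frame.columns:
            return None
        v = self.frame.at[protein, tissue]
        return None if pd.isna(v) else float(v)


def load_expression_atlas(source: Source) -> ExpressionAtlas:
    """Load the atlas TSV (rows = proteins, columns = tissues).

    Blank cells become missing values; negative values and duplicate
    protein rows are errors.
    """
    handle, close = _open(source)
    try:
        frame = pd.read_csv(handle, sep="\t", index_col=0)
    finally:
        if close:
            handle.close()
    if frame.index.has_duplicates:
        dupes = sorted(frame.index[frame.index.duplicated()].unique())
        raise KnowledgeError(f"duplicate protein rows in atlas: {dupes}")
    if (frame < 0).any().any():
        bad = frame.stack(future_stack=True)
        bad = bad[bad < 0]
        p, t = bad.index[0]
        raise KnowledgeError(f"negative expression value at ({p}, {t})")
    return ExpressionAtlas(frame=frame.astype(float))


def write_expression_atlas(atlas: ExpressionAtlas, dest: Source) -> None:
    handle, close = (dest, False) if hasattr(dest, "write") else (
        open(os.fspath(dest), "w", encoding="utf-8"), True)
    try:
        atlas.frame.to_csv(handle, sep="\t", index_label="protein")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Abundance tables
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTable:
    """One tissue's protein x replicate intensity matrix with group labels.

    Intensities are strictly positive (log2 must be defined) and every
    replicate column carries a 'control' or 'case' label with at least two
    replicates per group.
    """

    tissue: str
    frame: pd.DataFrame           # index: proteins, columns: replicates
    groups: Mapping[str, str]     # replicate -> 'control' | 'case'

    @property
    def proteins(self) -> list:
        return list(self.frame.index)

    def replicates(self, group: str) -> list:
        return [r for r in self.frame.columns if self.groups[r] == group]


def _validate_abundance(tissue, frame, groups) -> AbundanceTable:
    missing = [c for c in frame.columns if c not in groups]
    if missing:
        raise KnowledgeError(
            f"replicate column(s) without group label: {missing}")
    bad_labels = {g for g in groups.values()} - {"control", "case"}
    if bad_labels:
        raise KnowledgeError(f"unknown group label(s): {sorted(bad_labels)}")
    for grp in ("control", "case"):
        n = sum(1 for c in frame.columns if groups[c] == grp)
        if n < 2:
            raise KnowledgeError(
                f"group {grp!r} has {n} replicate(s); at least 2 required")
    if frame.index.has_duplicates:
        dupes = sorted(frame.index[frame.index.duplicated()].unique())
        raise KnowledgeError(f"duplicate protein ids: {dupes}")
    if frame.isna().any().any() or (frame <= 0).any().any():
        stacked = frame.stack(future_stack=True)
        bad = stacked[stacked.isna() | (stacked <= 0)]
        p, c = bad.index[0]
        raise KnowledgeError(f"non-positive intensity at ({p}, {c})")
    return AbundanceTable(tissue=tissue, frame=frame.astype(float), groups=dict(groups))


def load_abundance(table_source: Source, group_labels: Mapping[str, str],
                   tissue: str = "") -> AbundanceTable:
    """Load a per-tissue abundance TSV (rows = proteins, header names the
    replicate columns) and validate it against the replicate -> group map."""
    handle, close = _open(table_source)
    try:
        frame = pd.read_csv(handle, sep="\t", index_col=0)
    finally:
        if close:
            handle.close()
    return _validate_abundance(tissue, frame, group_labels)


def abundance_from_arrays(tissue, proteins, intensities, groups,
                          replicate_names) -> AbundanceTable:
    frame = pd.DataFrame(intensities, index=list(proteins),
                         columns=list(replicate_names))
    return _validate_abundance(tissue, frame, groups)


def write_abundance(table: AbundanceTable, dest: Source) -> None:
    handle, close = (dest, False) if hasattr(dest, "write") else (
        open(os.fspath(dest), "w", encoding="utf-8"), True)
    try:
        table.frame.to_csv(handle, sep="\t", index_label="protein")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# EC annotation
# ---------------------------------------------------------------------------

@dataclass
class EcAnnotation:
    """Protein -> set of EC-number strings; absence means no known EC."""

    ec: dict[str, frozenset] = field(default_factory=dict)

    def has_ec(self, protein: str) -> bool:
        return bool(self.ec.get(protein))


def load_ec(source: Source) -> EcAnnotation:
    """Load the EC TSV (header row; columns protein, ec; several EC numbers
    separated by ';').  EC strings must match the dotted EC pattern."""
    lines = [l for l in _read_text(source).splitlines()
             if l.strip() and not l.startswith("#")]
    mapping: dict[str, frozenset] = {}
    for line in lines[1:]:
        fields = line.rstrip("\n").split("\t")
        protein = fields[0]
        raw = fields[1] if len(fields) > 1 else ""
        numbers = [s.strip() for s in raw.split(";") if s.strip()]
        for num in numbers:
            if not _EC_PATTERN.match(num):
                raise KnowledgeError(
                    f"invalid EC number {num!r} for protein {protein}")
        if numbers:
            mapping[protein] = frozenset(numbers)
    return EcAnnotation(ec=mapping)


def write_ec(annotation: EcAnnotation, dest: Source) -> None:
    handle, close = (dest, False) if hasattr(dest, "write") else (
        open(os.fspath(dest), "w", encoding="utf-8"), True)
    try:
        handle.write("protein\tec\n")
        for p in sorted(annotation.ec):
            handle.write(f"{p}\t{';'.join(sorted(annotation.ec[p]))}\n")
    finally:
        if close:
            handle.close()
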
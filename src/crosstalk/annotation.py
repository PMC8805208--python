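"""Protein role classification and edge typing.

Roles follow the pathway-restricted definitions used for metabolic
characterization: a *metabolic enzyme* carries an EC number and maps only
to metabolic pathways; a *signaling protein* maps to at least one
signaling pathway and to no metabolic one.  Disease pathways and global
maps (the excluded flag) never count toward membership.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from .knowledge_io import EcAnnotation, PathwayCollection, SecretedCatalog

ROLE_METABOLIC = "metabolic_enzyme"
ROLE_SIGNALING = "signaling_protein"
ROLE_OTHER = "other"


@dataclass(frozen=True)
class ProteinRole:
    protein: str
    role: str                    # metabolic_enzyme | signaling_protein | other
    has_ec: bool
    pathway_classes: frozenset   # classes of non-excluded pathways holding it


def classify_protein(protein: str, ec: EcAnnotation,
                     pathways: PathwayCollection) -> ProteinRole:
    """Classify one protein from its EC status and pathway-class membership.

    The decision is a pure function of (has_ec, set of pathway classes over
    non-excluded pathways):

    * metabolic_enzyme — has an EC number and belongs to at least one
      pathway, all of them metabolic;
    * signaling_protein — belongs to at least one signaling pathway and to
      no metabolic one;
    * other — everything else (including enzymes that also sit in
      signaling pathways, i.e. kinases).
    """
    has_ec = ec.has_ec(protein)
    classes = frozenset(pathways.classes_of(protein))
    if has_ec and classes == {"metabolic"}:
        role = ROLE_METABOLIC
    elif "signaling" in classes and "metabolic" not in classes:
        role = ROLE_SIGNALING
    else:
        role = ROLE_OTHER
    return ProteinRole(protein=protein, role=role, has_ec=has_ec,
                       pathway_classes=classes)


def classify_all(proteins, ec: EcAnnotation,
                 pathways: PathwayCollection) -> dict[str, ProteinRole]:
    return {p: classify_protein(p, ec, pathways) for p in proteins}


def classify_edges(graph, roles: dict[str, ProteinRole],
                   precedence: bool = False) -> dict:
    """Label each undirected edge by its participants' roles.

    An edge is *metabolic_involved* if at least one endpoint is a metabolic
    enzyme and *signaling_involved* if at least one endpoint is a signaling
    protein; by default an edge may carry both labels.  With
    ``precedence=True`` mixed edges count as metabolic only (the exclusive
    variant), so the two fractions sum to at most 1.

    Returns edge sets and, for non-empty graphs, the label fractions.
    """
    missing = [n for n in graph.nodes if n not in roles]
    if missing:
        raise ValueError(f"roles missing for node(s), e.g. {sorted(missing)[:5]}")
    metabolic, signaling = set(), set()
    for u, v in graph.edges:
        edge = tuple(sorted((u, v)))
        m = ROLE_METABOLIC in (roles[u].role, roles[v].role)
        s = ROLE_SIGNALING in (roles[u].role, roles[v].role)
        if m:
            metabolic.add(edge)
        if s and not (precedence and m):
            signaling.add(edge)
    total = graph.number_of_edges()
    out = {"metabolic_involved": metabolic, "signaling_involved": signaling}
    if total:
        out["fractions"] = {"metabolic": len(metabolic) / total,
                            "signaling": len(signaling) / total}
    return out


def secreted_partition(detected: set, catalog: SecretedCatalog) -> dict:
    """Split a detected-protein pool into secreted vs non-secreted.

    Anything not in the secretome catalog is non-secreted; the two sets
    always form an exact bipartition of *detected*.
    """
    secreted = {p for p in detected if p in catalog}
    return {"secreted": secreted, "non_secreted": set(detected) - secreted}


def write_roles(roles: dict[str, ProteinRole], pathways: PathwayCollection,
                dest) -> None:
    """Export roles as TSV: protein, role, has_ec, n_metabolic_pathways,
    n_signaling_pathways."""
    handle, close = (dest, False) if hasattr(dest, "write") else (
        open(os.fspath(dest), "w", encoding="utf-8"), True)
    try:
        handle.write("protein\trole\thas_ec\tn_metabolic_pathways\t"
                     "n_signaling_pathways\n")
        for p in sorted(roles):
            member = pathways.membership(p)
            n_met = sum(1 for pw in member if pw.pw_class == "metabolic")
            n_sig = sum(1 for pw in member if pw.pw_class == "signaling")
            handle.write(f"{p}\t{roles[p].role}\t"
                         f"{'true' if roles[p].has_ec else 'false'}\t"
                         f"{n_met}\t{n_sig}\n")
    finally:
        if close:
            handle.close()
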
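"""Self-consistent synthetic input bundles with planted ground truth.

The generator emulates the structure of a multi-tissue differential
proteomics study: three insulin-sensitive tissues with three replicates
per group, a directed background regulatory network, a pathway collection
whose metabolic share matches the basic-pathway universe (91/243), a
secretome of about 5% of proteins, a tissue x protein expression atlas,
and per-tissue abundance tables with planted differential proteins (fold
change 2.0 on top of Gaussian log2 noise, sd 0.1, by default).

Planted crosstalk axes (upstream -> ligand -> receptor -> effector) are
inserted by direct construction, never by running the analysis code, so
recovery tests are non-circular.  Construction guarantees that the
planted cross edges are the only true ones: random secreted proteins are
drawn from never-differential proteins, and planted ligands emit no
random out-edges.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .knowledge_io import (AbundanceTable, BackgroundNetwork, EcAnnotation,
                           ExpressionAtlas, Pathway, PathwayCollection,
                           SecretedCatalog, write_abundance, write_ec,
                           write_expression_atlas, write_gmt,
                           write_pathway_categories, write_secreted)

TISSUE_NAMES = ("adipose", "liver", "muscle")

_METABOLIC_SUBCATS = ("carbohydrate metabolism", "lipid metabolism",
                      "amino acid metabolism")


class PlantedAxis(NamedTuple):
    source: str        # source tissue
    ligand: str        # secreted DEP of the source tissue
    receptor: str      # non-secreted protein in the target tissue network
    target: str        # target tissue
    upstream: str      # regulator DEP of the ligand (source tissue)
    downstream: str    # effector DEP of the receptor (target tissue)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults mirror the emulated study design: 3 tissues, 3 technical
    replicates per pooled group, planted linear fold change 2.0 with log2
    noise sd 0.1, a ~5% secretome and a 91/243 metabolic pathway share.
    """

    n_proteins: int = 300
    n_pathways: int = 30
    metabolic_fraction: float = 91 / 243
    n_tissues: int = 3
    n_replicates_per_group: int = 3
    planted_axes: list = field(default_factory=list)
    dep_fold_change: float = 2.0
    log2_noise_sd: float = 0.1
    rng_seed: int = 0
    # secondary knobs, fixed once for the study conditions
    mean_out_degree: float = 3.0
    secreted_fraction: float = 0.05
    dep_fraction: float = 0.10
    pathway_size: int = 12
    n_excluded_pathways: int = 2
    topology: str = "erdos_renyi"    # or "scale_free"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_proteins <= 0 or self.n_tissues <= 0 or self.n_pathways < 0:
            raise ValueError("sizes must be positive")
        if self.n_replicates_per_group < 2:
            raise ValueError("need >=2 replicates per group")
        if not (0 <= self.metabolic_fraction <= 1):
            raise ValueError("metabolic_fraction must lie in [0, 1]")
        proteins = set(self.protein_ids())
        for axis in self.planted_axes:
            members = [axis.ligand, axis.receptor, axis.upstream,
                       axis.downstream]
            if len(set(members)) != 4:
                raise ValueError(f"axis proteins must be distinct: {axis}")
            unknown = [m for m in members if m not in proteins]
            if unknown:
                raise ValueError(
                    f"axis protein(s) beyond n_proteins: {unknown}")
            if axis.source == axis.target:
                raise ValueError(f"axis source equals target: {axis}")

    def protein_ids(self) -> list:
        return [f"P{i:04d}" for i in range(self.n_proteins)]

    def tissue_ids(self) -> list:
        names = list(TISSUE_NAMES[:self.n_tissues])
        names += [f"tissue{i}" for i in range(len(names), self.n_tissues)]
        return names

    def axis_proteins(self) -> set:
        out = set()
        for a in self.planted_axes:
            out |= {a.ligand, a.receptor, a.upstream, a.downstream}
        return out


def default_spec(rng_seed: int = 0, **overrides) -> FixtureSpec:
    """The default study: two planted axes among the first three tissues."""
    spec = FixtureSpec(rng_seed=rng_seed, **overrides)
    tissues = spec.tissue_ids()
    axes = [
        PlantedAxis(source=tissues[0], ligand="P0001", receptor="P0002",
                    target=tissues[1 % spec.n_tissues], upstream="P0000",
                    downstream="P0003"),
    ]
    if spec.n_tissues >= 3:
        axes.append(
            PlantedAxis(source=tissues[1], ligand="P0005", receptor="P0006",
                        target=tissues[2], upstream="P0004",
                        downstream="P0007"))
    spec.planted_axes = axes
    spec.validate()
    return spec


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.rng_seed % (2 ** 31), stream])


def _protein_pools(spec: FixtureSpec) -> tuple[list, list]:
    """Deterministic split of non-axis proteins into (secretome candidates,
    DEP-eligible).  Keeping the two disjoint ensures no secreted protein
    other than a planted ligand can ever be differential."""
    rng = _rng(spec, 0)
    axis = spec.axis_proteins()
    rest = [p for p in spec.protein_ids() if p not in axis]
    rng.shuffle(rest)
    n_secreted = max(0, round(spec.secreted_fraction * spec.n_proteins)
                     - len({a.ligand for a in spec.planted_axes}))
    return rest[:n_secreted], rest[n_secreted:]


def generate_background(spec: FixtureSpec):
    """Random directed background plus pathways, secretome and EC numbers.

    Returns (BackgroundNetwork, PathwayCollection, SecretedCatalog,
    EcAnnotation).  All planted-axis edges (upstream->ligand,
    ligand->receptor, receptor->downstream) are inserted; planted ligands
    get no other out-edges.
    """
    rng = _rng(spec, 1)
    proteins = spec.protein_ids()
    n = len(proteins)
    ligands = {a.ligand for a in spec.planted_axes}
    receptors = {a.receptor for a in spec.planted_axes}

    # receptors keep only their planted edges: a receptor with random
    # edges could be retained as a Steiner connector in a third tissue's
    # network and absorb extra (real but unplanted) cross edges
    blocked = ligands | receptors
    edges = []
    if spec.topology == "scale_free":
        # preferential attachment on out-edges: heavier-degree hubs
        weights = np.arange(1, n + 1, dtype=float)
        weights /= weights.sum()
        m = int(spec.mean_out_degree * n)
        us = rng.choice(n, size=m)
        vs = rng.choice(n, size=m, p=weights)
        for ui, vi in zip(us, vs):
            u, v = proteins[ui], proteins[vi]
            if u != v and u not in blocked and v not in receptors:
                edges.append((u, v))
    else:
        p_edge = min(1.0, spec.mean_out_degree / max(1, n - 1))
        for i, u in enumerate(proteins):
            mask = rng.random(n) < p_edge    # one rng draw per row regardless
            if u in blocked:
                continue
            mask[i] = False
            for j in np.flatnonzero(mask):
                v = proteins[j]
                if v not in receptors:
                    edges.append((u, v))
    for a in spec.planted_axes:
        edges.extend([(a.upstream, a.ligand), (a.ligand, a.receptor),
                      (a.receptor, a.downstream)])
    background = BackgroundNetwork.from_edges(edges, nodes=proteins)

    # pathways -------------------------------------------------------------
    n_metabolic = round(spec.metabolic_fraction * spec.n_pathways)
    n_rest = spec.n_pathways - n_metabolic
    n_signaling = n_rest // 2 + n_rest % 2
    classes = (["metabolic"] * n_metabolic + ["signaling"] * n_signaling
               + ["other"] * (n_rest - n_signaling))
    pathways: dict[str, Pathway] = {}
    for i, pw_class in enumerate(classes):
        pid = f"pw{i:04d}"
        members = rng.choice(proteins, size=min(spec.pathway_size, n),
                             replace=False)
        if pw_class == "metabolic":
            subcat = _METABOLIC_SUBCATS[i % len(_METABOLIC_SUBCATS)]
        elif pw_class == "signaling":
            subcat = "signal transduction"
        else:
            subcat = "cellular processes"
        pathways[pid] = Pathway(pid, f"pathway {i}", frozenset(members),
                                pw_class, subcat, excluded=False)
    for j in range(spec.n_excluded_pathways):
        pid = f"pwx{j:03d}"
        members = rng.choice(proteins, size=min(spec.pathway_size, n),
                             replace=False)
        pathways[pid] = Pathway(pid, f"disease map {j}", frozenset(members),
                                "other", "disease", excluded=True)
    collection = PathwayCollection(pathways)

    # secretome ------------------------------------------------------------
    secreted_pool, _ = _protein_pools(spec)
    secreted = (set(secreted_pool) | ligands) - receptors
    catalog = SecretedCatalog(ids=frozenset(secreted))

    # EC numbers for metabolic-pathway members ------------------------------
    ec_map: dict[str, frozenset] = {}
    metabolic_members = set()
    for pw in collection.basic():
        if pw.pw_class == "metabolic":
            metabolic_members |= pw.members
    for prot in sorted(metabolic_members):
        a, b, c, d = rng.integers(1, 7), rng.integers(1, 10), \
            rng.integers(1, 10), rng.integers(1, 100)
        ec_map[prot] = frozenset({f"{a}.{b}.{c}.{d}"})
    ec = EcAnnotation(ec=ec_map)
    return background, collection, catalog, ec


def generate_dep_assignment(spec: FixtureSpec) -> dict:
    """tissue -> {protein: 'up' | 'down'} with every axis protein planted
    in its home tissue and random DEPs drawn from the DEP-eligible pool."""
    rng = _rng(spec, 2)
    _, eligible = _protein_pools(spec)
    assignment: dict[str, dict] = {t: {} for t in spec.tissue_ids()}
    for a in spec.planted_axes:
        assignment[a.source][a.upstream] = "up"
        assignment[a.source][a.ligand] = "up"
        assignment[a.target][a.receptor] = "up"
        assignment[a.target][a.downstream] = "up"
    n_random = round(spec.dep_fraction * spec.n_proteins)
    for tissue in spec.tissue_ids():
        chosen = rng.choice(sorted(eligible), size=min(n_random, len(eligible)),
                            replace=False)
        for prot in chosen:
            assignment[tissue].setdefault(
                prot, "up" if rng.random() < 0.5 else "down")
    return assignment


def generate_atlas(spec: FixtureSpec) -> ExpressionAtlas:
    """Expression atlas exercising the low-expression filter both ways:
    planted ligands are high in their source tissue and >10x lower in
    every other tissue; all other proteins vary within a 10x band."""
    rng = _rng(spec, 3)
    tissues = spec.tissue_ids()
    proteins = spec.protein_ids()
    values = rng.uniform(5.0, 45.0, size=(len(proteins), len(tissues)))
    frame = pd.DataFrame(values, index=proteins, columns=tissues)
    for a in spec.planted_axes:
        frame.loc[a.ligand, :] = 1.0
        frame.loc[a.ligand, a.source] = 200.0
    return ExpressionAtlas(frame=frame)


def generate_abundance(spec: FixtureSpec, dep_assignment: dict) -> dict:
    """tissue -> AbundanceTable with planted group offsets.

    log2 intensity = protein baseline + group offset + Gaussian noise; the
    offset is +/- log2(dep_fold_change) for planted DEPs and 0 otherwise.
    Linear intensities are strictly positive by construction.
    """
    rng = _rng(spec, 4)
    proteins = spec.protein_ids()
    nrep = spec.n_replicates_per_group
    rep_names = [f"con_{i + 1}" for i in range(nrep)] + \
        [f"case_{i + 1}" for i in range(nrep)]
    groups = {r: ("control" if r.startswith("con") else "case")
              for r in rep_names}
    out = {}
    shift = np.log2(spec.dep_fold_change)
    for tissue in spec.tissue_ids():
        baseline = rng.normal(10.0, 1.0, size=len(proteins))
        offsets = np.zeros(len(proteins))
        planted = dep_assignment.get(tissue, {})
        for i, prot in enumerate(proteins):
            if prot in planted:
                offsets[i] = shift if planted[prot] == "up" else -shift
        noise = rng.normal(0.0, spec.log2_noise_sd,
                           size=(len(proteins), 2 * nrep))
        log2 = baseline[:, None] + noise
        log2[:, nrep:] += offsets[:, None]
        frame = pd.DataFrame(np.exp2(log2), index=proteins, columns=rep_names)
        out[tissue] = AbundanceTable(tissue=tissue, frame=frame,
                                     groups=dict(groups))
    return out


@dataclass
class Bundle:
    """One complete in-memory study with its planted truths."""

    spec: FixtureSpec
    background: BackgroundNetwork
    pathways: PathwayCollection
    catalog: SecretedCatalog
    ec: EcAnnotation
    atlas: ExpressionAtlas
    abundances: dict               # tissue -> AbundanceTable
    dep_assignment: dict           # tissue -> {protein: direction}


def generate_bundle(spec: FixtureSpec) -> Bundle:
    background, pathways, catalog, ec = generate_background(spec)
    dep_assignment = generate_dep_assignment(spec)
    return Bundle(
        spec=spec, background=background, pathways=pathways, catalog=catalog,
        ec=ec, atlas=generate_atlas(spec),
        abundances=generate_abundance(spec, dep_assignment),
        dep_assignment=dep_assignment,
    )


def generate_fixture_bundle(spec: FixtureSpec, out_dir) -> dict:
    """Write every external-interface file plus a planted-truth manifest.

    Files: edges.tsv, pathways.gmt, pathway_categories.tsv, secreted.tsv,
    atlas.tsv, ec.tsv, abundance_<tissue>.tsv, groups.json, manifest.json.
    Returns the manifest dict.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    bundle = generate_bundle(spec)
    bundle.background.to_edge_list(os.path.join(out_dir, "edges.tsv"))
    write_gmt(bundle.pathways, os.path.join(out_dir, "pathways.gmt"))
    write_pathway_categories(bundle.pathways,
                             os.path.join(out_dir, "pathway_categories.tsv"))
    write_secreted(bundle.catalog, os.path.join(out_dir, "secreted.tsv"))
    write_expression_atlas(bundle.atlas, os.path.join(out_dir, "atlas.tsv"))
    write_ec(bundle.ec, os.path.join(out_dir, "ec.tsv"))
    groups = None
    for tissue, table in bundle.abundances.items():
        write_abundance(table, os.path.join(out_dir,
                                            f"abundance_{tissue}.tsv"))
        groups = table.groups
    manifest = {
        "rng_seed": spec.rng_seed,
        "tissues": spec.tissue_ids(),
        "groups": groups,
        "planted_axes": [a._asdict() for a in spec.planted_axes],
        "planted_deps": {t: dict(sorted(d.items()))
                         for t, d in bundle.dep_assignment.items()},
        "files": {
            "edges": "edges.tsv", "gmt": "pathways.gmt",
            "categories": "pathway_categories.tsv",
            "secreted": "secreted.tsv", "atlas": "atlas.tsv", "ec": "ec.tsv",
            "abundance": {t: f"abundance_{t}.tsv"
                          for t in spec.tissue_ids()},
        },
    }
    with open(os.path.join(out_dir, "manifest.json"), "w",
              encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
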
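"""End-to-end pipeline: configuration, validation and orchestration.

Stages run in order — differential calling, core-network construction,
null-model validation, interface assembly, functional quantification —
with every intermediate artifact written as a plain file, so each stage is
independently re-runnable from the CLI.  All randomness flows from the
single ``rng_seed`` in the configuration; reports carry no timestamps, so
two runs with the same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import yaml

from . import __version__
from .annotation import classify_all, secreted_partition, write_roles
from .core_network import build_tissue_network, randomize_validate
from .differential import call_deps, count_consistent_overlap, \
    differential_rate_test
from .enrichment import enrich, write_enrichment
from .functional_quant import summarize
from .interface import build_interface
from .knowledge_io import (KnowledgeError, load_abundance, load_background,
                           load_ec, load_expression_atlas, load_pathways,
                           load_secreted)


@dataclass
class RunConfig:
    """Input paths, thresholds and the run seed.

    Threshold defaults are the method's canonical values: fold-change gate
    1.2 / 0.83 with raw p < 0.05 for DEPs, FDR < 0.05 in enrichment,
    |Z| > 2.33 against 100 nulls for network validation, and a 10x
    low-expression fold for the interface filter.
    """

    edges: str = ""
    gmt: str = ""
    categories: str = ""
    secreted: str = ""
    atlas: str = ""
    ec: str = ""
    abundance: dict = field(default_factory=dict)   # tissue -> path
    groups: dict = field(default_factory=dict)      # replicate -> group
    out_dir: str = "results"
    fc_up: float = 1.2
    fc_down: float = 0.83
    alpha: float = 0.05
    fdr: float = 0.05
    z_threshold: float = 2.33
    fold: float = 10.0
    n_null: int = 100
    rng_seed: int = 0
    receptor_dep: bool = False
    exact_steiner: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(os.fspath(path), "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(os.fspath(path), "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def input_paths(self) -> dict:
        paths = {"edges": self.edges, "gmt": self.gmt,
                 "categories": self.categories, "secreted": self.secreted,
                 "atlas": self.atlas}
        if self.ec:
            paths["ec"] = self.ec
        for tissue, p in self.abundance.items():
            paths[f"abundance[{tissue}]"] = p
        return paths


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_inputs(config: RunConfig) -> dict:
    for name, path in config.input_paths().items():
        if not os.path.exists(path):
            raise FileNotFoundError(f"missing input {name}: {path}")
    inputs = {
        "background": load_background(config.edges),
        "pathways": load_pathways(config.gmt, config.categories),
        "catalog": load_secreted(config.secreted),
        "atlas": load_expression_atlas(config.atlas),
        "ec": load_ec(config.ec) if config.ec else None,
        "abundances": {},
    }
    for tissue, path in config.abundance.items():
        inputs["abundances"][tissue] = load_abundance(
            path, config.groups, tissue=tissue)
    return inputs


def validate_inputs(config: RunConfig) -> dict:
    """Run every loader in check mode and report problems without writing
    any analysis output.  Loader errors become report entries, not
    exceptions."""
    report = {"errors": [], "warnings": []}
    for name, path in config.input_paths().items():
        if not os.path.exists(path):
            report["errors"].append(f"missing input {name}: {path}")
    if report["errors"]:
        return report
    try:
        inputs = load_inputs(config)
    except (KnowledgeError, ValueError, OSError) as exc:
        report["errors"].append(str(exc))
        return report
    background = inputs["background"]
    if background.n_self_loops_dropped:
        report["warnings"].append(
            f"{background.n_self_loops_dropped} self-loop edge(s) dropped "
            "from the background")
    atlas_proteins = inputs["atlas"].proteins
    for tissue, table in inputs["abundances"].items():
        unmapped = len(set(table.proteins) - background.nodes)
        if unmapped:
            report["warnings"].append(
                f"{unmapped} detected protein(s) in {tissue} absent from "
                "the background network")
        missing_atlas = len(set(table.proteins) - atlas_proteins)
        if missing_atlas:
            report["warnings"].append(
                f"{missing_atlas} detected protein(s) in {tissue} missing "
                "from the expression atlas")
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all exports plus a machine-readable run
    report under ``config.out_dir``.  Returns the report dict."""
    os.makedirs(config.out_dir, exist_ok=True)
    report = {"version": __version__, "rng_seed": config.rng_seed,
              "thresholds": {"fc_up": config.fc_up, "fc_down": config.fc_down,
                             "alpha": config.alpha, "fdr": config.fdr,
                             "z_threshold": config.z_threshold,
                             "fold": config.fold, "n_null": config.n_null},
              "stages": {}}

    def out(name: str) -> str:
        return os.path.join(config.out_dir, name)

    try:
        inputs = load_inputs(config)
    except Exception as exc:
        raise StageError("load", exc) from exc
    background, pathways = inputs["background"], inputs["pathways"]
    catalog, atlas = inputs["catalog"], inputs["atlas"]
    tissues = sorted(inputs["abundances"])

    # -- differential -------------------------------------------------------
    try:
        dep_tables = {}
        for tissue in tissues:
            dep = call_deps(inputs["abundances"][tissue], fc_up=config.fc_up,
                            fc_down=config.fc_down, alpha=config.alpha)
            dep.to_tsv(out(f"deps_{tissue}.tsv"))
            dep_tables[tissue] = dep
        stage = {t: {"detected": len(dep_tables[t].detected),
                     "deps": len(dep_tables[t].deps)} for t in tissues}
        if len(tissues) >= 2:
            stage["consistent_overlap"] = count_consistent_overlap(
                list(dep_tables.values()))
        report["stages"]["differential"] = stage
    except Exception as exc:
        raise StageError("differential", exc) from exc

    # -- secreted partition and differential rates --------------------------
    try:
        stage = {}
        for tissue in tissues:
            parts = secreted_partition(dep_tables[tissue].detected, catalog)
            entry = {"secreted": len(parts["secreted"]),
                     "non_secreted": len(parts["non_secreted"])}
            try:
                entry["rate_test"] = differential_rate_test(
                    dep_tables[tissue], parts["secreted"])
            except ValueError as exc:
                entry["rate_test"] = {"error": str(exc)}
            stage[tissue] = entry
        report["stages"]["secreted"] = stage
    except Exception as exc:
        raise StageError("secreted", exc) from exc

    # -- core networks ------------------------------------------------------
    try:
        networks = {}
        stage = {}
        for tissue in tissues:
            net = build_tissue_network(tissue, dep_tables[tissue].deps,
                                       background,
                                       exact_small=config.exact_steiner)
            net.to_graphml(out(f"network_{tissue}.graphml"))
            net.to_edge_list(out(f"network_{tissue}.tsv"))
            networks[tissue] = net
            stage[tissue] = dict(net.stats)
        report["stages"]["networks"] = stage
    except Exception as exc:
        raise StageError("networks", exc) from exc

    # -- randomization validation ------------------------------------------
    try:
        stage = {}
        for i, tissue in enumerate(tissues):
            rep = randomize_validate(
                networks[tissue], background,
                n_seeds=len(dep_tables[tissue].deps & background.nodes),
                n_null=config.n_null, z_threshold=config.z_threshold,
                rng_seed=(config.rng_seed + i) % (2 ** 31))
            stage[tissue] = rep.to_dict()
        with open(out("randomization.json"), "w", encoding="utf-8") as fh:
            json.dump(stage, fh, indent=2, sort_keys=True)
            fh.write("\n")
        report["stages"]["randomization"] = {
            t: {"passed": stage[t]["passed"]} for t in tissues}
    except Exception as exc:
        raise StageError("randomization", exc) from exc

    # -- roles export (optional EC annotation) ------------------------------
    if inputs["ec"] is not None:
        try:
            all_detected = set().union(*(dep_tables[t].detected
                                         for t in tissues))
            roles = classify_all(sorted(all_detected), inputs["ec"], pathways)
            write_roles(roles, pathways, out("roles.tsv"))
            report["stages"]["roles"] = {
                "metabolic_enzyme": sum(1 for r in roles.values()
                                        if r.role == "metabolic_enzyme"),
                "signaling_protein": sum(1 for r in roles.values()
                                         if r.role == "signaling_protein")}
        except Exception as exc:
            raise StageError("roles", exc) from exc

    # -- interface ----------------------------------------------------------
    try:
        iface = build_interface(dep_tables, networks, background, catalog,
                                atlas, fold=config.fold,
                                receptor_dep=config.receptor_dep)
        iface.to_tsv(out("interface.tsv"))
        iface.to_graphml(out("interface.graphml"))
        report["stages"]["interface"] = {
            "cross_edges": len(iface.cross_edges),
            "upstream_pairs": sum(len(v) for v in
                                  iface.upstream_pairs.values()),
            "downstream_pairs": sum(len(v) for v in
                                    iface.downstream_pairs.values())}
    except Exception as exc:
        raise StageError("interface", exc) from exc

    # -- functional quantification -----------------------------------------
    try:
        universe = set()
        for pw in pathways.basic():
            universe |= pw.members
        backgrounds = {t: dep_tables[t].detected & universe for t in tissues}
        summary = summarize(iface, dep_tables, pathways, backgrounds,
                            fdr_cut=config.fdr)
        summary.to_json(out("functional_summary.json"))
        for ps in summary.process_sets:
            if ps.enriched:
                write_enrichment(ps.enriched, pathways,
                                 out(f"enriched_{ps.tissue}_{ps.side}.tsv"),
                                 fdr_cut=config.fdr)
        report["stages"]["functional"] = {
            "n_sets_with_enrichment": len(summary.proportions),
            "background_metabolic_proportion":
                summary.background["proportion"],
            "z_test": summary.z_test.to_dict() if summary.z_test else None}
    except Exception as exc:
        raise StageError("functional", exc) from exc

    with open(out("run_report.json"), "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
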
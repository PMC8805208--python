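"""Functional quantification of the cross-tissue interface.

Per tissue, the *upstream process set* (upstream regulator DEPs plus the
ligands they feed) and the *downstream process set* (receptors plus their
downstream effector DEPs) are enriched against the pathway collection.
The fraction of enriched pathways that are metabolic is compared, across
process sets, to the background fraction of metabolic pathways among all
non-excluded ("basic") pathways with a one-sample z-test; each directed
tissue pair is then characterized by the dominant subcategory of its
source tissue's upstream enrichment.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .enrichment import EnrichmentResult, enrich, significant
from .interface import CrosstalkInterface
from .knowledge_io import PathwayCollection


@dataclass
class ProcessSet:
    tissue: str
    side: str                       # 'upstream' | 'downstream'
    proteins: set
    enriched: list = field(default_factory=list)  # significant results only


@dataclass
class ZTestResult:
    mean_prop: float
    ci_low: float
    ci_high: float
    p0: float
    z: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {"mean_prop": self.mean_prop, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "p0": self.p0, "z": self.z,
                "p_value": self.p_value, "n": self.n}


def assemble_process_sets(interface: CrosstalkInterface, dep_tables: dict,
                          pathways: PathwayCollection, backgrounds: dict,
                          fdr_cut: float = 0.05) -> list[ProcessSet]:
    """Build and enrich the upstream/downstream process set of each tissue.

    ``backgrounds`` maps tissue -> background protein set for enrichment
    (typically the tissue's detected pool intersected with the pathway
    universe).  Process-set proteins outside the tissue background (e.g.
    Steiner-retained receptors never detected in that tissue) are dropped
    from the query before testing.  Empty sets yield empty enrichment.
    """
    out = []
    for tissue in sorted(dep_tables):
        upstream = interface.upstream_regulators_of(tissue) | \
            interface.ligands_of(tissue)
        downstream = interface.receptors_of(tissue) | \
            interface.downstream_effectors_of(tissue)
        for side, proteins in (("upstream", upstream),
                               ("downstream", downstream)):
            query = set(proteins) & set(backgrounds[tissue])
            enriched: list[EnrichmentResult] = []
            if query:
                enriched = significant(
                    enrich(query, pathways, backgrounds[tissue]), fdr_cut)
            out.append(ProcessSet(tissue=tissue, side=side,
                                  proteins=set(proteins), enriched=enriched))
    return out


def metabolic_proportion(enriched: list, pathways: PathwayCollection):
    """Fraction of enriched pathways classed metabolic; None when empty."""
    if not enriched:
        return None
    n_met = sum(1 for r in enriched
                if pathways[r.pathway].pw_class == "metabolic")
    return n_met / len(enriched)


def background_metabolic_proportion(pathways: PathwayCollection) -> dict:
    """Metabolic share of the non-excluded (basic) pathway universe."""
    basic = pathways.basic()
    if not basic:
        raise ValueError("no non-excluded pathways in the collection")
    metabolic = sum(1 for p in basic if p.pw_class == "metabolic")
    return {"metabolic": metabolic, "total": len(basic),
            "proportion": metabolic / len(basic)}


def one_sample_z(proportions, p0: float) -> ZTestResult:
    """One-sample z-test of mean(proportions) against p0.

    z = (mean - p0) / (sd / sqrt(n)) with the sample sd (ddof=1); the
    two-sided p comes from the standard normal, and the 95% CI is
    mean +/- 1.96 * sd / sqrt(n).
    """
    arr = np.asarray(list(proportions), dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError("insufficient spread: need n >= 2 proportions")
    sd = float(arr.std(ddof=1))
    if sd == 0:
        raise ValueError("insufficient spread: sample sd is 0")
    mean = float(arr.mean())
    se = sd / math.sqrt(n)
    z = (mean - p0) / se
    p_value = float(2 * stats.norm.sf(abs(z)))
    return ZTestResult(mean_prop=mean, ci_low=mean - 1.96 * se,
                       ci_high=mean + 1.96 * se, p0=p0, z=z,
                       p_value=p_value, n=n)


def dominant_upstream_category(process_set: ProcessSet,
                               pathways: PathwayCollection,
                               weighted: bool = False):
    """Subcategory holding the plurality of a set's enriched pathways.

    Ties are reported as the sorted list of all tied names; empty
    enrichment yields None.  With ``weighted=True`` pathways count by
    -log10(p) instead of 1 each.
    """
    if not process_set.enriched:
        return None
    scores: dict[str, float] = {}
    for r in process_set.enriched:
        subcat = pathways[r.pathway].subcategory
        w = -math.log10(max(r.p_value, 1e-300)) if weighted else 1.0
        scores[subcat] = scores.get(subcat, 0.0) + w
    best = max(scores.values())
    winners = sorted(s for s, v in scores.items() if v == best)
    return winners


@dataclass
class FunctionalSummary:
    process_sets: list
    proportions: dict               # (tissue, side) -> proportion (non-empty)
    background: dict                # metabolic / total / proportion
    z_test: ZTestResult | None
    dominant_by_pair: dict          # (source, target) -> subcategory list

    def to_json(self, dest) -> None:
        payload = {
            "per_set_proportions": {f"{t}:{s}": v for (t, s), v
                                    in self.proportions.items()},
            "n_process_sets_with_enrichment": len(self.proportions),
            "background": self.background,
            "z_test": self.z_test.to_dict() if self.z_test else None,
            "dominant_by_pair": {f"{a}->{b}": v for (a, b), v
                                 in self.dominant_by_pair.items()},
        }
        handle, close = (dest, False) if hasattr(dest, "write") else (
            open(os.fspath(dest), "w", encoding="utf-8"), True)
        try:
            json.dump(payload, handle, indent=2, sort_keys=True)
            handle.write("\n")
        finally:
            if close:
                handle.close()


def summarize(interface: CrosstalkInterface, dep_tables: dict,
              pathways: PathwayCollection, backgrounds: dict,
              fdr_cut: float = 0.05) -> FunctionalSummary:
    """End-to-end functional quantification of a built interface.

    Process sets with empty enrichment are excluded from the metabolic-
    proportion average (the effective n is reported); the z-test is
    omitted (None) when fewer than two informative sets exist or their
    proportions do not vary.
    """
    process_sets = assemble_process_sets(interface, dep_tables, pathways,
                                         backgrounds, fdr_cut)
    proportions = {}
    for ps in process_sets:
        prop = metabolic_proportion(ps.enriched, pathways)
        if prop is not None:
            proportions[(ps.tissue, ps.side)] = prop
    background = background_metabolic_proportion(pathways)
    z_test = None
    values = list(proportions.values())
    if len(values) >= 2 and float(np.std(values, ddof=1)) > 0:
        z_test = one_sample_z(values, background["proportion"])

    upstream_by_tissue = {ps.tissue: ps for ps in process_sets
                          if ps.side == "upstream"}
    dominant = {}
    for source, target in interface.tissue_pairs():
        dominant[(source, target)] = dominant_upstream_category(
            upstream_by_tissue[source], pathways)
    return FunctionalSummary(process_sets=process_sets,
                             proportions=proportions, background=background,
                             z_test=z_test, dominant_by_pair=dominant)
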
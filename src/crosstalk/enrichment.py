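"""Hypergeometric over-representation analysis with Benjamini-Hochberg FDR.

Pathways are tested against a caller-supplied background (by default the
tissue's detected proteins intersected with the pathway universe, since
proteomics detection defines the sampling frame).  Excluded (disease /
global-map) pathways are dropped before testing, and pathways with no
background members after intersection are skipped rather than scored.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .knowledge_io import PathwayCollection


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    k: int          # hits in query
    K: int          # pathway size in background
    n: int          # query size in background
    N: int          # background size
    p_value: float
    fdr: float

    @property
    def significant(self) -> bool:
        return self.fdr < 0.05


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper tail P(X >= k) of the hypergeometric(N, K, n).

    This is the probability of drawing at least k members of a K-sized
    category in n draws without replacement from a pool of N.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(
            f"invalid hypergeometric bounds N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values) -> list[float]:
    """Benjamini-Hochberg adjusted p-values, input order preserved.

    Each adjusted value is min over j >= rank of (m * p_(j) / j), capped at
    1 (the right-to-left monotone minimum).
    """
    p_values = list(p_values)
    if not p_values:
        raise ValueError("empty p-value list")
    for p in p_values:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value out of (0, 1]: {p}")
    _, adjusted, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(q) for q in adjusted]


def enrich(query: set, pathways: PathwayCollection, background: set,
           fdr_cut: float = 0.05) -> list[EnrichmentResult]:
    """Over-representation of *query* in each non-excluded pathway.

    Memberships are intersected with *background* before counting; the
    query must be a subset of the background.  Results are sorted by
    (fdr, p, pathway id) for reproducible ranking.
    """
    query, background = set(query), set(background)
    if not query <= background:
        offenders = sorted(query - background)
        raise ValueError(
            f"query proteins outside the background: {offenders[:10]}")
    N, n = len(background), len(query)
    tested = []
    for pw in sorted(pathways.basic(), key=lambda p: p.id):
        members = pw.members & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        tested.append((pw.id, k, K, hypergeom_upper_tail(N, K, n, k)))
    if not tested:
        return []
    fdrs = bh_fdr([t[3] for t in tested])
    results = [EnrichmentResult(pathway=pid, k=k, K=K, n=n, N=N,
                                p_value=p, fdr=q)
               for (pid, k, K, p), q in zip(tested, fdrs)]
    results.sort(key=lambda r: (r.fdr, r.p_value, r.pathway))
    return results


def significant(results: list[EnrichmentResult],
                fdr_cut: float = 0.05) -> list[EnrichmentResult]:
    return [r for r in results if r.fdr < fdr_cut]


def top_terms_overlap(results_by_tissue: dict, k: int = 20) -> dict:
    """Incidence of each tissue's top-k enriched terms: term -> tissue set.

    Each tissue's list must already be ranked ascending by (fdr, p); ties
    at the rank-k boundary are broken lexicographically by pathway id,
    which :func:`enrich` guarantees.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    incidence: dict[str, set] = {}
    for tissue, results in results_by_tissue.items():
        ranked = sorted(results, key=lambda r: (r.fdr, r.p_value, r.pathway))
        for r in ranked[:k]:
            incidence.setdefault(r.pathway, set()).add(tissue)
    return incidence


def write_enrichment(results: list[EnrichmentResult],
                     pathways: PathwayCollection, dest,
                     fdr_cut: float = 0.05) -> None:
    """Export TSV: pathway, name, class, subcategory, k, K, n, N, p_value,
    fdr, significant."""
    handle, close = (dest, False) if hasattr(dest, "write") else (
        open(os.fspath(dest), "w", encoding="utf-8"), True)
    try:
        handle.write("pathway\tname\tclass\tsubcategory\tk\tK\tn\tN\t"
                     "p_value\tfdr\tsignificant\n")
        for r in results:
            pw = pathways[r.pathway]
            handle.write(
                f"{r.pathway}\t{pw.name}\t{pw.pw_class}\t{pw.subcategory}\t"
                f"{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p_value:.6g}\t{r.fdr:.6g}\t"
                f"{'true' if r.fdr < fdr_cut else 'false'}\n")
    finally:
        if close:
            handle.close()
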
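"""Per-tissue differential protein calling and the associated count and
proportion statistics.

A protein is differentially expressed (DEP) when its case/control fold
change passes the gate (>= `fc_up` or <= `fc_down`, both inclusive) and the
raw two-sided t-test p-value on log2 intensities is below `alpha`.  No
multiple-testing correction is applied at this stage; FDR control happens
later, in pathway enrichment.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .knowledge_io import AbundanceTable

FC_UP_DEFAULT = 1.2
FC_DOWN_DEFAULT = 0.83
ALPHA_DEFAULT = 0.05


@dataclass
class DepTable:
    """Differential results for one tissue.

    `frame` has one row per detected protein with columns ``log2fc``,
    ``fold_change``, ``p_value``, ``direction`` (up/down/none), ``is_dep``
    and ``untestable``.
    """

    tissue: str
    frame: pd.DataFrame

    @property
    def detected(self) -> set:
        return set(self.frame.index)

    @property
    def deps(self) -> set:
        return set(self.frame.index[self.frame["is_dep"]])

    def direction_of(self, protein: str) -> str:
        return str(self.frame.at[protein, "direction"])

    def is_dep(self, protein: str) -> bool:
        return protein in self.frame.index and bool(self.frame.at[protein, "is_dep"])

    def to_tsv(self, dest) -> None:
        handle, close = (dest, False) if hasattr(dest, "write") else (
            open(os.fspath(dest), "w", encoding="utf-8"), True)
        try:
            self.frame.to_csv(handle, sep="\t", index_label="protein")
        finally:
            if close:
                handle.close()


def dep_flag(fold_change: float, p_value: float,
             fc_up: float = FC_UP_DEFAULT, fc_down: float = FC_DOWN_DEFAULT,
             alpha: float = ALPHA_DEFAULT) -> bool:
    """Apply the DEP gate: (FC >= fc_up or FC <= fc_down) and p < alpha.

    Both fold-change thresholds are inclusive, exactly as printed.
    """
    if not (fc_down < 1.0 < fc_up):
        raise ValueError("thresholds must satisfy fc_down < 1 < fc_up")
    if math.isnan(p_value):
        return False
    return (fold_change >= fc_up or fold_change <= fc_down) and p_value < alpha


def call_deps(table: AbundanceTable, fc_up: float = FC_UP_DEFAULT,
              fc_down: float = FC_DOWN_DEFAULT, alpha: float = ALPHA_DEFAULT,
              welch: bool = False) -> DepTable:
    """Call DEPs on one tissue's abundance table.

    The fold change is the geometric-mean ratio, 2**(mean(log2 case) -
    mean(log2 control)); the p-value comes from a two-sided two-sample
    t-test on the log2 intensities (pooled variance by default, Welch
    behind the `welch` flag).  Proteins with zero within-group variance in
    both groups and equal means have no defined test and are flagged
    untestable (never DEP); zero variance with unequal means is infinitely
    significant (p = 0).
    """
    if not (fc_down < 1.0 < fc_up):
        raise ValueError("thresholds must satisfy fc_down < 1 < fc_up")
    log2 = np.log2(table.frame.to_numpy(dtype=float))
    con_cols = [i for i, c in enumerate(table.frame.columns)
                if table.groups[c] == "control"]
    case_cols = [i for i, c in enumerate(table.frame.columns)
                 if table.groups[c] == "case"]
    con, case = log2[:, con_cols], log2[:, case_cols]

    diff = case.mean(axis=1) - con.mean(axis=1)
    fc = np.exp2(diff)

    import warnings
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        # zero-variance rows are re-derived explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(case, con, axis=1, equal_var=not welch)
    p = np.asarray(res.pvalue, dtype=float)

    # constant replicate rows, detected by range (variance of identical
    # floats can round to a subnormal instead of 0)
    zero_var = (np.ptp(con, axis=1) == 0) & (np.ptp(case, axis=1) == 0)
    equal_means = np.isclose(diff, 0.0)
    untestable = zero_var & equal_means
    # degenerate but separated groups: the test statistic diverges
    p = np.where(zero_var & ~equal_means, 0.0, p)
    p = np.where(untestable, np.nan, p)

    direction = np.where(fc > 1, "up", np.where(fc < 1, "down", "none"))
    is_dep = np.array([dep_flag(f, pv, fc_up, fc_down, alpha)
                       for f, pv in zip(fc, p)])

    frame = pd.DataFrame(
        {"log2fc": diff, "fold_change": fc, "p_value": p,
         "direction": direction, "is_dep": is_dep, "untestable": untestable},
        index=table.frame.index.copy(),
    )
    return DepTable(tissue=table.tissue, frame=frame)


def count_consistent_overlap(tables: list[DepTable]) -> int:
    """Count proteins DEP in *every* table with the same direction in all.

    This is the shared-response count across tissues: a protein up in two
    tissues but down in the third does not contribute.
    """
    if len(tables) < 2:
        raise ValueError("need >=2 tables")
    common = set.intersection(*(t.deps for t in tables))
    n = 0
    for p in common:
        directions = {t.direction_of(p) for t in tables}
        if len(directions) == 1:
            n += 1
    return n


def chi_square_2x2(a: int, b: int, c: int, d: int) -> dict:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]], df = 1, no
    continuity correction: N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("cell counts must be non-negative")
    n = a + b + c + d
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("degenerate table: zero margin")
    statistic = n * (a * d - b * c) ** 2 / math.prod(margins)
    p_value = float(stats.chi2.sf(statistic, df=1))
    return {"statistic": float(statistic), "p_value": p_value}


def differential_rate_test(dep: DepTable, partition: set) -> dict:
    """Compare DEP rates inside vs outside a protein partition (e.g.
    secreted vs non-secreted) with the 2x2 chi-square test."""
    if not partition <= dep.detected:
        offenders = sorted(partition - dep.detected)[:5]
        raise ValueError(
            f"partition is not a subset of detected proteins, e.g. {offenders}")
    if not partition or partition == dep.detected:
        raise ValueError("degenerate table: partition empty or all of detected")
    deps = dep.deps
    a = len(deps & partition)                     # DEP, in partition
    b = len(partition) - a                        # non-DEP, in partition
    out = dep.detected - partition
    c = len(deps & out)                           # DEP, out
    d = len(out) - c
    result = chi_square_2x2(a, b, c, d)
    result["rate_in"] = a / len(partition)
    result["rate_out"] = c / len(out)
    return result
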
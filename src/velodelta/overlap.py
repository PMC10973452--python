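"""Cross-dataset replication: significance of gene-set overlap.

Whether the differential-velocity genes found in one cohort replicate in an
independent cohort is quantified per cell type by the overlap of the two
significant-gene sets against the universe of genes tested in both, with a
one-sided (enrichment) Fisher exact p-value and the sample odds ratio.  The
replication criterion follows the convention p < 0.01 and odds ratio > 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["OverlapResult", "hypergeom_tail", "fisher_overlap", "summarize_overlap"]


@dataclass
class OverlapResult:
    cell_type: str
    n_universe: int
    n_a: int
    n_b: int
    n_overlap: int
    odds_ratio: float
    p_fisher: float
    significant: bool
    haldane_corrected: bool = False
    degenerate: bool = False


def hypergeom_tail(k, N, a, b):
    """P(X >= k) for X ~ Hypergeom(N, a, b): the one-sided enrichment
    p-value of a 2x2 table [[k, a-k], [b-k, N-a-b+k]].  Vectorized."""
    k = np.asarray(k)
    return stats.hypergeom.sf(k - 1, N, a, b)


def fisher_overlap(
    set_a,
    set_b,
    universe,
    cell_type: str = "all",
    p_thresh: float = 0.01,
) -> OverlapResult:
    """One-sided Fisher exact test of the overlap of two gene sets.

    Both sets must be subsets of ``universe``.  The odds ratio is the sample
    odds ratio of the 2x2 table; when a zero cell occurs the Haldane 0.5
    correction is applied and flagged.  ``significant`` requires p below
    ``p_thresh`` AND odds ratio > 1; a degenerate table (a margin equal to 0
    or the whole universe) is flagged and never significant.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("set_a and set_b must be subsets of the universe")
    N, a, b = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)

    table = np.array([[k, a - k], [b - k, N - a - b + k]], dtype=float)
    degenerate = a in (0, N) or b in (0, N)
    p = float(hypergeom_tail(k, N, a, b))
    haldane = False
    if (table == 0).any():
        table = table + 0.5
        haldane = True
    odds = float(table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0]))
    return OverlapResult(
        cell_type=cell_type,
        n_universe=N,
        n_a=a,
        n_b=b,
        n_overlap=k,
        odds_ratio=odds,
        p_fisher=p,
        significant=bool(not degenerate and p < p_thresh and odds > 1.0),
        haldane_corrected=haldane,
        degenerate=degenerate,
    )


def summarize_overlap(results, total_b: int):
    """Total replication bookkeeping across cell types.

    ``results`` may be :class:`OverlapResult` objects or raw per-cell-type
    overlap counts; ``total_b`` is the total number of significant genes in
    the replication dataset.  Returns (total_overlap, percent_of_b) with the
    percentage rounded to the nearest integer, plus per-cell-type Venn-style
    counts when full results are given.
    """
    counts = [
        r.n_overlap if isinstance(r, OverlapResult) else int(r) for r in results
    ]
    total = int(sum(counts))
    percent = int(round(100.0 * total / total_b)) if total_b else 0
    venn = [
        {
            "cell_type": r.cell_type,
            "only_a": r.n_a - r.n_overlap,
            "only_b": r.n_b - r.n_overlap,
            "overlap": r.n_overlap,
        }
        for r in results
        if isinstance(r, OverlapResult)
    ]
    return total, percent, venn
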
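"""Group-wise differential velocity/expression with a subject-level null.

Cells from the same subject are correlated, so permuting cell labels between
groups overstates the effective sample size (pseudoreplication) and is
anti-conservative.  The null here reassigns whole *subjects* to groups
(preserving group sizes), carrying each subject's cells together, and
recomputes the Wilcoxon rank-sum U statistic for every reassignment.  The
two-sided empirical p-value uses the add-one estimator

    p = (1 + #{ |U* - mu*| >= |U - mu| }) / (n_perm + 1),

centering each draw at its own null mean mu = n1*n2/2 (cell counts per group
can change when subjects contribute unequal numbers of cells).

Significance calls combine a Benjamini-Hochberg q-value threshold with a
log2 fold-change threshold on group means (defaults q < 0.05, |log2fc| >
0.25).  Velocity means can be negative: a sign flip between the groups is
itself a strong dynamic difference, so sign-discordant genes are flagged and
treated as exceeding any fold-change threshold; two negative means use the
magnitude ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "group_fold_change",
    "wilcoxon_permutation",
    "fdr_adjust",
    "call_significant",
    "length_bias_check",
    "differential_table",
]


def group_fold_change(values, groups, group_a, group_b):
    """log2 ratio of group means per gene, with sign-discordance handling.

    Returns (log2fc, discordant).  Both means positive -> log2(mean_a /
    mean_b); both negative -> log2(|mean_a| / |mean_b|); opposite signs or a
    zero mean -> discordant flag set and log2fc = +/-inf (sign of
    mean_a - mean_b), which exceeds any finite threshold.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    in_a, in_b = groups == group_a, groups == group_b
    if not in_a.any() or not in_b.any():
        raise ValueError(f"empty group among ({group_a!r}, {group_b!r})")
    with np.errstate(invalid="ignore"):
        ma = np.nanmean(values[in_a], axis=0)
        mb = np.nanmean(values[in_b], axis=0)
    ma, mb = np.atleast_1d(ma), np.atleast_1d(mb)
    log2fc = np.full(ma.shape, np.nan)
    discordant = np.zeros(ma.shape, dtype=bool)

    both_pos = (ma > 0) & (mb > 0)
    both_neg = (ma < 0) & (mb < 0)
    log2fc[both_pos] = np.log2(ma[both_pos] / mb[both_pos])
    log2fc[both_neg] = np.log2(np.abs(ma[both_neg]) / np.abs(mb[both_neg]))
    disc = ~(both_pos | both_neg)
    discordant[disc] = True
    log2fc[disc] = np.where(ma[disc] >= mb[disc], np.inf, -np.inf)
    return log2fc, discordant


def _u_statistic_from_ranksums(rank_sums, n1, n2):
    return rank_sums - n1 * (n1 + 1) / 2.0


def wilcoxon_permutation(
    values,
    cell_groups,
    subject_of_cell,
    group_a,
    group_b,
    n_perm: int = 5000,
    seed: int = 0,
):
    """Observed U and subject-permutation empirical p per gene.

    ``values`` is cells x genes; ranks use average-rank tie handling.  The
    null permutes the subject -> group map uniformly among assignments with
    the observed group sizes; a draw leaving either group without cells is
    resampled (and logged).  Fixed seed => identical p values.

    When the number of distinct reassignments C(n_subjects, n_a) does not
    exceed ``n_perm``, every assignment is enumerated exactly once and the
    p-value is the exact tail fraction (the observed assignment counts
    itself, so p >= 1/N); otherwise assignments are sampled with
    replacement and the add-one Monte-Carlo estimator is used.

    Returns (u_stat, p_emp) arrays of length n_genes.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and np.asarray(cell_groups).shape[0] != 1:
        values = values.T
    cell_groups = np.asarray(cell_groups)
    subject_of_cell = np.asarray(subject_of_cell)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    subjects = pd.unique(subject_of_cell)
    subj_group = {}
    for s in subjects:
        g = cell_groups[subject_of_cell == s]
        if len(set(g)) != 1:
            raise ValueError(f"subject {s!r} spans multiple groups")
        subj_group[s] = g[0]
    n_a_subj = sum(1 for s in subjects if subj_group[s] == group_a)
    n_b_subj = len(subjects) - n_a_subj
    if n_a_subj < 2 or n_b_subj < 2:
        raise ValueError("need >= 2 subjects per group for a permutation null")

    # ranks are permutation-invariant: precompute per-subject rank sums
    ranks = stats.rankdata(values, axis=0)  # average ties
    subj_idx = pd.Series(subject_of_cell).map(
        {s: i for i, s in enumerate(subjects)}
    ).to_numpy()
    n_subj = len(subjects)
    subj_rank_sums = np.zeros((n_subj, values.shape[1]))
    np.add.at(subj_rank_sums, subj_idx, ranks)
    subj_cells = np.bincount(subj_idx, minlength=n_subj).astype(float)

    in_a_subj = np.array([subj_group[s] == group_a for s in subjects])
    n1 = subj_cells[in_a_subj].sum()
    n2 = subj_cells[~in_a_subj].sum()
    u_obs = _u_statistic_from_ranksums(subj_rank_sums[in_a_subj].sum(axis=0), n1, n2)
    dev_obs = np.abs(u_obs - n1 * n2 / 2.0)

    from math import comb

    n_exact = comb(n_subj, n_a_subj)
    exceed = np.zeros(values.shape[1])
    if n_exact <= n_perm:
        from itertools import combinations

        n_used = 0
        for combo in combinations(range(n_subj), n_a_subj):
            mask = np.zeros(n_subj, dtype=bool)
            mask[list(combo)] = True
            m1 = subj_cells[mask].sum()
            m2 = subj_cells[~mask].sum()
            if m1 == 0 or m2 == 0:
                continue
            u_star = _u_statistic_from_ranksums(
                subj_rank_sums[mask].sum(axis=0), m1, m2
            )
            exceed += np.abs(u_star - m1 * m2 / 2.0) >= dev_obs - 1e-9
            n_used += 1
        p_emp = exceed / n_used
        return u_obs, p_emp

    rng = np.random.default_rng(seed)
    n_resampled = 0
    for _ in range(n_perm):
        while True:
            perm = rng.permutation(n_subj)[:n_a_subj]
            mask = np.zeros(n_subj, dtype=bool)
            mask[perm] = True
            m1 = subj_cells[mask].sum()
            m2 = subj_cells[~mask].sum()
            if m1 > 0 and m2 > 0:
                break
            n_resampled += 1
        u_star = _u_statistic_from_ranksums(
            subj_rank_sums[mask].sum(axis=0), m1, m2
        )
        exceed += np.abs(u_star - m1 * m2 / 2.0) >= dev_obs - 1e-9
    if n_resampled:
        logger.warning("resampled %d permutations that emptied a group", n_resampled)
    p_emp = (1.0 + exceed) / (n_perm + 1.0)
    return u_obs, p_emp


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def differential_table(
    values,
    cell_groups,
    subject_of_cell,
    gene_ids,
    group_a,
    group_b,
    metric: str = "velocity",
    cell_type: str = "all",
    n_perm: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene differential table for one cell type and metric.

    Columns: gene, cell_type, metric, log2fc, sign_discordant, u_stat,
    p_emp, q, significant (filled by :func:`call_significant`).
    """
    u, p = wilcoxon_permutation(
        values, cell_groups, subject_of_cell, group_a, group_b,
        n_perm=n_perm, seed=seed,
    )
    log2fc, disc = group_fold_change(values, cell_groups, group_a, group_b)
    tab = pd.DataFrame(
        {
            "gene": list(gene_ids),
            "cell_type": cell_type,
            "metric": metric,
            "log2fc": log2fc,
            "sign_discordant": disc,
            "u_stat": u,
            "p_emp": p,
        }
    )
    tab["q"] = fdr_adjust(tab["p_emp"].to_numpy())
    return call_significant(tab)


def call_significant(
    table: pd.DataFrame, q_thresh: float = 0.05, fc_thresh: float = 0.25
) -> pd.DataFrame:
    """Set the ``significant`` flag: q below threshold AND |log2fc| above
    threshold (sign-discordant rows pass the fold-change part by flag)."""
    table = table.copy()
    passes_fc = table["sign_discordant"] | (table["log2fc"].abs() > fc_thresh)
    table["significant"] = (table["q"] < q_thresh) & passes_fc
    return table


def length_bias_check(u_stats, gene_lengths):
    """Pearson correlation of per-gene U statistics with gene length.

    Guards against over-representation of long unspliced transcripts driving
    the differential signal.  Returns (r, p); constant input is flagged by
    returning (nan, nan) with a warning.
    """
    u_stats = np.asarray(u_stats, dtype=float)
    gene_lengths = np.asarray(gene_lengths, dtype=float)
    if u_stats.shape != gene_lengths.shape:
        raise ValueError("u_stats and gene_lengths must align")
    if np.any(gene_lengths <= 0):
        raise ValueError("gene lengths must be > 0")
    if np.ptp(u_stats) == 0 or np.ptp(gene_lengths) == 0:
        logger.warning("constant input: length-bias correlation undefined")
        return np.nan, np.nan
    r, p = stats.pearsonr(u_stats, gene_lengths)
    return float(r), float(p)
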
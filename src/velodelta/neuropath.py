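"""Partial-Spearman association of subject-mean velocity with traits.

For each cell type, every subject's cells are averaged gene-wise to a
subjects x genes velocity matrix; each gene is then tested for association
with each neuropathology trait (neuritic plaques, NFT counts, beta-amyloid
load, PHF tau tangle density) by partial Spearman correlation — rank both
variables, residualize the ranks on an intercept plus covariates by least
squares, and correlate the residuals — with the p-value from the
t-distribution on n - 2 - k degrees of freedom.  Family-wise error within
each (cell type, trait) family is controlled by Holm step-down; genes with
adjusted p below alpha (default 0.001) are called significant.

The default covariate set is {age, sex, education, pmi}; the narrower
{age, sex, pmi} variant is available via the ``covariates`` argument.  Sex
enters the design as a binary indicator.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "subject_mean_velocity",
    "partial_spearman",
    "trait_association",
    "trait_overlap_summary",
]

DEFAULT_COVARIATES = ("age", "sex", "education", "pmi")


def subject_mean_velocity(V, cells: pd.DataFrame, subject_ids=None) -> dict:
    """Per cell type: subjects x genes NaN-aware mean velocity + cell counts.

    Returns {cell_type: (mean_df, count_df)} where rows are subjects (all of
    ``subject_ids`` if given, else the subjects present) and a subject
    lacking the cell type has a NaN row with count 0.
    """
    V = np.asarray(V, dtype=float)
    if V.shape[0] != len(cells):
        raise ValueError("V rows and annotation rows must align")
    if subject_ids is None:
        subject_ids = list(pd.unique(cells["subject_id"]))
    out = {}
    for ct in pd.unique(cells["cell_type"]):
        rows = np.flatnonzero((cells["cell_type"] == ct).to_numpy())
        sub = cells.iloc[rows]["subject_id"].to_numpy()
        means = pd.DataFrame(
            np.nan, index=subject_ids, columns=range(V.shape[1])
        )
        counts = pd.Series(0, index=subject_ids)
        for s in pd.unique(sub):
            sel = rows[sub == s]
            with np.errstate(invalid="ignore"):
                means.loc[s] = np.nanmean(V[sel], axis=0)
            counts.loc[s] = len(sel)
        out[ct] = (means, counts)
    return out


def _encode_covariates(df: pd.DataFrame) -> np.ndarray:
    cols = []
    for c in df.columns:
        col = df[c]
        if col.dtype == object or str(col.dtype) == "category":
            levels = pd.unique(col.dropna())
            if len(levels) > 2:
                raise ValueError(f"covariate {c!r} has >2 categorical levels")
            cols.append((col == levels[0]).astype(float).to_numpy())
        else:
            cols.append(col.astype(float).to_numpy())
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def partial_spearman(x, y, covariates=None):
    """Covariate-adjusted Spearman correlation.

    All variables — x, y and each covariate column — are rank-transformed
    (average ranks for ties); the ranks of x and y are residualized on an
    intercept plus the covariate ranks by least squares, and the Pearson
    correlation of the residuals is returned with its t-test p-value on
    n - 2 - k degrees of freedom.  Ranking the covariates makes a perfectly
    monotone confounder cancel exactly, which a linear adjustment on raw
    covariate values would not.  With no covariates this reduces to the
    ordinary Spearman correlation.  Rows with any missing value are dropped;
    fewer than k + 3 complete rows yields (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        C = np.empty((len(x), 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(C).any(axis=1))
    n, k = int(ok.sum()), C.shape[1]
    if n < k + 3:
        logger.warning("partial_spearman: %d complete cases < %d required", n, k + 3)
        return np.nan, np.nan
    rx = stats.rankdata(x[ok])
    ry = stats.rankdata(y[ok])
    rC = (
        np.column_stack([stats.rankdata(C[ok, j]) for j in range(k)])
        if k
        else C[ok]
    )
    design = np.column_stack([np.ones(n), rC])
    bx, *_ = np.linalg.lstsq(design, rx, rcond=None)
    by, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ bx
    ey = ry - design @ by
    sx2, sy2 = (ex**2).sum(), (ey**2).sum()
    # residual power below numerical noise on the rank scale means the
    # variable is fully explained by the covariates: no association left
    tol = 1e-10 * n**3
    if sx2 <= tol or sy2 <= tol:
        return 0.0, 1.0
    denom = np.sqrt(sx2 * sy2)
    rho = float((ex * ey).sum() / denom)
    df = n - 2 - k
    if df <= 0 or abs(rho) >= 1.0:
        return rho, 0.0 if abs(rho) >= 1.0 else np.nan
    t = rho * np.sqrt(df / (1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, p


def trait_association(
    sgm: dict,
    meta: pd.DataFrame,
    traits=("np", "nft", "amyloid", "tangles"),
    covariates=DEFAULT_COVARIATES,
    alpha: float = 0.001,
    subjects_subset=None,
    gene_ids=None,
) -> pd.DataFrame:
    """Holm-adjusted partial Spearman over all (cell type, trait, gene).

    ``sgm`` is the output of :func:`subject_mean_velocity`; ``meta`` a
    subject table carrying the traits and covariates.  Families are
    (cell type x trait); constant traits skip their family with a warning.
    ``subjects_subset`` restricts the test to e.g. the pathology group only.
    """
    meta = meta.set_index("subject_id") if "subject_id" in meta.columns else meta
    rows = []
    for ct, (means, _counts) in sgm.items():
        idx = means.index if subjects_subset is None else [
            s for s in means.index if s in set(subjects_subset)
        ]
        sub_meta = meta.loc[idx]
        C = _encode_covariates(sub_meta[list(covariates)])
        for trait in traits:
            tvals = sub_meta[trait].astype(float).to_numpy()
            finite = tvals[~np.isnan(tvals)]
            if finite.size == 0 or np.ptp(finite) == 0:
                logger.warning("trait %r constant/missing in %s: family skipped", trait, ct)
                continue
            fam = []
            for g in means.columns:
                rho, p = partial_spearman(
                    means.loc[idx, g].to_numpy(), tvals, C
                )
                fam.append((g, rho, p))
            fam_df = pd.DataFrame(fam, columns=["gene", "rho", "p"])
            ok = fam_df["p"].notna()
            fam_df["p_fwer"] = np.nan
            if ok.any():
                fam_df.loc[ok, "p_fwer"] = multipletests(
                    fam_df.loc[ok, "p"], method="holm"
                )[1]
            fam_df["cell_type"] = ct
            fam_df["trait"] = trait
            fam_df["significant"] = fam_df["p_fwer"] < alpha
            rows.append(fam_df)
    if not rows:
        return pd.DataFrame(
            columns=["gene", "rho", "p", "p_fwer", "cell_type", "trait", "significant"]
        )
    out = pd.concat(rows, ignore_index=True)
    if gene_ids is not None:
        out["gene"] = out["gene"].map(lambda i: gene_ids[i] if isinstance(i, int) else i)
    return out[["gene", "cell_type", "trait", "rho", "p", "p_fwer", "significant"]]


def trait_overlap_summary(assoc: pd.DataFrame) -> pd.DataFrame:
    """Pairwise overlap of significant gene sets across traits per cell type
    (Jaccard and overlap-over-smaller percentages)."""
    rows = []
    for ct, sub in assoc.groupby("cell_type"):
        sets = {
            t: set(s.loc[s["significant"], "gene"])
            for t, s in sub.groupby("trait")
        }
        for t1, t2 in combinations(sorted(sets), 2):
            a, b = sets[t1], sets[t2]
            inter = len(a & b)
            denom = min(len(a), len(b))
            rows.append(
                {
                    "cell_type": ct,
                    "trait_a": t1,
                    "trait_b": t2,
                    "n_a": len(a),
                    "n_b": len(b),
                    "n_overlap": inter,
                    "pct_of_smaller": 100.0 * inter / denom if denom else 0.0,
                }
            )
    return pd.DataFrame(rows)
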
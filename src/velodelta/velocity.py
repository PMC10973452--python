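"""Moment-based RNA velocity estimation on a kNN graph in PCA space.

Velocity of a gene in a cell is the residual of the (smoothed) unspliced
abundance from the steady-state line u = (gamma/beta) * s, with beta fixed to
1 so the fitted slope is the gamma/beta ratio:

    v[c, g] = Mu[c, g] - gamma_g * Ms[c, g]

Two slope estimators are provided.  The *steady-state* fit regresses Mu on Ms
through the origin over cells in the extreme quantiles of Ms (proxies for the
repressed and induced equilibria).  The *stochastic* fit augments this
first-moment relation with the second-moment equation of the counting
process,

    2 E[us] + E[u] = gamma * (2 E[s^2] - E[s]),

stacking both equations into one weighted least-squares problem on the same
extreme-quantile cells; each equation block is weighted by the inverse of its
response variance so neither dominates through scale alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "Moments",
    "GammaFit",
    "VelocityMatrix",
    "neighbor_moments",
    "fit_gamma",
    "compute_velocity",
    "rank_velocity_genes",
    "estimate_velocity",
]


@dataclass
class Moments:
    """kNN-neighborhood moments of normalized layers (cells x genes).

    Mu, Ms are neighbor means of U and S; Mss, Mus are neighbor means of
    S^2 and U*S (second moments, non-central).
    """

    Mu: np.ndarray
    Ms: np.ndarray
    Mss: np.ndarray
    Mus: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.Mu, self.Ms, self.Mss, self.Mus)}
        if len(shapes) != 1:
            raise ValueError(f"moment matrices have differing shapes: {shapes}")


@dataclass
class GammaFit:
    """Per-gene steady-state slope gamma/beta with validity flags."""

    gamma: np.ndarray
    r2: np.ndarray
    mode: str
    valid: np.ndarray
    reason: list

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class VelocityMatrix:
    """Cells x genes velocities; NaN columns mark invalid gene fits."""

    V: np.ndarray
    gene_ids: list
    barcodes: list

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.V, index=self.barcodes, columns=self.gene_ids)


def neighbor_moments(S_norm, U_norm, n_pcs: int = 30, k: int = 100) -> Moments:
    """Smooth layers by averaging over k nearest neighbors in PCA space.

    PCA is computed on log1p of the normalized spliced layer; neighbors are
    Euclidean in PC space and include the cell itself (stabilizing moments
    for boundary cells).  If fewer than ``k`` cells exist, k is reduced to
    n_cells - 1 with a warning.
    """
    S_norm = np.asarray(S_norm, dtype=float)
    U_norm = np.asarray(U_norm, dtype=float)
    n_cells, n_genes = S_norm.shape
    if n_cells < 2:
        raise ValueError("need at least 2 cells for neighbor moments")
    if k >= n_cells:
        logger.warning("k=%d >= n_cells=%d; reducing k to %d", k, n_cells, n_cells - 1)
        k = n_cells - 1
    n_pcs = min(n_pcs, n_cells - 1, n_genes)

    X = np.log1p(S_norm)
    pcs = PCA(n_components=n_pcs, svd_solver="auto", random_state=0).fit_transform(X)
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    # querying the training set returns each cell as its own nearest neighbor
    _, idx = nn.kneighbors(pcs)

    def avg(M):
        return M[idx].mean(axis=1)

    return Moments(
        Mu=avg(U_norm), Ms=avg(S_norm), Mss=avg(S_norm**2), Mus=avg(U_norm * S_norm)
    )


def _extreme_mask(ms_col: np.ndarray, q_lo: float, q_hi: float) -> np.ndarray:
    lo, hi = np.quantile(ms_col, [q_lo, q_hi])
    return (ms_col <= lo) | (ms_col >= hi)


def fit_gamma(
    moments: Moments,
    mode: str = "stochastic",
    quantile_pair: tuple = (0.05, 0.95),
) -> GammaFit:
    """Fit the per-gene steady-state slope on extreme-quantile cells.

    Genes with an all-zero smoothed spliced signal, or a non-positive fitted
    slope, are flagged invalid with the reason recorded (never silently
    zeroed).
    """
    if mode not in ("steady_state", "stochastic"):
        raise ValueError(f"unknown fit mode {mode!r}")
    q_lo, q_hi = quantile_pair
    if not (0.0 < q_lo < q_hi < 1.0):
        raise ValueError(f"need 0 < q_lo < q_hi < 1, got {quantile_pair}")

    n_genes = moments.Ms.shape[1]
    gamma = np.full(n_genes, np.nan)
    r2 = np.full(n_genes, np.nan)
    valid = np.zeros(n_genes, dtype=bool)
    reason = [""] * n_genes

    for g in range(n_genes):
        ms, mu = moments.Ms[:, g], moments.Mu[:, g]
        if not np.any(ms > 0):
            reason[g] = "all-zero spliced moments"
            continue
        sel = _extreme_mask(ms, q_lo, q_hi)
        x1, y1 = ms[sel], mu[sel]
        if mode == "steady_state":
            x, y, w = x1, y1, np.ones_like(x1)
        else:
            x2 = 2.0 * moments.Mss[sel, g] - ms[sel]
            y2 = 2.0 * moments.Mus[sel, g] + mu[sel]
            w1 = 1.0 / max(np.var(y1), 1e-12)
            w2 = 1.0 / max(np.var(y2), 1e-12)
            x = np.concatenate([x1, x2])
            y = np.concatenate([y1, y2])
            w = np.concatenate([np.full(x1.shape, w1), np.full(x2.shape, w2)])
        denom = np.sum(w * x * x)
        if denom <= 0:
            reason[g] = "degenerate regressors"
            continue
        slope = np.sum(w * x * y) / denom
        if not np.isfinite(slope) or slope <= 0:
            reason[g] = f"non-positive slope {slope:.3g}"
            continue
        gamma[g] = slope
        ss_res = np.sum(w * (y - slope * x) ** 2)
        ss_tot = np.sum(w * y**2)
        r2[g] = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        valid[g] = True
    return GammaFit(gamma=gamma, r2=r2, mode=mode, valid=valid, reason=reason)


def compute_velocity(
    moments: Moments, fit: GammaFit, gene_ids=None, barcodes=None
) -> VelocityMatrix:
    """Velocity as the residual from the steady-state line, NaN if invalid."""
    if moments.Ms.shape[1] != fit.gamma.shape[0]:
        raise ValueError(
            f"moments have {moments.Ms.shape[1]} genes, fit has {fit.gamma.shape[0]}"
        )
    V = moments.Mu - fit.gamma[None, :] * moments.Ms
    V[:, ~fit.valid] = np.nan
    n_cells, n_genes = V.shape
    return VelocityMatrix(
        V=V,
        gene_ids=list(gene_ids) if gene_ids is not None else list(range(n_genes)),
        barcodes=list(barcodes) if barcodes is not None else list(range(n_cells)),
    )


def rank_velocity_genes(vm: VelocityMatrix, cell_types) -> dict:
    """Rank genes driving cell-type-specific dynamics by Welch's t.

    For every cell type, each gene's velocities in-type are tested against
    all remaining cells (Welch's unequal-variance t); genes are returned
    ranked by t descending.  Zero-variance genes get a small variance floor
    in the denominator rather than an undefined statistic.
    """
    cell_types = np.asarray(cell_types)
    uniq = pd.unique(cell_types)
    if len(uniq) < 2:
        raise ValueError("need at least two cell types to rank against the rest")
    out = {}
    V = vm.V
    for ct in uniq:
        a = V[cell_types == ct]
        b = V[cell_types != ct]
        if a.shape[0] < 2 or b.shape[0] < 2:
            raise ValueError(f"cell type {ct!r} needs >= 2 cells on each side")
        with np.errstate(invalid="ignore"):
            ma, mb = np.nanmean(a, axis=0), np.nanmean(b, axis=0)
            va, vb = np.nanvar(a, axis=0, ddof=1), np.nanvar(b, axis=0, ddof=1)
        na = np.sum(~np.isnan(a), axis=0)
        nb = np.sum(~np.isnan(b), axis=0)
        floor = 1e-12
        se2 = np.maximum(va, floor) / np.maximum(na, 1) + np.maximum(vb, floor) / np.maximum(nb, 1)
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (
            (np.maximum(va, floor) / np.maximum(na, 1)) ** 2 / np.maximum(na - 1, 1)
            + (np.maximum(vb, floor) / np.maximum(nb, 1)) ** 2 / np.maximum(nb - 1, 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t), df)
        tab = pd.DataFrame(
            {"gene": vm.gene_ids, "t": t, "p": p, "mean_in": ma, "mean_rest": mb}
        ).sort_values("t", ascending=False, kind="mergesort")
        out[ct] = tab.reset_index(drop=True)
    return out


def estimate_velocity(
    S_norm,
    U_norm,
    mode: str = "stochastic",
    n_pcs: int = 30,
    k: int = 100,
    quantile_pair: tuple = (0.05, 0.95),
    gene_ids=None,
    barcodes=None,
    pooling: str = "pooled",
    subjects=None,
):
    """Moments -> gamma fit -> velocity in one call.

    ``pooling="pooled"`` (default) estimates on all cells together;
    ``pooling="per_subject"`` repeats moments/fit/velocity independently
    within each subject (requires ``subjects``, one label per cell) and
    reassembles the velocity matrix in the original cell order.

    Returns (VelocityMatrix, GammaFit, Moments); for per-subject pooling the
    fit and moments are those of the last subject processed and the velocity
    matrix is the assembled one.
    """
    if pooling == "pooled":
        moments = neighbor_moments(S_norm, U_norm, n_pcs=n_pcs, k=k)
        fit = fit_gamma(moments, mode=mode, quantile_pair=quantile_pair)
        vm = compute_velocity(moments, fit, gene_ids=gene_ids, barcodes=barcodes)
        return vm, fit, moments
    if pooling != "per_subject":
        raise ValueError(f"unknown pooling {pooling!r}")
    if subjects is None:
        raise ValueError("per_subject pooling requires per-cell subject labels")
    subjects = np.asarray(subjects)
    S_norm = np.asarray(S_norm, dtype=float)
    U_norm = np.asarray(U_norm, dtype=float)
    V = np.full(S_norm.shape, np.nan)
    fit = moments = None
    for subj in pd.unique(subjects):
        rows = np.flatnonzero(subjects == subj)
        moments = neighbor_moments(
            S_norm[rows], U_norm[rows], n_pcs=n_pcs, k=min(k, len(rows) - 1)
        )
        fit = fit_gamma(moments, mode=mode, quantile_pair=quantile_pair)
        sub_vm = compute_velocity(moments, fit)
        V[rows] = sub_vm.V
    vm = VelocityMatrix(
        V=V,
        gene_ids=list(gene_ids) if gene_ids is not None else list(range(V.shape[1])),
        barcodes=list(barcodes) if barcodes is not None else list(range(V.shape[0])),
    )
    return vm, fit, moments
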
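"""Whole-transcriptome group comparison: cell speed and residual fields.

*Cell speed* is the Euclidean norm of a cell's velocity vector across (valid)
genes — a scalar rate-of-change summary compared between groups with the
rank-sum test.

*Velocity fields* project each cell's high-dimensional velocity onto a 2D
embedding: the velocity is compared (cosine similarity) with the gene-space
displacement toward each embedding neighbor, similarities are softmax-
weighted into transition probabilities, and the 2D vector is the probability-
weighted mean of unit displacements minus the uniform-neighbor baseline.  The
group fields are then kernel-smoothed onto one shared lattice, subtracted,
and lattice points whose residual norm is an outlier (|z| beyond a threshold,
default 1.96) form the residual-field mask.  Only the mask and z magnitudes
carry interpretation; residual directions do not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.interpolate import griddata
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddedVelocity",
    "FieldGrid",
    "cell_speed",
    "compare_speed",
    "embed_velocity",
    "residual_field",
    "pca_embedding",
]


@dataclass
class EmbeddedVelocity:
    """Cells x 2 embedding coordinates and projected velocity vectors."""

    coords: np.ndarray
    vec2d: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.vec2d = np.asarray(self.vec2d, dtype=float)
        if self.coords.shape != self.vec2d.shape or self.coords.shape[1] != 2:
            raise ValueError("coords and vec2d must both be n_cells x 2")


@dataclass
class FieldGrid:
    """Smoothed group fields on a shared lattice with residual z-scores."""

    grid_coords: np.ndarray
    field_a: np.ndarray
    field_b: np.ndarray
    residual: np.ndarray
    z: np.ndarray
    mask: np.ndarray
    shape: tuple


def cell_speed(V) -> np.ndarray:
    """Euclidean norm of each cell's velocity across valid (non-NaN) genes."""
    V = np.asarray(V, dtype=float)
    valid = ~np.isnan(V)
    speeds = np.sqrt(np.nansum(V**2, axis=1))
    none_valid = ~valid.any(axis=1)
    if none_valid.any():
        logger.warning("%d cell(s) have no valid genes; speed = NaN", none_valid.sum())
        speeds[none_valid] = np.nan
    return speeds


def compare_speed(speeds, groups, group_a, group_b):
    """Group medians and the two-sided rank-sum p-value over cells."""
    speeds = np.asarray(speeds, dtype=float)
    groups = np.asarray(groups)
    a = speeds[(groups == group_a) & ~np.isnan(speeds)]
    b = speeds[(groups == group_b) & ~np.isnan(speeds)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 cells with defined speed")
    p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return float(np.median(a)), float(np.median(b)), float(p)


def pca_embedding(expression, random_state: int = 0) -> np.ndarray:
    """First two principal components as a deterministic 2D fallback
    embedding (external t-SNE/UMAP coordinates are accepted verbatim)."""
    from sklearn.decomposition import PCA

    X = np.asarray(expression, dtype=float)
    return PCA(n_components=2, random_state=random_state).fit_transform(X)


def embed_velocity(
    V,
    expression,
    coords,
    n_neighbors: int = 30,
    sigma: float | None = None,
) -> EmbeddedVelocity:
    """Project gene-space velocities onto 2D embedding coordinates.

    For cell i with embedding neighbors j: cosine similarity c_ij between
    v_i and the expression displacement (x_j - x_i); transition weights
    w_ij = softmax(c_ij / sigma_i) with adaptive temperature sigma_i =
    median |c_ij| per cell unless ``sigma`` is given; then

        vec2d_i = sum_j w_ij * e_ij  -  mean_j e_ij

    with e_ij the unit embedding displacement.  The subtracted uniform
    baseline makes a zero (or all-NaN) velocity map to a zero vector.
    """
    V = np.asarray(V, dtype=float)
    X = np.asarray(expression, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n_cells = V.shape[0]
    if not (X.shape[0] == n_cells == coords.shape[0]):
        raise ValueError("V, expression and coords must share the cell axis")
    k = min(n_neighbors, n_cells - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    idx = idx[:, 1:]  # drop self

    Vz = np.nan_to_num(V, nan=0.0)
    vec2d = np.zeros((n_cells, 2))
    for i in range(n_cells):
        nbrs = idx[i]
        if nbrs.size == 0:
            logger.warning("cell %d is isolated; zero 2D vector", i)
            continue
        disp = X[nbrs] - X[i]
        dnorm = np.linalg.norm(disp, axis=1)
        vnorm = np.linalg.norm(Vz[i])
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = disp @ Vz[i] / (dnorm * vnorm)
        cos = np.nan_to_num(cos, nan=0.0)
        if vnorm == 0:
            w = np.full(nbrs.size, 1.0 / nbrs.size)
        else:
            s = sigma if sigma is not None else max(np.median(np.abs(cos)), 1e-3)
            e = np.exp((cos - cos.max()) / s)
            w = e / e.sum()
        emb_disp = coords[nbrs] - coords[i]
        emb_norm = np.linalg.norm(emb_disp, axis=1)
        emb_norm[emb_norm == 0] = 1.0
        unit = emb_disp / emb_norm[:, None]
        vec2d[i] = w @ unit - unit.mean(axis=0)
    return EmbeddedVelocity(coords=coords, vec2d=vec2d)


def _smooth_on_grid(coords, vec2d, gx, gy, bandwidth):
    """Gaussian-kernel average of vectors at lattice points; NaN where the
    total kernel weight is negligible (no local support)."""
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    d2 = (
        (pts[:, None, 0] - coords[None, :, 0]) ** 2
        + (pts[:, None, 1] - coords[None, :, 1]) ** 2
    )
    w = np.exp(-d2 / (2.0 * bandwidth**2))
    tot = w.sum(axis=1)
    field = np.full((pts.shape[0], 2), np.nan)
    # support threshold: roughly one cell within ~2 bandwidths
    ok = tot > np.exp(-2.0)
    field[ok] = (w[ok] @ vec2d) / tot[ok, None]
    return field, ok


def _fill_missing(pts, field, ok):
    if ok.all():
        return field
    filled = field.copy()
    for d in range(2):
        vals = griddata(pts[ok], field[ok, d], pts[~ok], method="linear")
        nan = np.isnan(vals)
        if nan.any():
            vals[nan] = griddata(
                pts[ok], field[ok, d], pts[~ok][nan], method="nearest"
            )
        filled[~ok, d] = vals
    return filled


def residual_field(
    emb_a: EmbeddedVelocity,
    emb_b: EmbeddedVelocity,
    grid_size: int = 50,
    bandwidth: float | None = None,
    z_thresh: float = 1.96,
) -> FieldGrid:
    """Difference of two groups' smoothed fields on a shared lattice.

    Both groups must live in one embedding coordinate system.  Each group's
    vectors are Gaussian-smoothed onto a ``grid_size`` x ``grid_size``
    lattice spanning the union bounding box (bandwidth defaults to the
    lattice spacing); lattice points covered by only one group are filled by
    linear interpolation of that group's own field, so the subtraction is
    defined at identical coordinates everywhere.  z-scores standardize the
    residual *norms* over the lattice; the mask is |z| > ``z_thresh``.
    """
    all_xy = np.vstack([emb_a.coords, emb_b.coords])
    lo, hi = all_xy.min(axis=0), all_xy.max(axis=0)
    span = hi - lo
    if np.any(span <= 0):
        raise ValueError("degenerate embedding support (zero extent)")
    # restrict to the overlap of the two groups' bounding boxes
    lo_ov = np.maximum(emb_a.coords.min(axis=0), emb_b.coords.min(axis=0))
    hi_ov = np.minimum(emb_a.coords.max(axis=0), emb_b.coords.max(axis=0))
    if np.any(hi_ov <= lo_ov):
        raise ValueError("embedding supports of the two groups do not overlap")

    xs = np.linspace(lo[0], hi[0], grid_size)
    ys = np.linspace(lo[1], hi[1], grid_size)
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    if bandwidth is None:
        bandwidth = max(span[0], span[1]) / (grid_size - 1)

    fa, ok_a = _smooth_on_grid(emb_a.coords, emb_a.vec2d, gx, gy, bandwidth)
    fb, ok_b = _smooth_on_grid(emb_b.coords, emb_b.vec2d, gx, gy, bandwidth)
    fa = _fill_missing(pts, fa, ok_a)
    fb = _fill_missing(pts, fb, ok_b)

    residual = fa - fb
    norms = np.linalg.norm(residual, axis=1)
    sd = norms.std()
    if sd == 0:
        z = np.zeros_like(norms)
    else:
        z = (norms - norms.mean()) / sd
    return FieldGrid(
        grid_coords=pts,
        field_a=fa,
        field_b=fb,
        residual=residual,
        z=z,
        mask=np.abs(z) > z_thresh,
        shape=(grid_size, grid_size),
    )
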
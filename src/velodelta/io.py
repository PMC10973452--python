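"""Reading, harmonizing and normalizing spliced/unspliced count layers.

On-disk layout (produced by :func:`velodelta.simulate.write_dataset`, and the
format the pipeline ingests):

* ``spliced.mtx`` / ``unspliced.mtx`` — Matrix-Market coordinate matrices,
  cells x genes, 1-based indices on disk, 0-based in memory.
* ``barcodes.tsv`` — one cell barcode per line.
* ``features.tsv`` — ``gene_id<TAB>symbol<TAB>length`` (length in bases,
  optional column).
* ``cells.tsv`` — per-cell annotation (barcode, subject_id, cell_type, group).
* ``subjects.tsv`` — per-subject covariates, group and neuropathology traits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "CountLayers",
    "FormatError",
    "read_matrices",
    "read_cell_annotation",
    "read_subject_meta",
    "harmonize",
    "normalize",
]

#: per-subject neuropathology trait columns expected in subjects.tsv
TRAIT_COLUMNS = ("np", "nft", "amyloid", "tangles")
#: per-subject covariate columns
COVARIATE_COLUMNS = ("age", "sex", "education", "pmi")


class FormatError(ValueError):
    """Raised for malformed or mutually inconsistent input files."""


@dataclass
class CountLayers:
    """Paired spliced (S) and unspliced (U) cells x genes matrices.

    Both layers share shape, barcode order and feature order.  ``features``
    is a DataFrame with at least ``gene_id`` and ``symbol`` columns and an
    optional ``length`` column (gene length in bases).
    """

    S: np.ndarray
    U: np.ndarray
    barcodes: list[str] = field(default_factory=list)
    features: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.S = _to_dense(self.S)
        self.U = _to_dense(self.U)
        if self.S.shape != self.U.shape:
            raise FormatError(
                f"spliced {self.S.shape} and unspliced {self.U.shape} shapes differ"
            )
        if not self.barcodes:
            self.barcodes = [f"cell{i}" for i in range(self.S.shape[0])]
        if self.features.empty:
            self.features = pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(self.S.shape[1])],
                    "symbol": [f"g{i}" for i in range(self.S.shape[1])],
                }
            )
        if len(self.barcodes) != self.S.shape[0]:
            raise FormatError(
                f"{len(self.barcodes)} barcodes for {self.S.shape[0]} matrix rows"
            )
        if len(self.features) != self.S.shape[1]:
            raise FormatError(
                f"{len(self.features)} features for {self.S.shape[1]} matrix columns"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("duplicate barcodes")

    @property
    def n_cells(self) -> int:
        return self.S.shape[0]

    @property
    def n_genes(self) -> int:
        return self.S.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.features["gene_id"])

    def subset(self, cell_idx=None, gene_idx=None) -> "CountLayers":
        ci = np.arange(self.n_cells) if cell_idx is None else np.asarray(cell_idx)
        gi = np.arange(self.n_genes) if gene_idx is None else np.asarray(gene_idx)
        return CountLayers(
            S=self.S[np.ix_(ci, gi)],
            U=self.U[np.ix_(ci, gi)],
            barcodes=[self.barcodes[i] for i in ci],
            features=self.features.iloc[gi].reset_index(drop=True),
        )


def _to_dense(m) -> np.ndarray:
    if sp.issparse(m):
        return np.asarray(m.todense())
    return np.asarray(m)


def _read_lines(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_matrices(directory) -> CountLayers:
    """Load paired MTX layers plus barcode/feature lists from ``directory``.

    Raises :class:`FormatError` naming the offending file on shape
    mismatches, duplicate barcodes, or malformed MTX content.
    """
    directory = Path(directory)
    layers = {}
    for name in ("spliced", "unspliced"):
        path = directory / f"{name}.mtx"
        try:
            layers[name] = _to_dense(scipy.io.mmread(path))
        except (ValueError, OSError) as exc:
            raise FormatError(f"cannot read {path}: {exc}") from exc
    barcodes = _read_lines(directory / "barcodes.tsv")
    feat_path = directory / "features.tsv"
    features = pd.read_csv(feat_path, sep="\t", header=None, dtype={0: str, 1: str})
    features.columns = ["gene_id", "symbol", "length"][: features.shape[1]]
    if "symbol" not in features.columns:
        features["symbol"] = features["gene_id"]

    S, U = layers["spliced"], layers["unspliced"]
    if S.shape != U.shape:
        raise FormatError(
            f"{directory}/spliced.mtx {S.shape} vs unspliced.mtx {U.shape}"
        )
    if S.shape[0] != len(barcodes):
        raise FormatError(
            f"{directory}/barcodes.tsv has {len(barcodes)} entries, "
            f"matrices have {S.shape[0]} rows"
        )
    if S.shape[1] != len(features):
        raise FormatError(
            f"{feat_path} has {len(features)} entries, matrices have "
            f"{S.shape[1]} columns"
        )
    if len(set(barcodes)) != len(barcodes):
        raise FormatError(f"duplicate barcodes in {directory}/barcodes.tsv")
    return CountLayers(S=S, U=U, barcodes=barcodes, features=features)


def read_cell_annotation(path) -> pd.DataFrame:
    """Per-cell table with columns barcode, subject_id, cell_type, group."""
    cells = pd.read_csv(path, sep="\t", dtype=str)
    required = {"barcode", "subject_id", "cell_type", "group"}
    missing = required - set(cells.columns)
    if missing:
        raise FormatError(f"{path} missing columns {sorted(missing)}")
    if cells["barcode"].duplicated().any():
        raise FormatError(f"duplicate barcodes in {path}")
    per_subject = cells.groupby("subject_id")["group"].nunique()
    if (per_subject > 1).any():
        bad = per_subject[per_subject > 1].index.tolist()
        raise FormatError(f"{path}: group varies within subject(s) {bad}")
    return cells


def read_subject_meta(path) -> pd.DataFrame:
    """Per-subject covariates, group label and neuropathology traits."""
    meta = pd.read_csv(path, sep="\t")
    if "subject_id" not in meta.columns or "group" not in meta.columns:
        raise FormatError(f"{path} must have subject_id and group columns")
    if meta["subject_id"].duplicated().any():
        raise FormatError(f"duplicate subject_id in {path}")
    meta["subject_id"] = meta["subject_id"].astype(str)
    return meta


def harmonize(
    counts: CountLayers,
    cells: pd.DataFrame,
    keep_genes=None,
    exclude_cell_types=(),
):
    """Restrict layers and annotation to shared barcodes and a gene list.

    Mirrors the ingest step of matching filtered counts against a previously
    reported cell/gene list: the result keeps the barcode intersection (in
    count-matrix order), the requested genes in ``keep_genes`` order, and
    drops any annotated cell type in ``exclude_cell_types`` (e.g. endothelial
    cells and pericytes, which are excluded for their very low counts).

    Idempotent: harmonizing an already-harmonized pair is the identity.
    """
    cells = cells.copy()
    if exclude_cell_types:
        cells = cells[~cells["cell_type"].isin(set(exclude_cell_types))]
    annotated = set(cells["barcode"])
    cell_idx = [i for i, b in enumerate(counts.barcodes) if b in annotated]
    if not cell_idx:
        raise FormatError("no barcodes shared between counts and annotation")

    if keep_genes is None:
        gene_idx = None
    else:
        pos = {g: i for i, g in enumerate(counts.gene_ids)}
        gene_idx = [pos[g] for g in keep_genes if g in pos]
        if not gene_idx:
            raise FormatError("no genes shared between counts and keep_genes")
    out = counts.subset(cell_idx, gene_idx)
    order = {b: i for i, b in enumerate(out.barcodes)}
    cells = cells[cells["barcode"].isin(order)].copy()
    cells = cells.sort_values("barcode", key=lambda s: s.map(order))
    return out, cells.reset_index(drop=True)


def normalize(counts: CountLayers, mode: str = "velocity_layers"):
    """Size-factor normalization of the count layers.

    ``velocity_layers``
        Each cell's S row and U row are divided by that cell's own layer
        total and rescaled by the median of the layer totals, so both layers
        end up with constant per-cell totals on the original count scale.
        Cells with a zero total in either layer are dropped with a warning.
        Returns a new :class:`CountLayers` with float entries.

    ``expression``
        Library-size normalization of S only: divide by the per-cell total,
        multiply by 10,000 and apply log(1 + x).  Returns (matrix, barcodes).
    """
    if mode not in ("velocity_layers", "expression"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    S = counts.S.astype(float)
    U = counts.U.astype(float)
    s_tot = S.sum(axis=1)
    u_tot = U.sum(axis=1)

    if mode == "expression":
        keep = s_tot > 0
        if not keep.all():
            _warn_dropped(counts, keep, "spliced")
        X = S[keep] / s_tot[keep][:, None] * 1e4
        return np.log1p(X), [b for b, k in zip(counts.barcodes, keep) if k]

    keep = (s_tot > 0) & (u_tot > 0)
    if not keep.all():
        _warn_dropped(counts, keep, "spliced or unspliced")
    S, U = S[keep], U[keep]
    s_tot, u_tot = s_tot[keep], u_tot[keep]
    S = S / s_tot[:, None] * np.median(s_tot)
    U = U / u_tot[:, None] * np.median(u_tot)
    return CountLayers(
        S=S,
        U=U,
        barcodes=[b for b, k in zip(counts.barcodes, keep) if k],
        features=counts.features.copy(),
    )


def _warn_dropped(counts: CountLayers, keep: np.ndarray, which: str) -> None:
    dropped = [b for b, k in zip(counts.barcodes, keep) if not k]
    msg = f"dropped {len(dropped)} cell(s) with zero {which} total: {dropped[:5]}"
    logger.warning(msg)
    warnings.warn(msg, stacklevel=3)
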
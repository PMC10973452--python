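"""End-to-end orchestration: simulate/ingest -> preprocess -> velocity ->
differential -> fields/speed -> trait association (-> overlap), with a
manifest recording parameters, seeds and per-output checksums so a rerun
with an identical config is verifiably identical."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import differential_table, length_bias_check
from .fields import (
    cell_speed,
    compare_speed,
    embed_velocity,
    pca_embedding,
    residual_field,
)
from .io import harmonize, normalize, read_cell_annotation, read_matrices, read_subject_meta
from .neuropath import subject_mean_velocity, trait_association
from .simulate import SimConfig, generate_cohort, write_dataset
from .velocity import estimate_velocity, rank_velocity_genes

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Parameters of one pipeline run.

    ``input_dir`` of None simulates a cohort (with ``sim`` overrides) instead
    of ingesting files; ``embedding_path`` of None falls back to the 2D PCA
    embedding.  ``stratify_by`` (e.g. "sex") repeats the differential stage
    within each stratum.
    """

    out_dir: str = "velodelta_run"
    input_dir: str | None = None
    embedding_path: str | None = None
    sim: dict = field(default_factory=dict)
    exclude_cell_types: tuple = ()
    mode: str = "stochastic"
    k: int = 100
    n_pcs: int = 30
    n_perm: int = 1000
    q_thresh: float = 0.05
    fc_thresh: float = 0.25
    covariates: tuple = ("age", "sex", "education", "pmi")
    traits: tuple = ("np", "nft", "amyloid", "tangles")
    assoc_alpha: float = 0.001
    grid_size: int = 50
    z_thresh: float = 1.96
    stratify_by: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_perm < 1 or self.k < 1 or self.n_pcs < 1:
            raise ValueError("n_perm, k and n_pcs must be >= 1")
        if self.mode not in ("steady_state", "stochastic"):
            raise ValueError(f"unknown velocity mode {self.mode!r}")
        for p in (self.input_dir, self.embedding_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the run directory containing stage outputs
    and ``manifest.json``.  Any stage failure aborts with the stage named;
    outputs of completed stages are retained."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "velodelta_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "stages": {},
        "outputs": {},
    }
    stage = "init"
    try:
        # --- stage 1: simulate or ingest -------------------------------
        stage = "ingest"
        t0 = time.time()
        if config.input_dir is None:
            sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
            ds = generate_cohort(sim_cfg)
            write_dataset(ds, out / "dataset")
            counts, cells, subjects = ds.counts, ds.cells, ds.subjects
        else:
            src = Path(config.input_dir)
            counts = read_matrices(src)
            cells = read_cell_annotation(src / "cells.tsv")
            subjects = read_subject_meta(src / "subjects.tsv")
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}

        # --- stage 2: preprocess --------------------------------------
        stage = "preprocess"
        t0 = time.time()
        counts, cells = harmonize(
            counts, cells, exclude_cell_types=config.exclude_cell_types
        )
        norm = normalize(counts, mode="velocity_layers")
        expr, expr_barcodes = normalize(counts, mode="expression")
        keep = set(norm.barcodes) & set(expr_barcodes)
        if len(keep) < len(norm.barcodes) or len(keep) < len(expr_barcodes):
            norm_idx = [i for i, b in enumerate(norm.barcodes) if b in keep]
            norm = norm.subset(cell_idx=norm_idx)
            expr = expr[[b in keep for b in expr_barcodes]]
        cells = cells[cells["barcode"].isin(norm.barcodes)].reset_index(drop=True)
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "n_cells": norm.n_cells,
            "n_genes": norm.n_genes,
        }

        # --- stage 3: velocity ----------------------------------------
        stage = "velocity"
        t0 = time.time()
        vm, fit, _ = estimate_velocity(
            norm.S, norm.U, mode=config.mode, n_pcs=config.n_pcs, k=config.k,
            gene_ids=norm.gene_ids, barcodes=norm.barcodes,
        )
        vm.frame().to_csv(
            out / "velocity.tsv.gz", sep="\t",
            compression={"method": "gzip", "mtime": 0},  # checksum-stable
        )
        pd.DataFrame(
            {"gene": norm.gene_ids, "gamma": fit.gamma, "r2": fit.r2,
             "valid": fit.valid, "reason": fit.reason}
        ).to_csv(out / "gamma_fit.tsv", sep="\t", index=False)
        ranks = rank_velocity_genes(vm, cells["cell_type"].to_numpy())
        pd.concat(
            [t.assign(cell_type=ct) for ct, t in ranks.items()], ignore_index=True
        ).to_csv(out / "velocity_gene_ranks.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "mode": config.mode,
            "n_valid_genes": fit.n_valid,
        }

        # --- stage 4: differential (velocity and expression) ----------
        stage = "differential"
        t0 = time.time()
        groups = list(pd.unique(subjects["group"]))
        ga, gb = groups[1], groups[0]  # case vs control orientation
        strata = (
            {"all": np.ones(len(cells), dtype=bool)}
            if config.stratify_by is None
            else _strata_masks(cells, subjects, config.stratify_by)
        )
        diff_frames = []
        for stratum, smask in strata.items():
            for metric, mat in (("velocity", vm.V), ("expression", expr)):
                for ct in pd.unique(cells["cell_type"]):
                    m = smask & (cells["cell_type"] == ct).to_numpy()
                    if m.sum() < 4:
                        continue
                    try:
                        tab = differential_table(
                            mat[m],
                            cells.loc[m, "group"].to_numpy(),
                            cells.loc[m, "subject_id"].to_numpy(),
                            norm.gene_ids, ga, gb,
                            metric=metric, cell_type=ct,
                            n_perm=config.n_perm, seed=config.seed,
                        )
                    except ValueError as exc:
                        logger.warning("skipping %s/%s/%s: %s", stratum, metric, ct, exc)
                        continue
                    tab["stratum"] = stratum
                    diff_frames.append(tab)
        diff = pd.concat(diff_frames, ignore_index=True)
        diff.to_csv(out / "differential.tsv", sep="\t", index=False)
        for (metric, ct), sub in diff[diff["significant"]].groupby(
            ["metric", "cell_type"]
        ):
            path = out / f"significant_{metric}_{ct}.txt"
            path.write_text("\n".join(sub["gene"].astype(str)) + "\n")
        if "length" in norm.features.columns:
            vel_diff = diff[(diff["metric"] == "velocity") & (diff["stratum"] == strata_first(strata))]
            by_gene = vel_diff.groupby("gene")["u_stat"].mean()
            lengths = norm.features.set_index("gene_id")["length"]
            common = by_gene.index.intersection(lengths.index)
            r, p = length_bias_check(
                by_gene.loc[common].to_numpy(), lengths.loc[common].to_numpy()
            )
            manifest["stages"]["length_bias"] = {"r": r, "p": p}
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "n_significant_velocity": int(
                diff.query("metric == 'velocity'")["significant"].sum()
            ),
            "n_significant_expression": int(
                diff.query("metric == 'expression'")["significant"].sum()
            ),
        }

        # --- stage 5: speed and residual fields -----------------------
        stage = "fields"
        t0 = time.time()
        speeds = cell_speed(vm.V)
        speed_rows = []
        for ct in pd.unique(cells["cell_type"]):
            m = (cells["cell_type"] == ct).to_numpy()
            try:
                med_a, med_b, p = compare_speed(
                    speeds[m], cells.loc[m, "group"].to_numpy(), ga, gb
                )
            except ValueError:
                continue
            speed_rows.append(
                {"cell_type": ct, f"median_{ga}": med_a, f"median_{gb}": med_b, "p": p}
            )
        pd.DataFrame(speed_rows).to_csv(out / "cell_speed.tsv", sep="\t", index=False)

        if config.embedding_path is not None:
            coords = pd.read_csv(config.embedding_path, sep="\t").iloc[:, -2:].to_numpy()
        else:
            coords = pca_embedding(np.log1p(norm.S))
        in_a = (cells["group"] == ga).to_numpy()
        emb_a = embed_velocity(vm.V[in_a], np.log1p(norm.S[in_a]), coords[in_a])
        emb_b = embed_velocity(vm.V[~in_a], np.log1p(norm.S[~in_a]), coords[~in_a])
        grid = residual_field(
            emb_a, emb_b, grid_size=config.grid_size, z_thresh=config.z_thresh
        )
        np.savetxt(
            out / "residual_field.tsv",
            np.column_stack([grid.grid_coords, grid.residual, grid.z, grid.mask]),
            header="x\ty\tres_x\tres_y\tz\tmasked", delimiter="\t", comments="",
        )
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "masked_fraction": float(grid.mask.mean()),
        }

        # --- stage 6: trait association -------------------------------
        stage = "association"
        t0 = time.time()
        sgm = subject_mean_velocity(
            vm.V, cells, subject_ids=list(subjects["subject_id"])
        )
        assoc = trait_association(
            sgm, subjects, traits=config.traits,
            covariates=config.covariates, alpha=config.assoc_alpha,
            gene_ids=norm.gene_ids,
        )
        assoc.to_csv(out / "trait_association.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "n_significant": int(assoc["significant"].sum()),
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][str(f.relative_to(out))] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def strata_first(strata: dict) -> str:
    return next(iter(strata))


def _strata_masks(cells: pd.DataFrame, subjects: pd.DataFrame, column: str) -> dict:
    values = cells["subject_id"].map(
        subjects.set_index("subject_id")[column]
    )
    return {
        str(level): (values == level).to_numpy()
        for level in pd.unique(values.dropna())
    }
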
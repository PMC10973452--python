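"""Synthetic multi-subject spliced/unspliced cohorts with known kinetics.

The generator places cells along induction/repression trajectories of the
transcription--splicing--degradation model (see :mod:`velodelta.kinetics`),
applies group effects to designated genes, couples neuropathology-like traits
to subject-mean velocities, and samples counting noise — so every downstream
stage (velocity estimation, differential testing, trait association) can be
validated against ground truth.

Gene classes
------------
``dynamic``
    Kinetics differ between groups: the degradation rate gamma is multiplied
    by ``group_effect_gamma`` in the affected (second) group.  Expression
    levels stay comparable, velocities differ.
``de``
    Transcription rate alpha is multiplied by ``group_effect_alpha`` in the
    affected group: an expression difference, the classical DE signal.
``null``
    Identical kinetics in both groups.

Each cell carries one latent-time fraction q in [0, 1); gene g sees the cell
at phase ((q + phi_g) mod 1) of its own induction/repression cycle, where
phi_g is a fixed per-gene phase offset.  Desynchronizing genes this way
matches real tissue — transcriptional programs are not globally in phase —
and keeps per-cell totals stable, so library-size normalization behaves as
it does on real data instead of erasing the shared trajectory.

Subject heterogeneity is modelled as an independent log-normal scaling of
alpha per (subject, gene) (sd ``subject_alpha_sd`` on the log scale), which
induces the within-subject correlation that a subject-level permutation null
must respect and that survives size-factor normalization.  beta is fixed to
1 for all genes, so gamma is the gamma/beta ratio the phase portrait
identifies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .io import CountLayers
from .kinetics import KineticParams, simulate_kinetics

__all__ = ["SimConfig", "SyntheticDataset", "generate_cohort", "write_dataset"]

DEFAULT_CELL_TYPES = (
    "excitatory",
    "inhibitory",
    "astrocyte",
    "microglia",
    "oligodendrocyte",
    "OPC",
)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Counts default to a small two-group design (2 groups x 6 subjects x 100
    cells, 200 genes of which 30 dynamic and 30 DE) that a laptop handles in
    seconds; noise is Poisson unless ``noise="nb"`` with ``nb_dispersion``
    (negative binomial, var = mu + mu^2/dispersion).

    ``trait_coupling`` maps each trait name to ``{"cell_type": name,
    "genes": [(gene, weight), ...]}``; the trait is that weighted sum of
    subject-mean true velocities over the subject's cells of the designated
    type, plus Gaussian noise with sd ``trait_noise_sd`` times the spread of
    the noise-free signal across subjects (a relative noise level).
    """

    n_genes: int = 200
    n_dynamic_genes: int = 30
    n_de_genes: int = 30
    n_subjects_per_group: int = 6
    n_cells_per_subject: int = 100
    cell_types: tuple = DEFAULT_CELL_TYPES
    groups: tuple = ("control", "AD")
    group_effect_gamma: float = 2.0
    group_effect_alpha: float = 2.0
    subject_alpha_sd: float = 0.1
    trait_coupling: dict = dc_field(default_factory=dict)
    trait_genes_per_trait: int = 3
    trait_noise_sd: float = 0.3
    noise: str = "poisson"
    nb_dispersion: float = 10.0
    # kinetic parameter ranges (beta fixed to 1)
    alpha_range: tuple = (5.0, 15.0)
    gamma_range: tuple = (0.2, 0.8)
    t_switch_range: tuple = (8.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dynamic_genes + self.n_de_genes > self.n_genes:
            raise ValueError("n_dynamic_genes + n_de_genes must be <= n_genes")
        if self.n_genes <= 0 or self.n_subjects_per_group <= 0:
            raise ValueError("gene and subject counts must be positive")
        if self.n_cells_per_subject <= 0:
            raise ValueError("n_cells_per_subject must be positive")
        if self.group_effect_gamma <= 0 or self.group_effect_alpha <= 0:
            raise ValueError("group effect factors must be > 0")
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        if self.noise not in ("poisson", "nb"):
            raise ValueError(f"unknown noise family {self.noise!r}")


@dataclass
class SyntheticDataset:
    """A generated cohort together with its ground truth.

    ``truth`` holds per-gene labels, per-group kinetic parameters, per-gene
    phase offsets and the per-cell latent-time fraction; expected abundances
    and the true velocity matrix (beta*u - gamma*s on expected values) are
    kept in memory for validation but are not written to disk.
    """

    counts: CountLayers
    cells: pd.DataFrame
    subjects: pd.DataFrame
    truth: dict
    u_expected: np.ndarray
    s_expected: np.ndarray
    true_velocity: np.ndarray

    @property
    def induction_mask(self) -> np.ndarray:
        """Cells x genes boolean matrix: True where the cell sits in the
        induction phase of that gene's cycle."""
        q = np.asarray(self.truth["latent_fraction"])[:, None]
        phi = np.asarray(self.truth["phase_offset"])[None, :]
        return ((q + phi) % 1.0) < 0.5


def _type_windows(n_types: int, width: float = 0.5):
    """Overlapping latent-time-fraction windows, one per cell type."""
    centers = (np.arange(n_types) + 0.5) / n_types
    lo = np.clip(centers - width / 2, 0.0, 1.0)
    hi = np.clip(centers + width / 2, 0.0, 1.0)
    return lo, hi


def generate_cohort(config: SimConfig) -> SyntheticDataset:
    """Generate a cohort; a fixed seed yields a byte-identical dataset."""
    rng = np.random.default_rng(config.seed)
    n_types = len(config.cell_types)
    n_subj = config.n_subjects_per_group * len(config.groups)
    n_cells = n_subj * config.n_cells_per_subject
    affected_group = config.groups[1]

    # gene-level kinetics (beta == 1 throughout)
    alpha = rng.uniform(*config.alpha_range, size=config.n_genes)
    gamma = rng.uniform(*config.gamma_range, size=config.n_genes)
    t_switch = rng.uniform(*config.t_switch_range, size=config.n_genes)
    phase_offset = rng.uniform(0.0, 1.0, size=config.n_genes)
    labels = np.array(["null"] * config.n_genes, dtype=object)
    labels[: config.n_dynamic_genes] = "dynamic"
    labels[config.n_dynamic_genes : config.n_dynamic_genes + config.n_de_genes] = "de"
    # effects alternate direction (factor f / 1/f) across designated genes:
    # dysregulation goes both ways in disease, and balancing the directions
    # keeps layer totals comparable between groups so per-cell size-factor
    # normalization does not translate a global perturbation into spurious
    # shifts of every unaffected gene
    sign = np.where(np.arange(config.n_genes) % 2 == 0, 1.0, -1.0)
    gamma_aff = np.where(
        labels == "dynamic", gamma * config.group_effect_gamma**sign, gamma
    )
    alpha_aff = np.where(
        labels == "de", alpha * config.group_effect_alpha**sign, alpha
    )

    # subjects: covariates, group, per-(subject, gene) alpha random effect
    subject_ids = [f"S{i:02d}" for i in range(n_subj)]
    subj_group = np.repeat(list(config.groups), config.n_subjects_per_group)
    subj_alpha_re = np.exp(
        rng.normal(0.0, config.subject_alpha_sd, size=(n_subj, config.n_genes))
    )
    subjects = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "group": subj_group,
            "age": np.round(rng.normal(86.0, 4.0, size=n_subj), 1),
            # alternating within each contiguous group block: sexes are
            # balanced within groups, as in the cohorts this emulates
            "sex": np.tile(["F", "M"], (n_subj + 1) // 2)[:n_subj],
            "education": np.round(rng.normal(18.0, 3.0, size=n_subj), 1),
            "pmi": np.round(rng.uniform(4.0, 12.0, size=n_subj), 2),
        }
    )

    # cells: balanced composition — every subject gets the same round-robin
    # mix of cell types and a stratified-uniform latent grid per type, so
    # group differences can only arise from kinetics and subject effects,
    # never from cell-state sampling noise
    cell_subject = np.repeat(subject_ids, config.n_cells_per_subject)
    cell_type_idx = np.tile(
        np.arange(config.n_cells_per_subject) % n_types, n_subj
    )
    lo, hi = _type_windows(n_types)
    latent_frac = np.empty(n_cells)
    for s in range(n_subj):
        block = slice(s * config.n_cells_per_subject, (s + 1) * config.n_cells_per_subject)
        types_here = cell_type_idx[block]
        q = np.empty(config.n_cells_per_subject)
        for k in range(n_types):
            sel = np.flatnonzero(types_here == k)
            if sel.size == 0:
                continue
            strata = (np.arange(sel.size) + rng.uniform(0, 1, sel.size)) / sel.size
            q[sel] = lo[k] + strata * (hi[k] - lo[k])
        latent_frac[block] = q
    cells = pd.DataFrame(
        {
            "barcode": [f"C{i:06d}" for i in range(n_cells)],
            "subject_id": cell_subject,
            "cell_type": np.asarray(config.cell_types, dtype=object)[cell_type_idx],
            "group": pd.Series(cell_subject).map(
                dict(zip(subject_ids, subj_group))
            ),
        }
    )
    cell_affected = (cells["group"] == affected_group).to_numpy()
    subj_index = pd.Series(cell_subject).map(
        {s: i for i, s in enumerate(subject_ids)}
    ).to_numpy()

    # expected abundances per cell x gene (gene-specific phase offsets)
    u_exp = np.empty((n_cells, config.n_genes))
    s_exp = np.empty((n_cells, config.n_genes))
    for g in range(config.n_genes):
        t = ((latent_frac + phase_offset[g]) % 1.0) * 2.0 * t_switch[g]
        for aff, (a, gam) in (
            (False, (alpha[g], gamma[g])),
            (True, (alpha_aff[g], gamma_aff[g])),
        ):
            mask = cell_affected == aff
            params = KineticParams(alpha=a, beta=1.0, gamma=gam, t_switch=t_switch[g])
            u_exp[mask, g], s_exp[mask, g] = simulate_kinetics(params, t[mask])
    u_exp *= subj_alpha_re[subj_index]
    s_exp *= subj_alpha_re[subj_index]

    if config.noise == "poisson":
        U = rng.poisson(u_exp)
        S = rng.poisson(s_exp)
    else:
        r = config.nb_dispersion
        U = rng.negative_binomial(r, r / (r + np.maximum(u_exp, 1e-12)))
        S = rng.negative_binomial(r, r / (r + np.maximum(s_exp, 1e-12)))

    # traits: weighted subject-mean true velocity of coupled genes within a
    # designated cell type, plus Gaussian noise scaled to the signal spread
    # (a whole-cycle mean velocity is ~0 by construction, so coupling acts
    # through the cell type whose latent window breaks the cancellation)
    gamma_cellwise = np.where(cell_affected[:, None], gamma_aff, gamma)
    v_true = u_exp - gamma_cellwise * s_exp
    type_names_arr = np.asarray(config.cell_types, dtype=object)[cell_type_idx]
    coupling = dict(config.trait_coupling) or _default_coupling(
        labels,
        config.cell_types,
        v_true,
        type_names_arr,
        n_per_trait=config.trait_genes_per_trait,
    )
    gene_pos = {f"g{g:04d}": g for g in range(config.n_genes)}
    type_names = type_names_arr
    for trait, spec_t in coupling.items():
        ct, pairs = spec_t["cell_type"], spec_t["genes"]
        in_ct = type_names == ct
        vals = np.zeros(n_subj)
        for gene, weight in pairs:
            gi = gene_pos[gene] if isinstance(gene, str) else int(gene)
            mean_v = (
                pd.Series(v_true[in_ct, gi])
                .groupby(subj_index[in_ct])
                .mean()
            )
            vals += weight * mean_v.reindex(range(n_subj)).fillna(0.0).to_numpy()
        noise_sd = config.trait_noise_sd * (vals.std() if vals.std() > 0 else 1.0)
        subjects[trait] = np.round(
            vals + rng.normal(0.0, noise_sd, size=n_subj), 6
        )

    features = pd.DataFrame(
        {
            "gene_id": [f"g{g:04d}" for g in range(config.n_genes)],
            "symbol": [f"G{g:04d}" for g in range(config.n_genes)],
            "length": rng.integers(500, 200_000, size=config.n_genes),
        }
    )
    counts = CountLayers(
        S=S.astype(np.int64),
        U=U.astype(np.int64),
        barcodes=list(cells["barcode"]),
        features=features,
    )
    truth = {
        "labels": labels.tolist(),
        "alpha": alpha.tolist(),
        "gamma": gamma.tolist(),
        "t_switch": t_switch.tolist(),
        "alpha_affected": alpha_aff.tolist(),
        "gamma_affected": gamma_aff.tolist(),
        "affected_group": affected_group,
        "beta": 1.0,
        "phase_offset": phase_offset.tolist(),
        "latent_fraction": latent_frac.tolist(),
        "subject_alpha_effect": dict(
            zip(subject_ids, np.round(subj_alpha_re, 6).tolist())
        ),
        "trait_coupling": {
            t: {
                "cell_type": spec_t["cell_type"],
                "genes": [
                    [g if isinstance(g, str) else f"g{g:04d}", w]
                    for g, w in spec_t["genes"]
                ],
            }
            for t, spec_t in coupling.items()
        },
    }
    return SyntheticDataset(
        counts=counts,
        cells=cells,
        subjects=subjects,
        truth=truth,
        u_expected=u_exp,
        s_expected=s_exp,
        true_velocity=v_true,
    )


def _default_coupling(
    labels: np.ndarray, cell_types, v_true, type_names, n_per_trait: int = 3
) -> dict:
    """Couple each trait to the dynamic genes with the strongest mean true
    velocity in its designated cell type (weight 1), round-robin over
    traits and cell types; genes already claimed by another trait are
    skipped so the planted signals stay distinct."""
    dyn = np.flatnonzero(labels == "dynamic")
    traits = ("np", "nft", "amyloid", "tangles")
    coupling = {}
    claimed: set = set()
    for i, trait in enumerate(traits):
        ct = cell_types[i % len(cell_types)]
        in_ct = type_names == ct
        strength = np.abs(v_true[in_ct][:, dyn].mean(axis=0)) if in_ct.any() else np.zeros(dyn.size)
        order = [g for g in dyn[np.argsort(-strength)] if g not in claimed]
        picks = order[:n_per_trait]
        claimed.update(picks)
        coupling[trait] = {
            "cell_type": ct,
            "genes": [(f"g{g:04d}", 1.0) for g in picks],
        }
    return coupling


def write_dataset(ds: SyntheticDataset, directory) -> Path:
    """Write MTX layers, annotation tables and truth.json to ``directory``.

    ``read_matrices(write_dataset(ds, d))`` reproduces the counts exactly.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(
            directory / "spliced.mtx", sp.coo_matrix(ds.counts.S), field="integer"
        )
        scipy.io.mmwrite(
            directory / "unspliced.mtx", sp.coo_matrix(ds.counts.U), field="integer"
        )
        (directory / "barcodes.tsv").write_text(
            "\n".join(ds.counts.barcodes) + "\n"
        )
        ds.counts.features.to_csv(
            directory / "features.tsv", sep="\t", header=False, index=False
        )
        ds.cells.to_csv(directory / "cells.tsv", sep="\t", index=False)
        ds.subjects.to_csv(directory / "subjects.tsv", sep="\t", index=False)
        with open(directory / "truth.json", "w") as fh:
            json.dump(ds.truth, fh, indent=1)
    except OSError as exc:
        raise OSError(f"failed writing dataset under {directory}: {exc}") from exc
    return directory
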
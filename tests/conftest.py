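import warnings

import numpy as np
import pytest

from velodelta import SimConfig, estimate_velocity, generate_cohort, normalize

warnings.filterwarnings("ignore", message="dropped .* cell")


@pytest.fixture(scope="session")
def small_cohort():
    """Small default-style cohort with group effects, shared across tests."""
    cfg = SimConfig(
        n_genes=80,
        n_dynamic_genes=10,
        n_de_genes=10,
        n_subjects_per_group=4,
        n_cells_per_subject=48,
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_velocity(small_cohort):
    """Normalized layers + pooled velocity estimate for the small cohort."""
    norm = normalize(small_cohort.counts)
    cells = small_cohort.cells[
        small_cohort.cells["barcode"].isin(norm.barcodes)
    ].reset_index(drop=True)
    vm, fit, mom = estimate_velocity(
        norm.S, norm.U, k=15, gene_ids=norm.gene_ids, barcodes=norm.barcodes
    )
    return norm, cells, vm, fit, mom


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
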
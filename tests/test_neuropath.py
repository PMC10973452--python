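"""Subject-mean velocities and covariate-adjusted Spearman association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from velodelta import (
    SimConfig,
    estimate_velocity,
    generate_cohort,
    normalize,
    partial_spearman,
    subject_mean_velocity,
    trait_association,
    trait_overlap_summary,
)


def spearman_oracle(x, y, C):
    """Independent route: explicit ranks (variables and covariates), QR
    projection, np.corrcoef."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rC = np.column_stack([stats.rankdata(C[:, j]) for j in range(C.shape[1])])
    design = np.column_stack([np.ones(len(x)), rC])
    Q, _ = np.linalg.qr(design)
    ex = rx - Q @ (Q.T @ rx)
    ey = ry - Q @ (Q.T @ ry)
    return np.corrcoef(ex, ey)[0, 1]


class TestSubjectMeanVelocity:
    def setup_method(self):
        self.cells = pd.DataFrame(
            {
                "barcode": ["c0", "c1", "c2", "c3"],
                "subject_id": ["s0", "s0", "s1", "s1"],
                "cell_type": ["exc", "exc", "exc", "mic"],
                "group": ["A", "A", "B", "B"],
            }
        )
        self.V = np.array([[1.0], [3.0], [5.0], [7.0]])

    def test_mean_of_two_cells(self):
        sgm = subject_mean_velocity(self.V, self.cells)
        means, counts = sgm["exc"]
        assert means.loc["s0", 0] == 2.0
        assert counts.loc["s0"] == 2

    def test_single_cell_subject(self):
        means, counts = subject_mean_velocity(self.V, self.cells)["exc"]
        assert means.loc["s1", 0] == 5.0 and counts.loc["s1"] == 1

    def test_missing_cell_type_is_nan_with_zero_count(self):
        means, counts = subject_mean_velocity(self.V, self.cells)["mic"]
        assert np.isnan(means.loc["s0", 0]) and counts.loc["s0"] == 0


class TestPartialSpearman:
    def test_reduces_to_ordinary_spearman(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, p = partial_spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert np.isclose(rho, ref.statistic, atol=1e-12)
        assert np.isclose(p, ref.pvalue, rtol=1e-6)

    def test_perfect_confounder_kills_correlation(self, rng):
        """y identical to a covariate: ranking the covariate removes the
        association entirely, leaving no residual correlation."""
        c = rng.normal(size=40)
        x = np.exp(c) + rng.normal(0, 0.3, size=40)
        rho, p = partial_spearman(x, c.copy(), covariates=c)
        assert rho == 0.0 and p == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=30), rng.normal(size=30)
        C = rng.normal(size=(30, 3))
        rho, _ = partial_spearman(x, y, covariates=C)
        assert abs(rho - spearman_oracle(x, y, C)) < 1e-10

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.normal(size=25), rng.normal(size=25)
        C = rng.normal(size=(25, 2))
        r1, p1 = partial_spearman(x, y, C)
        r2, p2 = partial_spearman(np.exp(x), y**3, C)
        assert np.isclose(r1, r2) and np.isclose(p1, p2)

    def test_insufficient_cases_give_nan(self):
        rho, p = partial_spearman(np.ones(4), np.ones(4), covariates=np.ones((4, 3)))
        assert np.isnan(rho) and np.isnan(p)


@pytest.fixture(scope="module")
def planted_cohort():
    cfg = SimConfig(
        n_genes=100,
        n_dynamic_genes=12,
        n_de_genes=0,
        cell_types=("excitatory", "inhibitory"),
        n_subjects_per_group=12,
        n_cells_per_subject=120,
        group_effect_gamma=1.0,
        group_effect_alpha=1.0,
        subject_alpha_sd=0.3,
        trait_noise_sd=0.2,
        trait_genes_per_trait=1,
        seed=7,
    )
    ds = generate_cohort(cfg)
    norm = normalize(ds.counts)
    cells = ds.cells[ds.cells["barcode"].isin(norm.barcodes)].reset_index(drop=True)
    vm, _, _ = estimate_velocity(
        norm.S,
        norm.U,
        k=15,
        gene_ids=norm.gene_ids,
        pooling="per_subject",
        subjects=cells["subject_id"].to_numpy(),
    )
    sgm = subject_mean_velocity(vm.V, cells, subject_ids=list(ds.subjects["subject_id"]))
    assoc = trait_association(sgm, ds.subjects, gene_ids=norm.gene_ids)
    return ds, assoc


class TestTraitAssociation:
    def test_planted_genes_recovered_as_top_hits(self, planted_cohort):
        """With 24 subjects the best null correlation among ~100 genes can
        occasionally edge out one planted signal, so the check is that at
        least 3 of the 4 planted genes sit in their family's top 3 and the
        median planted rank is 1."""
        ds, assoc = planted_cohort
        ranks = []
        for trait, info in ds.truth["trait_coupling"].items():
            planted = info["genes"][0][0]
            fam = assoc[
                (assoc["trait"] == trait) & (assoc["cell_type"] == info["cell_type"])
            ].sort_values("p")
            ranks.append(int(np.flatnonzero(fam["gene"].to_numpy() == planted)[0]) + 1)
        assert sum(r <= 3 for r in ranks) >= 3, ranks
        assert np.median(ranks) == 1, ranks

    def test_holm_dominates_bonferroni_and_p(self, planted_cohort):
        _, assoc = planted_cohort
        fam = assoc[(assoc["trait"] == "np")].dropna(subset=["p"])
        m = fam.groupby("cell_type")["p"].transform("size")
        assert (fam["p_fwer"] >= fam["p"] - 1e-15).all()
        assert (fam["p_fwer"] <= np.minimum(m * fam["p"], 1.0) + 1e-12).all()

    def test_null_traits_rarely_significant(self):
        """Traits independent of all velocities: no FWER calls at alpha
        1e-3 in nearly every replicate."""
        clean = 0
        n_rep = 12
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            n_subj, n_genes = 24, 300
            means = pd.DataFrame(
                rng.normal(size=(n_subj, n_genes)),
                index=[f"s{i}" for i in range(n_subj)],
            )
            meta = pd.DataFrame(
                {
                    "subject_id": means.index,
                    "age": rng.normal(85, 4, n_subj),
                    "sex": rng.choice(["F", "M"], n_subj),
                    "education": rng.normal(18, 3, n_subj),
                    "pmi": rng.uniform(4, 12, n_subj),
                    "np": rng.normal(size=n_subj),
                }
            )
            sgm = {"exc": (means, pd.Series(10, index=means.index))}
            assoc = trait_association(sgm, meta, traits=("np",))
            clean += assoc["significant"].sum() == 0
        assert clean >= int(0.9 * n_rep)

    def test_single_gene_family_fwer_equals_p(self, rng):
        means = pd.DataFrame(
            rng.normal(size=(20, 1)), index=[f"s{i}" for i in range(20)]
        )
        meta = pd.DataFrame(
            {
                "subject_id": means.index,
                "age": rng.normal(85, 4, 20),
                "sex": rng.choice(["F", "M"], 20),
                "education": rng.normal(18, 3, 20),
                "pmi": rng.uniform(4, 12, 20),
                "np": rng.normal(size=20),
            }
        )
        assoc = trait_association({"exc": (means, None)}, meta, traits=("np",))
        assert np.isclose(assoc["p_fwer"].iloc[0], assoc["p"].iloc[0])

    def test_constant_trait_family_skipped(self, rng):
        means = pd.DataFrame(rng.normal(size=(10, 2)), index=[f"s{i}" for i in range(10)])
        meta = pd.DataFrame(
            {
                "subject_id": means.index,
                "age": rng.normal(85, 4, 10),
                "sex": rng.choice(["F", "M"], 10),
                "education": rng.normal(18, 3, 10),
                "pmi": rng.uniform(4, 12, 10),
                "np": np.ones(10),
            }
        )
        assoc = trait_association({"exc": (means, None)}, meta, traits=("np",))
        assert assoc.empty

    def test_recovery_improves_with_coupling_weight(self):
        """Correlation of the planted gene rises with the coupling weight
        relative to trait noise (3 noise levels as weight surrogates)."""
        rhos = []
        for noise in (2.0, 0.5, 0.1):
            cfg = SimConfig(
                n_genes=40,
                n_dynamic_genes=4,
                n_de_genes=0,
                cell_types=("excitatory",),
                n_subjects_per_group=12,
                n_cells_per_subject=80,
                group_effect_gamma=1.0,
                group_effect_alpha=1.0,
                subject_alpha_sd=0.3,
                trait_noise_sd=noise,
                trait_genes_per_trait=1,
                seed=3,
            )
            ds = generate_cohort(cfg)
            info = ds.truth["trait_coupling"]["np"]
            gi = int(info["genes"][0][0][1:])
            subj = ds.cells["subject_id"].to_numpy()
            true_mean = (
                pd.Series(ds.true_velocity[:, gi]).groupby(subj).mean()
            )
            trait = ds.subjects.set_index("subject_id")["np"]
            rhos.append(abs(stats.spearmanr(true_mean, trait.loc[true_mean.index]).statistic))
        assert rhos[0] < rhos[1] < rhos[2]


def test_trait_overlap_summary_counts():
    assoc = pd.DataFrame(
        {
            "cell_type": ["exc"] * 6,
            "trait": ["np", "np", "np", "nft", "nft", "nft"],
            "gene": ["a", "b", "c", "b", "c", "d"],
            "significant": [True] * 6,
        }
    )
    out = trait_overlap_summary(assoc)
    row = out.iloc[0]
    assert row["n_overlap"] == 2 and row["pct_of_smaller"] == pytest.approx(2 / 3 * 100)
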
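"""Subject-level permutation differential testing and FDR calls."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from velodelta import (
    call_significant,
    fdr_adjust,
    group_fold_change,
    length_bias_check,
    wilcoxon_permutation,
)


def two_group_setup(rng, n_subj_per_group=3, cells_per_subj=10, n_genes=4, shift=0.0):
    n_subj = 2 * n_subj_per_group
    subj = np.repeat([f"s{i}" for i in range(n_subj)], cells_per_subj)
    groups = np.repeat(["A", "B"], n_subj_per_group * cells_per_subj)
    X = rng.normal(size=(n_subj * cells_per_subj, n_genes))
    X[groups == "A"] += shift
    return X, groups, subj


class TestGroupFoldChange:
    def test_powers_of_two(self):
        vals = np.array([[2.0], [2.0], [1.0], [1.0]])
        fc, disc = group_fold_change(vals, np.array(["A", "A", "B", "B"]), "A", "B")
        assert fc[0] == 1.0 and not disc[0]

    def test_equal_means_zero(self):
        vals = np.array([[3.0], [3.0]])
        fc, _ = group_fold_change(vals, np.array(["A", "B"]), "A", "B")
        assert fc[0] == 0.0

    def test_sign_discordant_flagged_and_unbounded(self):
        vals = np.array([[0.2], [-0.2]])
        fc, disc = group_fold_change(vals, np.array(["A", "B"]), "A", "B")
        assert disc[0] and np.isposinf(fc[0])
        assert abs(fc[0]) > 1e12  # exceeds any finite threshold

    def test_both_negative_uses_magnitude_ratio(self):
        vals = np.array([[-4.0], [-1.0]])
        fc, disc = group_fold_change(vals, np.array(["A", "B"]), "A", "B")
        assert fc[0] == 2.0 and not disc[0]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_fold_change(np.ones((2, 1)), np.array(["A", "A"]), "A", "B")


class TestWilcoxonPermutation:
    def test_all_equal_values(self, rng):
        X = np.ones((60, 2))
        subj = np.repeat([f"s{i}" for i in range(6)], 10)
        groups = np.repeat(["A", "B"], 30)
        u, p = wilcoxon_permutation(X, groups, subj, "A", "B", n_perm=99, seed=1)
        assert np.allclose(u, 30 * 30 / 2)  # n1*n2/2 under total ties
        assert np.allclose(p, 1.0)

    def test_exact_enumeration_matches_monte_carlo(self, rng):
        """4 subjects: the C(4,2)=6 exhaustive null equals the large-n_perm
        Monte-Carlo null."""
        X, groups, subj = two_group_setup(rng, n_subj_per_group=2, shift=1.0)
        u_ex, p_ex = wilcoxon_permutation(X, groups, subj, "A", "B", n_perm=6, seed=0)
        u_mc, p_mc = wilcoxon_permutation(X, groups, subj, "A", "B", n_perm=20000, seed=0)
        assert np.allclose(u_ex, u_mc)
        # MC add-one estimator converges to the exact tail fraction
        assert np.allclose(p_ex, p_mc, atol=0.02)

    def test_exact_enumeration_by_hand(self, rng):
        """p equals the hand-enumerated fraction of subject reassignments
        with as-extreme U."""
        X, groups, subj = two_group_setup(rng, n_subj_per_group=2, n_genes=1, shift=2.0)
        u_obs, p = wilcoxon_permutation(X, groups, subj, "A", "B", n_perm=100, seed=0)
        ranks = stats.rankdata(X[:, 0])
        subjects = [f"s{i}" for i in range(4)]
        n1 = n2 = 20.0
        devs = []
        for combo in combinations(range(4), 2):
            in_a = np.isin(subj, [subjects[i] for i in combo])
            u = ranks[in_a].sum() - n1 * (n1 + 1) / 2
            devs.append(abs(u - n1 * n2 / 2))
        dev_obs = abs(u_obs[0] - n1 * n2 / 2)
        expected = np.mean([d >= dev_obs - 1e-9 for d in devs])
        assert np.isclose(p[0], expected)

    def test_u_invariant_under_monotone_transform(self, rng):
        X, groups, subj = two_group_setup(rng, shift=0.5)
        u1, p1 = wilcoxon_permutation(X, groups, subj, "A", "B", n_perm=50, seed=3)
        u2, p2 = wilcoxon_permutation(np.exp(X), groups, subj, "A", "B", n_perm=50, seed=3)
        assert np.array_equal(u1, u2)
        assert np.array_equal(p1, p2)

    def test_seed_determinism(self, rng):
        X, groups, subj = two_group_setup(rng, n_subj_per_group=5, shift=0.3)
        r1 = wilcoxon_permutation(X, groups, subj, "A", "B", n_perm=200, seed=11)
        r2 = wilcoxon_permutation(X, groups, subj, "A", "B", n_perm=200, seed=11)
        assert np.array_equal(r1[1], r2[1])

    def test_too_few_subjects_rejected(self, rng):
        X, groups, subj = two_group_setup(rng, n_subj_per_group=1)
        with pytest.raises(ValueError):
            wilcoxon_permutation(X, groups, subj, "A", "B", n_perm=10, seed=0)


class TestFdrAdjust:
    def test_hand_applied_step_up(self):
        # q_i = min over j>=i of p_j * m / j ; here all reduce to 0.04
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert fdr_adjust([0.2])[0] == 0.2

    def test_all_ones(self):
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_empty(self):
        assert fdr_adjust([]).size == 0

    def test_matches_statsmodels_reference(self, rng):
        p = rng.uniform(size=50)
        from statsmodels.stats.multitest import multipletests

        assert np.allclose(fdr_adjust(p), multipletests(p, method="fdr_bh")[1])


class TestCallSignificant:
    def test_stated_thresholds_on_toy_table(self):
        tab = pd.DataFrame(
            {
                "gene": list("abcdef"),
                "q": [0.01, 0.04, 0.06, 0.2, 0.01, 0.03],
                "log2fc": [0.3, 0.1, 0.5, 0.3, 0.26, 0.24],
                "sign_discordant": [False] * 6,
            }
        )
        out = call_significant(tab)
        assert list(out.loc[out["significant"], "gene"]) == ["a", "e"]

    def test_empty_table(self):
        tab = pd.DataFrame(columns=["gene", "q", "log2fc", "sign_discordant"])
        assert call_significant(tab).empty

    def test_discordant_passes_fold_change_gate(self):
        tab = pd.DataFrame(
            {"gene": ["x"], "q": [0.01], "log2fc": [np.inf], "sign_discordant": [True]}
        )
        assert call_significant(tab)["significant"].iloc[0]


class TestLengthBias:
    def test_constant_input_flagged(self):
        r, p = length_bias_check(np.ones(10), np.arange(1, 11))
        assert np.isnan(r) and np.isnan(p)

    def test_perfect_correlation(self):
        lengths = np.linspace(1e3, 1e5, 20)
        r, p = length_bias_check(3.0 * lengths + 7.0, lengths)
        assert np.isclose(r, 1.0)

    def test_independent_inputs_uncorrelated(self):
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            u = rng.uniform(0, 1e4, size=1000)
            lengths = rng.uniform(500, 2e5, size=1000)
            r, p = length_bias_check(u, lengths)
            hits += (abs(r) < 0.08) and (p > 0.01)
        assert hits >= 23  # >=95% of seeds within the null band

    def test_positive_length_required(self):
        with pytest.raises(ValueError):
            length_bias_check(np.ones(3), np.array([1.0, -2.0, 3.0]))


class TestGroundTruthCalls:
    def test_dynamic_genes_called_null_rate_bounded(self):
        """On a cohort with two-fold kinetic effects, every dynamic gene is
        called for velocity while the null-gene call rate stays within the
        FDR budget plus Monte-Carlo allowance.  The cohort is large because
        kNN smoothing pools counting noise into a group-common component
        that shrinks with cell number (see the methods note)."""
        import velodelta as vd

        cfg = vd.SimConfig(
            n_genes=400,
            n_dynamic_genes=20,
            n_de_genes=20,
            n_subjects_per_group=6,
            n_cells_per_subject=1536,
            group_effect_gamma=2.0,
            group_effect_alpha=2.0,
            subject_alpha_sd=0.1,
            seed=4,
        )
        ds = vd.generate_cohort(cfg)
        norm = vd.normalize(ds.counts)
        cells = ds.cells[ds.cells["barcode"].isin(norm.barcodes)].reset_index(drop=True)
        vm, _, _ = vd.estimate_velocity(norm.S, norm.U, k=15, gene_ids=norm.gene_ids)
        labels = np.array(ds.truth["labels"])
        tab = vd.differential_table(
            vm.V,
            cells["group"].to_numpy(),
            cells["subject_id"].to_numpy(),
            norm.gene_ids,
            "AD",
            "control",
            metric="velocity",
            n_perm=1000,
            seed=4,
        )
        sig = tab["significant"].to_numpy()
        assert sig[labels == "dynamic"].all()
        assert sig[labels == "null"].mean() <= 0.08
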
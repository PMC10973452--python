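# Methods

## Kinetic model and velocity estimator

Expected unspliced/spliced abundance of a gene follows
du/dt = α − βu, ds/dt = βu − γs, with transcription switched off (α = 0) at
latent time `t_switch`.  The closed-form solution is used everywhere,
including the β = γ limit, where the cross term degenerates to
(βu₀ − α)·t·e^(−βt); the implementation switches to that limiting expression
when β and γ agree to relative 1e−12.  Velocity is ds/dt = βu − γs along the
trajectory; positive during induction, negative during repression, and
continuous at the switch — the sign flips only after the unspliced pool has
relaxed below γ/β, so cells in a short window after the switch genuinely
carry positive velocity while formally being in repression.

Estimation proceeds in three steps.  (1) Both count layers are normalized by
per-cell, per-layer size factors rescaled to the median layer total.
(2) Layers are smoothed by averaging over the k nearest neighbors (self
included) in the space of the top principal components of log1p spliced
expression; defaults k = 100, 30 PCs, matching common practice at the
10⁴–10⁵-cell scale.  For small cohorts k should be scaled down with the cell
count (the tests use k = 10–15 at 10³-cell scale): neighborhoods spanning a
large fraction of the data both oversmooth and, more subtly, share noise
across subjects (see *Limitations*).  (3) The slope γ/β is fitted through
the origin on cells in the extreme quantiles of smoothed spliced abundance
(default 5%/95%), which proxy the repressed and induced steady states.  The
`steady_state` mode uses the first-moment relation E[u] = γ′E[s] alone; the
`stochastic` mode stacks it with the second-moment relation
2E[us] + E[u] = γ′(2E[s²] − E[s]) of the Poisson counting process, weighting
each equation block by the inverse variance of its response so neither
dominates through scale.  Genes with all-zero spliced signal or a
non-positive slope are flagged invalid with the reason recorded; their
velocities are NaN, never silently zero.

Two properties worth knowing: the steady-state fit is exactly scale
equivariant (scaling both layers by c leaves γ̂ fixed and scales v by c),
while the stochastic fit is only asymptotically so, because its
second-moment equation lives on the count scale.  And on data whose second
moments are not Poisson-consistent (e.g. noise-free proportional layers)
the stochastic estimator is deliberately *not* expected to reproduce the
first-moment slope exactly; only the steady-state mode is.

Velocities are estimated on all cells pooled (the default) or independently
per subject (`pooling="per_subject"`).  Pooled estimation shares one γ̂ per
gene, which is what makes group differences in kinetics visible as velocity
differences; per-subject estimation preserves subject-level signal that
cross-subject smoothing would dilute, and is the right input for
subject-level trait association.

## Differential testing

Group differences per gene are scored by the Wilcoxon rank-sum U over cells
(average ranks at ties), but calibrated at the subject level: the null
reassigns whole subjects to groups, preserving group sizes and carrying each
subject's cells together.  When C(n_subjects, n_group) ≤ n_perm every
distinct reassignment is enumerated once and the p-value is the exact tail
fraction (the observed assignment counts itself, so p ≥ 1/N); otherwise
assignments are sampled with replacement and the add-one estimator
(1 + #exceed)/(n_perm + 1) is used, comparing |U − n₁n₂/2| per draw.  The
exact branch matters in small cohorts: with 12 subjects the Monte-Carlo p
floor (~6/1001, inflated by redraws of the identity assignment and its
complement) sits exactly where Benjamini–Hochberg needs p to be for a few
dozen true positives among a few hundred genes, making calls unstable; the
exact floor 2/924 is below it and deterministic.

Significance combines q < 0.05 (BH within each cell type × metric family)
with |log₂(mean_case/mean_control)| > 0.25.  Velocity means can be negative:
two negative means use the magnitude ratio; opposite signs (or a zero mean)
set a `sign_discordant` flag and an infinite signed log2fc, so a sign flip —
itself a strong dynamic difference — always passes the fold-change gate and
is identifiable downstream.  A per-gene Pearson check of U statistics
against gene length is provided to exclude length bias from intron-rich
transcripts.

## Speed, fields, traits, replication

Cell speed is the Euclidean norm of the velocity vector over valid genes;
group medians are compared by the two-sided rank-sum test.  For fields, each
cell's velocity is compared (cosine similarity) with expression
displacements toward its embedding neighbors; a softmax with per-cell
adaptive temperature (median |cosine|, floored at 1e−3) turns similarities
into transition weights, and the 2D vector is the weighted mean of unit
embedding displacements minus the uniform baseline, so zero velocity maps to
a zero vector.  Group fields are Gaussian-kernel smoothed onto one shared
lattice (default 50×50 over the union bounding box, bandwidth = lattice
spacing); lattice points with support from only one group are filled by
linear interpolation of that group's own field, making the subtraction
well-defined at identical coordinates.  z-scores standardize the residual
*norms* over the lattice and the mask is |z| > 1.96.  Under a shared field
with isotropic noise the masked fraction is ≈4–5%, not exactly 5%: norms of
2D Gaussian residuals are Rayleigh-like, so the lower tail contributes
almost nothing.  Residual directions carry no interpretation; only the mask
and |z| magnitudes do.  External embedding coordinates are accepted
verbatim; the fallback is the first two PCs (deterministic, unlike t-SNE).

Trait association averages each subject's per-cell-type velocities
(NaN-aware, contributing-cell counts recorded), then computes partial
Spearman correlations: *all* variables including covariates are
rank-transformed, ranks are residualized on an intercept plus covariate
ranks, and the Pearson correlation of residuals is tested on n − 2 − k
degrees of freedom.  Ranking the covariates makes a perfectly monotone
confounder cancel exactly; a variable fully explained by covariates returns
ρ = 0.  The default covariate set is {age, sex, education, pmi}; passing
`covariates=("age", "sex", "pmi")` reproduces the narrower adjustment.  FWER
is controlled by Holm step-down within each (cell type × trait) family —
the smallest defensible family given that the published analyses report per
cell type and trait.  Replication of significant gene sets across datasets
uses the one-sided (enrichment) Fisher exact p from hypergeometric tail
summation on the universe of genes tested in both datasets, with the sample
odds ratio (Haldane 0.5 correction only when a zero cell occurs, flagged);
the replication criterion is p < 0.01 and OR > 1.

## The synthetic cohort generator

The generator is the package's ground-truth instrument, not a data mimic.
Each cell carries one latent-time fraction q ∈ [0, 1); gene g sees the cell
at phase (q + φ_g) mod 1 of its own induction/repression cycle, with a fixed
per-gene offset φ_g.  Desynchronizing genes this way matches real tissue
(transcriptional programs are not globally in phase) and keeps per-cell
totals stable so size-factor normalization behaves as on real data; with a
single global phase, normalization erases the trajectory itself.

Defaults (all configurable): 200 genes, α ~ U(5, 15), γ ~ U(0.2, 0.8),
β ≡ 1, t_switch ~ U(8, 12) with latent time uniform over [0, 2·t_switch];
six cortical cell types assigned round-robin within each subject, and the
latent grid stratified-uniform and identical across subjects.  The balanced
composition is deliberate: subject-specific cell-state sampling noise is
shared across all genes and would otherwise dominate the between-subject
variance, so group differences can only arise from kinetics, designated
effects and subject effects — which is exactly what downstream tests must
be scored against.  Cell types occupy overlapping latent windows (width 0.5,
centers spread over the cycle), giving each type a distinct phase profile.

Group effects: "dynamic" genes have γ multiplied by `group_effect_gamma` in
the affected group, "de" genes have α multiplied by `group_effect_alpha`;
effects alternate direction (factor f and 1/f) across the designated genes,
both because dysregulation is bidirectional in disease and because
one-directional effects shift layer totals between groups, which size-factor
normalization then translates into spurious shifts of every null gene.
Subject heterogeneity is an independent log-normal scaling of α per
(subject, gene) (sd 0.1 on the log scale): a scaling shared across genes
would be removed exactly by normalization and leave no within-subject
correlation for the permutation machinery to respect.  Counting noise is
Poisson on the expected abundances (negative binomial with configurable
dispersion as an option).  Covariates: age ~ N(86, 4), sex alternating
within group, education ~ N(18, 3), pmi ~ U(4, 12) hours.

Traits (`np`, `nft`, `amyloid`, `tangles`) are weighted sums of subject-mean
*true* velocity of designated genes within a designated cell type, plus
Gaussian noise at `trait_noise_sd` times the signal spread across subjects
(default 0.3).  The cell-type restriction is essential: over a full cycle
the mean of ds/dt telescopes to ≈0, so only a partial phase window leaves a
coupling to detect.  By default each trait picks the dynamic genes with the
strongest within-type mean velocity (round-robin over traits and types,
previously claimed genes skipped).

`truth.json` schema: `labels` (per-gene "dynamic" / "de" / "null"),
`alpha`/`gamma`/`t_switch` (control-group kinetics per gene),
`alpha_affected`/`gamma_affected` (affected-group values), `beta` (1.0),
`affected_group`, `phase_offset` (per gene), `latent_fraction` (per cell),
`subject_alpha_effect` (subject → per-gene multipliers), `trait_coupling`
(trait → {cell_type, genes: [[gene, weight], …]}).

What the generator does **not** emulate: sequencing reads, barcode errors,
doublets, ambient RNA, per-cell depth variation, subject-specific cell-type
composition, batch effects, or gene–gene regulatory correlation beyond the
shared latent time.  Passing tests therefore demonstrate correctness of the
statistical machinery under the kinetic model, not robustness to those
real-data artifacts.

## Scenario configurations used in the tests

Problem sizes are chosen so each check measures what it claims at desk
scale.  γ-recovery uses equilibrium-dwelling trajectories
(t_switch ~ U(25, 35), all genes at γ = 0.3, 100 genes) at 200 / 2,000 /
20,000 cells: median relative error is within 10% at 2,000 cells for both
fit modes and decreases with cell count.  The velocity-sign check uses slow
degradation (γ ~ U(0.2, 0.4)): fast-degrading genes spend most of
repression at |v| ≈ 0 where no estimator can call a sign, while slow
degradation keeps both phases transient and ≥95% of (cell, gene) signs are
recovered.  Permutation calibration uses 12 subjects × 96 cells, 500 genes,
500 permutations, k = 15 (k scaled to the cohort as discussed above): the
p-value distribution over genes is KS-uniform and no null gene survives
q < 0.05 with the fold-change filter.  The ground-truth differential check
runs at 12 × 1,536 cells with two-fold effects: all dynamic genes are
called; the null-gene call rate is bounded by the FDR budget plus
Monte-Carlo allowance (0.08).

## Limitations

- **Group-common smoothing noise.**  When the groups separate in PCA space
  (which any real group effect causes), kNN neighborhoods become group-pure
  and moment smoothing pools counting noise into a component shared by all
  cells of a group at a given position.  This component is not
  subject-structured, so subject-level permutation cannot null it, and the
  velocity-metric false-positive rate inflates in small cohorts (observed:
  ~50% of null genes at ~1,000 cells, ~7% at 9,000, ~4% at 18,000, at
  k = 15).  It shrinks with cells-per-position and is far smaller at the
  10⁵-cell scale the default parameters target, but it is a genuine property
  of moment-smoothed velocities that users comparing small cohorts should
  know about.  Conversely, heavy smoothing averages *across* groups where
  they overlap, which erases real differences and makes naive cell-level
  tests paradoxically conservative on smoothed values — the classic
  pseudoreplication demonstration (cell-level tests anti-conservative,
  subject-level calibrated) is therefore run on unsmoothed expression.
- **Steady-state proxy bias.**  Extreme-quantile cells are contaminated by
  early-repression cells when trajectories do not dwell at equilibrium,
  biasing γ̂ low by up to tens of percent for strongly transient regimes.
- **Permutation granularity.**  With 12 subjects the smallest attainable
  two-sided exact p is 2/924 ≈ 0.0022; FWER/FDR conclusions below that
  resolution are not meaningful at this cohort size.
- The trait model is linear in subject-mean velocity with independent
  Gaussian noise; no nonlinearity, censoring or trait–covariate
  correlation is simulated.
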
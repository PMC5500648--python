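# Methods

## The statistical problem

Given one structural connectivity (SC) matrix per subject — an M×M
symmetric matrix of nonnegative integers whose (i, j) entry counts the
tractography streamlines joining brain modules i and j — we ask, module by
module, whether two (or more) groups of subjects differ in that module's
*connectivity profile*: the vector of its streamline counts to the other
M−1 modules. Because a profile is multivariate and its entries are strongly
inter-dependent, mass-univariate edge tests are both underpowered and
multiplicity-hungry; instead the comparison is carried out on pairwise
subject dissimilarities (multivariate distance matrix regression, MDMR —
the one-factor case is also known as PERMANOVA).

## Distance construction

For module i and subjects u, v with profiles x_u, x_v (length M−1, the
diagonal entry excluded), the dissimilarity is the correlation chord
distance

    d_uv = sqrt(2 · (1 − r_uv)),

with r_uv the Pearson correlation of the two profiles. Properties that
matter here:

* range [0, 2]: identical shape → 0, uncorrelated → √2, anticorrelated → 2;
* invariance under positive affine rescaling of a profile — the statistic
  responds to the *shape* of a module's connectivity pattern, not to a
  subject's overall streamline yield;
* Euclidean embeddability: the Gower-centred matrix of squared chord
  distances is positive semidefinite, which guarantees a nonnegative
  between-group sum of squares.

`metric="squared"` keeps the squared chord 2·(1 − r) (range [0, 4]) for
sensitivity analyses. Counts enter the correlation untransformed by
default; `transform="log1p"` is available. A zero-variance (constant)
profile leaves Pearson r undefined; the default is a hard validation
error, with an opt-in policy that defines r = 0 for such pairs and logs
the event.

## The pseudo-F decomposition and permutation inference

With N subjects in m groups of sizes n_g, and D = (d_uv) one module's
distance matrix:

    SS_T = (1/N) Σ_{u<v} d_uv²
    SS_W = Σ_g (1/n_g) Σ_{u<v in g} d_uv²
    SS_B = SS_T − SS_W
    F    = (SS_B / (m − 1)) / (SS_W / (N − m))

Sums run over unordered pairs. With m = 1 the identity SS_W = SS_T holds,
and on univariate data with Euclidean distance the pseudo-F reduces
exactly to the classical one-way ANOVA F (verified to 1e-8 in the test
suite). The pseudo-F is not F-distributed under the null for general
dissimilarities, so inference is by permutation: group labels are
shuffled (equivalently, rows and columns of D are jointly permuted) and

    p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)

under the default add-one convention, which keeps p in (0, 1] and makes
the permutation floor 1/(1 + n_perm) explicit. A literal convention
(#{F_perm > F_obs}/n_perm, which can return 0) is available via
`p_convention="literal"` and `tie_rule="gt"`. The observed statistic is
computed through the same vectorised code path as the permuted ones, so
a relabeling that maps every group onto itself ties with F_obs exactly
rather than to within rounding. Degenerate inputs are flagged, not
hidden: SS_W = 0 with SS_B > 0 reports F = +inf (`perfect-separation`),
an all-zero distance matrix reports F = nan (`degenerate`).

Across the M module tests of one comparison, raw permutation p-values are
adjusted by Benjamini–Hochberg step-up FDR (`statsmodels` implementation
behind a validated wrapper). FDR is applied within a comparison (M tests),
not across comparisons. Default n_perm is 10,000; the analyses shipped in
`scripts/acceptance.py` use 999 to keep runtimes in seconds at their
problem sizes (two to four groups of 20–36 subjects, 20 modules), which
leaves the p-value floor at 0.001.

Because permutation p-values saturate at their floor, "the most affected
module" is ill-defined by p alone when several modules saturate;
`rank_modules` therefore orders by adjusted p with ties broken by
descending pseudo-F, then module index.

### Seeding

Every random stream derives from `numpy` `SeedSequence` material: a
module's permutation stream is `SeedSequence([seed, module])` (or
`[seed, stage, module]` inside the pipeline), so any single module or
stage can be recomputed independently and reproducibly. Rerunning a
pipeline with the same config produces bit-identical report files.

## Demographic balance checks

Before any comparison the two groups are tested for balance on age
(two-sample t-test, pooled variance by default, Welch by flag) and sex
(chi-squared on the 2×2 sex-by-group table, Yates correction off by
default, flag available). Education years are reported descriptively
only, as cohort definitions of this kind control education upstream. A
comparison in which balance fails is reported, not blocked — the checks
are diagnostics, not gates.

## The synthetic cohort generator

The generator emulates a four-group (control plus three severity grades),
36-subjects-per-group, 20-module study design at the SC-matrix level; no
imaging, tractography or registration artifacts are simulated.

* **Template.** Per-edge expected counts are drawn once per cohort from a
  log-normal law with mean `edge_mean` (default 50) and log-scale spread
  `log_sigma` (default 0.5), then symmetrised. The spread produces a
  right-skewed edge-weight distribution while keeping module-pair means
  within roughly an order of magnitude of one another, as expected when a
  20-module parcellation aggregates a few thousand underlying regions.
* **Subject noise.** Counts are negative-binomial around the template
  with overdispersion α (default 0.1; variance μ + αμ², i.e. an
  inter-subject CV of ≈ 33% on strong edges), drawn on the upper triangle
  and mirrored so every matrix is exactly symmetric. α = 0 gives Poisson
  counts, retained for tests. The α and log_sigma defaults were fixed by
  a design-stage power analysis so that halving half of a module's
  connections constitutes a strong, reliably detectable effect at n ≈ 20
  per group — the regime the package's simulation studies treat as
  "strong".
* **Effects.** A group effect multiplies the expected counts on edges
  {target module} × {affected partners} by `multiplier`. The partner set
  must be a *proper* subset of the target's row (default: the
  lower-indexed half): because Pearson correlation is scale-invariant,
  attenuating the whole row uniformly would leave the profile's shape
  unchanged and be undetectable by construction. An edge effect leaks, by
  symmetry of SC, one affected entry into each partner module's profile;
  the target, with half its profile affected, carries a much larger
  signal and is the expected top-ranked module.
* **Heterogeneity.** `heterogeneity_sd` adds per-subject, *per-edge*
  log-normal factors (mean 1) on the affected edges: each affected
  subject deviates on their own set of connections. This raises
  within-group dispersion (the homogeneity diagnostic below) without
  moving the group mean pattern. By contrast, a shared attenuation
  *lowers* a group's within-group dispersion, since the altered pattern
  is common to all its subjects — the two mechanisms are deliberately
  separate knobs.
* **Demographics.** Ages are drawn from the same normal law (default
  75 ± 5 years) for every group; each group receives the same female
  fraction (default 0.5) by construction; education years are clipped
  normal (16 ± 2). Balance therefore holds by design, and no age or sex
  effect on connectivity is simulated — the QC battery should reject at
  its nominal rate only.

### Severity ladder

`severity_ladder` builds the stage-wise design: one four-group cohort in
which pathological group k receives the base effect with multiplier m_k
(deviations |1 − m_k| non-decreasing), the most severe group additionally
receives the same attenuation on two extra modules, and subject-level
heterogeneity scales with each stage's deviation — so a multiplier-1
stage is an *exact* null, not merely an approximate one. The three
two-group datasets share the identical control subjects, as in a
stage-wise case-control design.

## Within-group homogeneity diagnostic

For a chosen module, `within_group_ss_diagnostic` reports per group the
sum of squared distances over unordered within-group pairs (optionally
divided by group size, the SS_W weighting; both are emitted by the
pipeline since either normalisation is defensible). It quantifies how
alike a group's connectivity profiles are: under a planted heterogeneity
gradient the control arm attains the smallest value, and a group can be
*more* homogeneous than control under strong shared attenuation — the
diagnostic separates these two effect mechanisms.

## What the simulations do and do not show

Passing the simulation studies demonstrates that the statistic is
correctly computed (exact oracles), calibrated under the generator's null
(type-I rate ≈ α, uniform p-values), and powerful against the generator's
alternatives (planted-module recovery, severity monotonicity). The
generator draws independent negative-binomial edges around a shared
template; real streamline-count connectomes have correlated edge noise,
registration- and tractography-induced artifacts, site effects and
demographic confounds, none of which are simulated. Results on synthetic
cohorts therefore validate the machinery, not the biology of any real
dataset.

## Numerical choices

* Correlations are clipped to [−1, 1] and chord arguments to [0, 4]
  before the square root; distance matrices are symmetrised and their
  diagonals zeroed explicitly.
* The permutation batch computes SS_W for all label vectors via a
  group-indicator einsum — O(n_perm · N²) per group — making 10⁴
  permutations on N ≤ 144 a sub-second operation per module.
* SS_B is computed as SS_T − SS_W, so the decomposition identity is exact
  by construction; the Gower-trace formulation is used as an independent
  cross-check in tests, not in the computation path.
* Self-loop streamlines are recorded on the SC diagonal and the diagonal
  is excluded from every profile, so the self-loop convention cannot
  affect any downstream statistic.
* Module indices are 1-based in all files, reports and public APIs.

## Known limitations

* Only categorical one-factor designs: no continuous covariates
  (e.g. age as a regressor), no multi-factor or stratified permutation
  schemes.
* PERMANOVA-type statistics confound location and dispersion differences:
  a group with inflated within-group dispersion alone can modulate the
  pseudo-F. The homogeneity diagnostic is provided precisely to separate
  the two readings.
* The permutation floor 1/(1 + n_perm) bounds attainable significance;
  comparisons needing very small p-values need proportionally more
  permutations.
* Balance checks cover age and sex only, mirroring the intended study
  design; other confounds are out of scope.
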
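# Methods

## The analysis problem

A balanced multi-environment trial evaluates g genotypes under an optimal
condition and one or more stress conditions (drought, heat) across several
seasons, in randomized complete blocks with r replicates. The absolute
trait values do not express tolerance; the analysis therefore works on
per-replicate tolerance indices, the ratio of a trait's value under stress
to its value under the optimal condition of the same season and block.
Every (stress condition, season) pair becomes one derived *index
environment*; a drought+heat, three-season design yields six (E1…E6,
season-major, drought before heat). The index is formed per replicate,
pairing stress block k with optimal block k, which preserves a
replicate-within-environment stratum in the joint ANOVA: with e = 6 index
environments and r = 3 that stratum has e(r − 1) = 12 degrees of freedom.
Forming indices on genotype means instead would remove that stratum; the
per-replicate choice is the one consistent with the downstream ANOVA
layout and is the package default (there is no means-based option).

## Simulated trials

The generator plants, per trait,

y = (µ + g_i + r_k(j) + Σ_m λ_m u_im v_jm + ε) · f(group_i, condition)

with g_i ~ N(0, σ_g²), blocks r_k(j) ~ N(0, σ_b²), residual
ε ~ N(0, σ_ε²), and a bilinear interaction over the condition × season
cells whose score vectors u_m, v_m are drawn orthonormal inside the
sum-to-zero subspace — so the planted interaction's singular-value profile
equals the configured λ exactly, and AMMI recovery is checkable
axis-by-axis. The stress response is multiplicative: each genotype belongs
to a tolerance group with a per-condition factor f ≤ 1 (f = 1 under the
optimal condition), so the tolerance ratio has group-separated means by
construction, which is what the clustering and discriminant stages need a
ground truth for. Ratio-bound traits are truncated at 1e-6 (logged) rather
than resampled.

Default study-scale conditions (20 genotypes, 3 seasons,
optimal/drought/heat, 3 replicates, 20 traits): per-trait grand means
uniform on [5, 50] in arbitrary trait units, genotypic SD 8% of the mean,
residual SD 5%, block SD 2%, a rank-2 interaction with singular values
50% and 25% of the mean (per-cell interaction effects of roughly 4–5% of
the mean, comparable to the genotypic signal — the regime in which the
interaction axes carry most of the G×E sum of squares), and five tolerance
groups with drought/heat factors from 0.92/0.87 (highly tolerant) down to
0.60/0.52 (highly sensitive), i.e. stress reduces performance by 8–48%
depending on group and stress type. These are field-realistic magnitudes
for stress trials of this kind; they are fixed defaults, not fitted to any
particular dataset.

What the generator does *not* emulate: spatial field trends, weather
covariates, unbalanced or missing plots, trait-specific error
distributions, or genotype-level (within-group) variation in the stress
response. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to those features of
real data.

## Joint ANOVA, variance components, BLUP

The observation model is y_ijk = µ + G_i + E_j + R_k(j) + GE_ij + ε_ijk.
F-tests follow the fixed-genotype layout (GEN and GEN:ENV against the
pooled residual, ENV against REP(ENV)); variance components and everything
downstream of them treat genotypes as random. Both parameterizations are
deliberate: the hypothesis tests and the prediction machinery answer
different questions, and the package reports both.

Components come from the expected mean squares — σ²_ε = MS_res,
σ²_ge = (MS_GE − MS_res)/r, σ²_g = (MS_G − MS_GE)/(re) — with negative
solutions truncated at zero and flagged, so the heritability ratios stay in
[0, 1]. The REML option maximizes the restricted likelihood in its
balanced-design stratum form, Σ_s [df_s·log θ_s + SS_s/θ_s] over
non-negative components (Nelder–Mead on a scaled parameterization); on a
balanced design this coincides with the moment solution whenever that
solution is interior, which the test suite checks by simulation.

Genetic parameters: H² = σ²_g/σ²_p on a plot basis with
σ²_p = σ²_g + σ²_ge + σ²_ε; h²_mg = σ²_g/(σ²_g + σ²_ge/e + σ²_ε/(er)) on
the genotype-mean basis; accuracy √h²_mg; r_ge = σ²_ge/(σ²_ge + σ²_ε);
CV_g and CV_r as percent of the grand mean. Degenerate inputs (σ²_p = 0,
non-positive mean) set flags rather than raising.

BLUPs use the balanced closed form: the genotype effect shrinks the
centered genotype mean by h²_mg, each interaction cell shrinks the
double-centered cell mean by σ²_ge/(σ²_ge + σ²_ε/r). In the noise-free
limit both factors are 1 and the BLUP matrix equals the centered table
exactly; with no genetic signal the effects shrink to zero. A general
mixed-model solver is unnecessary for the balanced designs this package
accepts and is not attempted; unbalanced data are rejected at validation.

## AMMI

The genotype × environment means table is double-centered and factorized
by SVD. Scores are symmetric-scaled (both sides carry √λ_k, so each side's
per-axis sum of squares equals λ_k), axes ordered by descending singular
value, and the sign of each axis fixed by making the largest-magnitude
environment loading positive. Per-axis explained proportion is
λ_k²/Σλ², the multiplicative-term ANOVA uses Gollob degrees of freedom
g + e − 1 − 2k with SS r·λ_k² tested against the replicate-level residual
mean square, and AMMI(n) prediction adds the first n bilinear terms to the
additive fit (n at full rank reproduces the observed means to machine
precision). Biplot output includes pairwise environment vector angles;
angles above 90° read as negative association between environments.

## WAASB, WAASBY, quadrants

WAASB_i = Σ_k |score_ik|·EP_k / Σ_k EP_k over the included axes (all axes
by default — the stability ranking then uses every part of the interaction,
not just axis 1), computed identically for genotypes and environments;
lower is more stable. The default decomposition input is the BLUP-shrunken
interaction matrix; a fixed-effects option decomposes the raw centered
means, and on clean balanced data the two rankings agree closely (tested).
WAASBY rescales mean performance and stability to [0, 100] (performance
direction set by the trait's sense; stability reversed so stable = 100)
and averages them with weights θ_Y/θ_S, default 50/50. Quadrant
classification cuts the performance × WAASB plane at the grand mean of
each coordinate by default; both cuts are explicit parameters because
published figures of this kind do not always state their cutpoints, and
items exactly on a cut go to the lower quadrant with a flag. Ranks break
ties by label order, deterministically.

## MGIDI

Each trait's genotype means (BLUP-based means by default) are linearly
mapped to [0, 100] with 100 the desired direction — 'decrease' traits use
the reversed map, so orientation is handled here and nowhere else.
Factor analysis runs on the trait correlation matrix: retain eigenvalues
strictly greater than 1 (Kaiser), loadings = eigenvectors × √eigenvalue,
varimax rotation with Kaiser normalization (tolerance 1e-6, up to 1000
sweeps), factor scores by the regression method F = Z R⁻¹ A (a 1e-8 ridge
is added to a numerically singular R, logged). The ideotype is the all-100
row projected through the same score equation; MGIDI_i is the Euclidean
distance of genotype i to it in factor space, the selected set is the
round(α·g) closest (α = 0.20 by default, minimum 1), and per-factor
contribution shares decompose each squared distance. Because the rotation
is orthogonal and scores are recomputed consistently, distances are
rotation-invariant, and the [0, 100] map absorbs any affine rescaling of
the raw traits — both properties are tested. Selection gains report
X_o, X_s, the differential and SG% = 100·(X_s − X_o)·h²_mg/X_o per trait
(mean-basis heritability, stated in the output), with desired-direction
flags and separate totals for increase- and decrease-sense traits.

## Stepwise regression

Forward selection with backward elimination on p-values (enter 0.05,
remove 0.10 — conventional defaults, configurable): each step admits the
candidate with the smallest partial-F p-value below the entry threshold,
then drops any member whose p-value exceeds the stay threshold. Partial R²
values are the R² increments along the final entry order, so they sum to
the total R². The default regression pools the genotype × environment mean
rows; a means-level report applies the fitted equation per genotype with
error, relative error and accuracy 100·(1 − |relative error|).
`prediction_diagnostics` exposes the diagnostics as a pure function of
(observed, predicted), which is also how the worked-example table's
printed diagnostic columns are reproduced; an optional rounding of
predictions mirrors that table's 3-decimal display convention.

## Clustering and LDA

Trait columns are z-scored (sample SD), clustered with Ward linkage on
Euclidean distances (heights on the distance scale, the Ward.D2-style
convention common to both major ecosystems), and cut at k = 5 groups named
HT/T/M/S/HS by descending cluster-mean yield index. The exported heatmap
matrix clips z-scores at ±3 for display only; computation always uses the
unclipped values.

The discriminant model is the equal-covariance Gaussian classifier:
posterior ∝ prior · exp(−½·Mahalanobis²) with the pooled within-group
covariance (divisor n − G). When there are more predictors than residual
degrees of freedom — the 20-predictor, 20-genotype, 5-group configuration
is exactly this case — the covariance is singular and a Moore–Penrose
pseudo-inverse is used, with a log notice; this is the package's
documented choice for that regime. Priors are group-frequency proportional
by default with an equal-priors switch. Leave-one-out cross-validation
refits the model excluding each observation in turn (exact refits, no
shortcut formula), flagging folds in which a singleton group vanishes.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng` seeded from the
  configuration; pipeline manifests record SHA-256 checksums of every
  output, and equal seeds reproduce equal checksums.
- CSV round-trips use pandas' exact (`round_trip`) float parsing so a
  written dataset reloads bit-identically.
- Rank ties (WAASB, WAASBY, MGIDI) break by label order via stable sorts.
- Balance is enforced, not patched: missing cells raise errors listing the
  offending cells.
- The test suite's simulation sizes (e.g. g = 50, e = 6, r = 3 with
  50–100 seeds for recovery checks; 200 small-trial replicates for null
  calibrations) were chosen to bound Monte-Carlo error well inside the
  asserted tolerances while keeping the default run short.

## Known limitations

- Only fully balanced designs are supported; no missing-plot imputation.
- The BLUP machinery relies on the balanced closed form; genuinely
  unbalanced mixed-model fits are out of scope.
- Factor retention offers the Kaiser rule only (no parallel analysis), and
  rotation is varimax only.
- The LDA worked-example comparison depends on the granularity of the
  published inputs: a discriminant model fitted to genotype *means* is not
  the same model as one fitted to unprinted replicate-level rows, and the
  package reproduces only what its inputs determine.
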
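# Methods

## Data model

A balanced multi-environment trial observes `g` genotypes in `e`
environments with `r` replicates. The long format (one row per plot) is
canonical; analyses consume the `g x e` table of cell means. Missing values
are never imputed: an unbalanced layout is a hard error for ANOVA and the
GGE engine, because all closed-form identities used here (definitional sums
of squares, expected mean squares, exact SVD reconstruction) assume
balance. Labels are whitespace-trimmed on load and compared
case-sensitively.

## ANOVA and variance components

Sums of squares are definitional for the balanced two-way layout, and the
identity `SS_E + SS_G + SS_GE + SS_err = SS_total` is asserted in tests at
1e-9 relative. Expected mean squares under the random model are
`E[MS_err] = var_err`, `E[MS_GE] = var_err + r var_ge`,
`E[MS_G] = var_err + r var_ge + e r var_g`, giving the method-of-moments
estimators; negative estimates are truncated to zero and flagged, the
standard practice for moment estimators. REML and incomplete-block
(alpha-lattice) recovery are out of scope: the package analyses the trial
as a balanced two-way layout with replicates.

Percent contribution is the **mean-square share**
`100 MS_s / (MS_E + MS_G + MS_GE)`. This is deliberately not the more
common sum-of-squares share: the reference trial's published table is an
MS-share (all nine printed percentages reproduce exactly under it, none
under the SS-share), so the MS-share is the default and `basis="ss"` is
provided for the conventional alternative.

## Genetic parameters

Given a genotypic variance `var_g`, a broad-sense heritability `h2` and the
trait mean, the phenotypic variance is defined as `var_p = var_g / h2`.
Defining `var_p` through `h2` (rather than recomputing it from ANOVA error
terms) keeps GCV, PCV, `h2` and GA mutually consistent, which is how the
reference trial's parameter table is constructed; the ANOVA-based
genotype-mean heritability `var_g / (var_g + var_ge/e + var_err/(e r))` is
offered separately (`heritability_from_anova`). Genetic advance uses
selection intensity `k = 2.06`, the standardized selection differential at
a 5% selected fraction; `k` is an argument, not a constant. The reference
dataset's footer genotypic variance for maturity (0.92) cannot be the
method-of-moments estimate from its own mean squares (which is negative);
the package therefore reports both the MoM estimate and the variance of
genotype means, and asserts neither against the footer.

## Selection index

The base linear phenotypic selection index is `I = sum_t w_t y_t` with
caller-supplied economic weights (default: unit weights on raw scales).
The published per-genotype index in the bundled data follows no stated
weighting — no linear combination of the three printed trait means
reproduces it — so it is carried as data, never recomputed. Standardized
(z-scored) weighting is available; sign conventions (negative weight on
maturity for earliness) are the caller's.

## GGE engine

The two-way table is environment-centered (column means removed, no
scaling) and decomposed by SVD. Genotype-focused partitioning assigns
scores `U Λ` to genotypes and `V` to environments; environment-focused is
the transpose convention. Variance explained per axis is
`λ_n² / Σ λ²`, independent of the partitioning. All biplot-derived views
use two retained axes; full-rank scores are available for diagnostics and
reconstruct the centered table exactly (tested at 1e-10).

Numerical conventions:

* **Axis signs.** Each environment-loading column is flipped so its sum is
  ≥ 0 (ties: first nonzero loading positive), removing the SVD's sign
  ambiguity between runs.
* **AEC frame.** The abscissa is the normalized mean of environment
  scores; a zero mean vector is a degenerate-frame error. The ordinate is
  the +90° rotation, so stability is signed.
* **Which-won-where.** Vertices of the convex hull of genotype points
  (scipy's qhull, counter-clockwise); the boundary ray between adjacent
  vertices is the outward normal of their edge, i.e. the direction on
  which the two vertices' inner products tie. Because the centered rows
  sum to zero, the origin is the centroid of genotype points and lies
  inside the hull, so the sectors tile the plane. An environment direction
  exactly on a ray (tolerance 1e-12 rad) is assigned to the
  counter-clockwise sector and flagged; an environment at the origin is
  unassigned and flagged. The sector winner equals the inner-product
  argmax over all genotypes — the central correctness property, tested
  against the brute-force oracle on random instances.
* **Environment evaluation.** Discrimination = vector length,
  representativeness = cosine with the abscissa, desirability = their
  product (the projection onto the AEC axis). The projection rule is the
  standard combination in the biplot literature; the reference trial's
  printed desirability column is not recoverable from its own printed
  length/cosine columns, so no desirability value is asserted against it.
* **Ward clustering** uses scipy's linkage on (by default z-scored)
  features; merge heights are verified in tests against a from-scratch
  greedy Ward implementation.

## Simulator

`Y_ijr = mu + G_i + E_j + GE_ij + eps_ijr` with i.i.d. normal effects, not
sum-to-zero constrained (a `sum_to_zero` flag exists for exact small-sample
checks) — estimators must tolerate sampling deviation of the realized
effects. Defaults are the reference trial's conditions on the seed-yield
scale: `g=64, e=4, r=2, mu=1233.74`, `var_g=16,500` and `var_ge=95,000`
(the trial's reported genotypic and GxE variances), `var_e=270,000` (the
variance of the four reported location means) and `var_err=28,000` (implied
by the reported residual CV of 13.56% of the mean). With
`crossover=CrossoverSpec(n_groups=k)`, the interaction is the rank-1
product of standard-normal genotype loadings and alternating group signs,
rescaled so the mean square of the interaction matrix equals `var_ge`;
the centered table is then rank ≤ 2 by construction, the two-axis biplot is
exact, and the planted partition is the ground truth for which-won-where.
The generator emulates additive, normally distributed effects on a balanced
layout; it does not emulate incomplete-block structure, spatial trend,
non-normal errors or multi-trait genetic correlation, so passing recovery
tests demonstrate correctness of the estimators under the additive model,
not robustness to those realities.

## Validation harness

The six metrics are implemented directly from their definitions; RMSE is
the square root of the mean squared error, and MSLE uses the natural
logarithm of `1 + y` (both choices match the magnitudes reported for the
reference trial). Domain failures (MAPE with a zero observation, MSLE with
values ≤ −1, R² with zero-variance observations) yield NaN for that metric
only, with a flag. LOO-CV refits the learner `n` times; it is exact, not
approximated. Grid search is exhaustive with a declared selection metric
(maximize R², minimize the rest) and first-occurrence tie-breaking in grid
order. Feature construction defaults to one-hot genotype + environment
indicators — an explicit harness choice, since no canonical feature set
exists for trait prediction from trial structure alone. Learners are
scikit-learn's `RandomForestRegressor` and `MLPRegressor` with the seed
propagated; the harness and metrics, not the learners, are the tested
surface.

## Problem sizes

Monte-Carlo checks use 200 replicates of the 64 x 4 x 2 layout for
variance-component recovery (bias bounded by three Monte-Carlo standard
errors; truncation bias at these settings is ~70 units against a 3·SE band
of ~1,800, hence negligible), 100 random 10 x 4 instances for the
which-won-where oracle equivalence, 20 planted-crossover trials for
mega-environment recovery, and 1,000 random vector pairs for metric
agreement. These sizes make each check's sampling error small relative to
its assertion band while keeping the full suite fast.

## Known limitations

* Only balanced data are analysed; the alpha-lattice design the reference
  trial was laid out in is deliberately collapsed to the two-way layout.
* The exact two-way genotype x environment table behind the reference
  trial's biplot was not published, so biplot outputs are validated by
  construction (oracles and planted truth), not against the trial's
  printed biplot statistics.
* The LSD yardstick is reported but carries no multiplicity correction.
* `append_index_trait` standardization operates on plot-level records; for
  genotype-mean standardization compute the index on the mean table.
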
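# Methods

## The problem

Biomedical experiments are usually nested: images within wells, wells within
animals, trials within subjects.  Observations that share a cluster share its
random errors, so treating them as independent samples ("pseudoreplication")
inflates false-positive rates, while collapsing each cluster to a single
summary number discards the information in the within-cluster spread.
`nestperm` implements a hierarchical randomization test that uses every level
of the design: treatment labels are permuted only at the level where
treatment was actually randomized, and the uncertainty in each treated
entity's mean is represented by hierarchically bootstrapping its nested
observations.

## Design inference from column order

A dataset is a long-format table whose label columns run from the outermost
level of the hierarchy to the innermost, with the numeric response in the
final column.  Given the (user-supplied) index `t` of the treatment column:

* columns `1 .. t-1` are **blocks**: label permutation is restricted to
  within each joint block label (labels are only exchangeable where
  randomization happened);
* column `t+1` identifies the **treated entities** — the clusters that
  carry the treatment labels (if the treatment column is the innermost
  level, the rows themselves are the entities);
* columns below the treated-entity level are **bootstrap levels**, resampled
  with replacement within their parent clusters.

Crossed factors on the same level are handled by concatenating all factors
except the one under study into a composite column and nesting the factor of
interest inside it (`rearrange_crossed`).  A random (per-block) treatment
effect — an interaction — is declared by duplicating the treatment column;
it is auto-detected when the column following the treatment column adds
nothing to the unique-row partition, and it restricts permutation to
exchanging whole treatment groups within each block, collapsing e.g.
20³ = 8000 arrangements to 2³ = 8.  The auto-detection rule is structural
and therefore ambiguous for designs with exactly one treated entity per
(block × treatment) cell; the `interaction` argument overrides it in either
direction.

Unbalanced designs (unequal cluster sizes or clusters per block) are
accepted throughout; permutation counting uses the multinomial coefficient
of each block's actual label multiset and the bootstrap preserves each
cluster's own child count.  Labels are compared case-sensitively after
whitespace trimming, and rows are stably sorted by the level columns (in
first-appearance code order, so `"10"` does not sort before `"2"`) before
encoding.

## The test

1. Aggregate (by averaging) to one response per treated entity and compute
   the observed statistic.
2. For each bootstrap replicate: resample children with replacement, to the
   original count, within every cluster at every bootstrap level
   (outermost first); re-aggregate; and compute the statistic under each
   within-block label permutation (the full distinct set when it is
   enumerable, otherwise uniform draws with replacement — a fresh draw per
   replicate).
3. The two-tailed p-value is the fraction of the resampled statistics whose
   absolute value is at least the absolute observed statistic.  Ties count
   as extreme; the observed statistic is *not* added to the null set (a
   `plus_one` flag provides the conservative (b+1)/(N+1) variant).

When the design has no bootstrap level (one observation per entity) the
procedure degrades to an ordinary block-restricted permutation test.  When
every resample space is enumerable (`bootstraps="all"`,
`permutations="all"`), the test is exact and reproduces brute-force
enumeration bit-for-bit — this is tested.

The smallest two-tailed level the design can resolve is `2 / (number of
distinct label arrangements)`: 0.1 for 3 vs 3 entities, 2/70 ≈ 0.029 for
4 vs 4.  Requests for finer tails (in `confidence_interval`) are refused
with the best achievable level in the message.

## Test statistics

Both statistics are approximately pivotal (estimate divided by estimated
standard error), which gives the randomization test asymptotic validity
under unequal variances between groups.

**Welch t** on entity means: `t = (B̄ − Ā) / sqrt(s²_B/n_B + s²_A/n_A)`.

**Studentized covariance** for multi-group or regression-style nulls.  With
treatment codes `x` (integer dose order 0, 1, 2, … by first appearance, or
user-supplied numerics) and entity means `y`, the slope is
`β̂ = Cov(x, y)/Var(x)`; because `Var(x)` is constant under permutation the
pivot is built on the sample covariance `Q = n·μ₁₁/(n−1)` alone:
`T = Q / sqrt(S²(Q))`, where `S²(Q)` is a bias-corrected approximation to
the variance of `Q` built from the product central moments
`μ_{r,t} = mean((x−x̄)^r (y−ȳ)^t)`:

    S²(Q) = 1/(n−3/2) · [ −n²(n−2)μ₁₁² / ((n−1)(n−7/4)²)
                          + n²μ₀₂μ₂₀ / (n−1)³
                          + n·μ₂₂ / (n−2) ]

The exact unbiased estimator of Var(Q) is numerically unstable and is not
used.  `S²(Q)` is itself only approximately unbiased: under
bivariate-normal independence its expectation exceeds the truth by ≈ +9% at
n = 8, shrinking roughly like 1/n (the plug-in population formula
underestimates by ≈ 30% at the same n).  This residual scale inflation is
shared by every permuted statistic and therefore washes out of the p-value
comparison; the calibration is verified by a Monte-Carlo test.  Negative
values of `S²(Q)` (possible for extreme small-n inputs) are clipped to
zero, signalling an unusable denominator.  `S²(Q)` requires n ≥ 4 entities;
smaller two-group designs should use the t statistic.

On balanced two-group data `T` is a strictly monotone function of `t`
across any permutation set, so the two statistics give *identical*
p-values on a shared resample stream — implemented so the tie counting is
exact (both groups reduced through identical matmul kernels, making a full
label swap negate the statistic bit-for-bit) and verified by test.

## Confidence intervals by test inversion

A candidate effect `b` lies outside the `level` interval when the test of
H0: β = b rejects.  The test at `b` is run on the shifted response
`y − b·x` (x the per-observation treatment code); its rejection boundary is
the root of the continuous margin `|T_obs(b)| − q(b)`, where `q(b)` is the
interpolated `level` quantile of the absolute resampled statistics under
the shift.  Each bound is located by bisection from a starting bracket of
`β̂ ± 4·se` (doubled outward if it does not bracket), with at most 10
resampling rounds per bound, each round spending one full permutation ×
bootstrap set (1,000–10,000 shuffles at the defaults).  The resample
stream is frozen per bound, making the margin a deterministic function of
`b`, the interval reproducible, and wider levels nest narrower ones.  The
returned bounds are already in β units — the quantile construction
unstudentizes through `se(β̂)` implicitly.

## The synthetic data generator

Two additive models generate validation data:

* three-level: `y = β·treat + cluster + individual`
  (table `Treatment, Cluster, Obs, y`; treatment level 1);
* four-level: `y = block + β·treat + cluster + individual`
  (table `Block, Treatment, Cluster, Obs, y`; treatment level 2).

Random terms come from `normal`, `lognormal` (σ = 0.75), `pareto`
(shape 3), or `gamma` (shape 2) families, each centered and scaled to unit
variance using its analytic moments, so `β` is the only systematic group
difference even for skewed families and the variance decomposition is
exact.  The default non-normal parameters were chosen to give marked skew
(lognormal skewness ≈ 2.9; gamma ≈ 1.4) with finite variance (Pareto shape
must exceed 2 for the intraclass correlation to be defined).

Parameters that matter:

* `icc` (default 0.5): the conventional intraclass correlation — the share
  of the per-observation noise variance (`total_variance`, default 1)
  carried by the cluster baseline.  Cluster SD = `sqrt(icc·σ²)`, individual
  SD = `sqrt((1−icc)·σ²)`.
* `variance_ratio` (default 1): total-noise variance of the last treatment
  group relative to the first (e.g. 1.5 reproduces a 1:1.5 heteroscedastic
  comparison), interpolated linearly across groups.
* `block_variance` (default 1): variance of the block baseline in the
  four-level model.  It cancels from within-block permutations, so it
  stresses the comparators rather than the hierarchical test.
* `beta`, `n_treatment_groups` (2–4, coded 0,1,2,… for the covariance
  statistic), `clusters_per_group`, `obs_per_cluster`, `n_blocks`.

What the generator does *not* emulate: non-additive (multiplicative or
interaction) effects, heavy-tailed families without a variance,
within-cluster correlation structure beyond a shared baseline, missingness,
or measurement error.  Passing simulations therefore demonstrate
calibration under exchangeable additive noise — the regime the method's
assumptions describe — not robustness to arbitrary real-data pathologies.

## Simulation studies and problem sizes

`type_i_error_study` draws null datasets (β = 0), runs the full test on
each, and reports the rejection fraction at α with a Wilson interval and
the 95% binomial band around the nominal rate; closed-form Student, Welch,
and (for blocked designs) paired t tests on cluster means run alongside.
`coverage_study` does the same for the fraction of inverted-test intervals
containing the true β.  External p-value vectors (e.g. from a mixed model
fit elsewhere) can be tabulated side by side; those comparators are not
reimplemented here.

The package's own validation runs at desk scale: 2,000 null datasets per
distribution family for Type I error (two groups × 4 clusters × 3
observations, 50–100 bootstraps × all 70 permutations per test) and 1,000
datasets for coverage (same design, β = 1, 95% intervals).  At these sizes
the 95% binomial band around α = 0.05 is ±0.0096 and around 95% coverage
±1.35 points.

## Numerical choices

* Tie rule: `>=` on absolute values, observed excluded from the null.
* Batch statistic kernels return 0 for degenerate (zero-variance)
  permutations and ±inf when `S²(Q)` underflows with Q ≠ 0; the scalar API
  raises instead, and a constant response short-circuits to p = 1 with a
  warning.
* Exhaustive permutation enumeration is capped (default 100,000
  arrangements; error advises sampling), bootstrap enumeration at 20,000.
* One root seed drives everything; per-dataset and per-bound child streams
  are derived deterministically (`SeedSequence` spawning), so identical
  inputs give bit-identical results.
* Sampled permutations are independent uniform draws with replacement from
  the distinct arrangement set (not a without-replacement subset), matching
  Monte-Carlo p-value theory.
* The bootstrap is classic multinomial (equal-probability) resampling; the
  first replicate is not forced to the identity.

## Known limitations

* The test assumes the treated entities were randomized within blocks
  (exchangeability at the treatment level) and that bootstrap levels are
  random samples of their clusters — levels that were measured
  exhaustively (every cell in a field of view) should be excluded via
  `skip_levels`.
* With very few clusters and strong heteroscedasticity or skew the test
  can be mildly liberal; the pivotal statistics give asymptotic, not
  finite-sample, protection.
* Interaction designs sharply limit resolution (2/2³ = 0.25 for three
  blocks of two groups), so only coarse confidence levels are available.
* p-values are two-tailed only; no multiple-comparison machinery is
  included.
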
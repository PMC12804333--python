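# Methods

## Model and scope

We observe `k ≥ 2` independent groups of right-censored survival times:
`X_ji = min(T_ji, C_ji)`, `δ_ji = I(X_ji = T_ji)`, with `T_ji ~ F_j` and
`C_ji ~ G_j` continuous and mutually independent. Group differences are
expressed through cumulative hazards `A_j`; the local null for a pair
`(j1, j2)` is `A_j1 ≡ A_j2`, equivalent to equality of the survival
distributions. Only pairwise (±1) contrast rows are supported; the
`ContrastSet` type accepts general zero-sum rows but every procedure
rejects non-pairwise rows with an explicit error. Left truncation,
interval censoring, and covariate adjustment are out of scope.

**Tie handling.** The model assumes continuous laws, so tied times are a
finite-precision artifact. At a tied time, events are counted before
censored subjects leave the risk set: `Y_j(t) = #{X_ji ≥ t}`,
`dN_j(t) = #{X_ji = t, δ_ji = 1}`, and `dN_j(t)` may exceed one.

**Integration domain.** All `∫₀^∞` expressions are finite sums over the
sorted unique event times of the relevant (pairwise or all-group) sample;
grid points where a required risk set is empty contribute zero via the
`I{Y > 0}` guard. Left limits `F̂(t−)` are the estimate at the largest grid
point strictly below `t`, and 0 before the first event.

Group labels are arbitrary hashables, mapped internally to consecutive
codes in first-appearance order and reported back in original labels.

## Weight functions

Weights are continuous, bounded-variation functions on `[0, 1]`, evaluated
at the left limit of the pooled Kaplan–Meier CDF. Built-ins: the
Fleming–Harrington family `t^r (1−t)^g` (log-rank at `r = g = 0`; late
differences for `r > 0`, early for `g > 0`) and the crossing weight
`1 − 2t`, which changes sign at the pooled median and targets crossing
hazards. Every multi-weight procedure defaults to the pair
`{1, 1 − 2t}`, a combination known to be robust across proportional,
late-effect and crossing alternatives; additional weights can be attached,
and `check_linear_independence` verifies the set is not numerically
degenerate. User-supplied weight evaluators are not validated for bounded
variation — that is the caller's responsibility.

## The four procedures

**Adjusted log-rank.** Per pair, `T(w)²/Σ̂` is referred to `χ²₁`; local
rejection at `p < α/q`. The default weight is `w ≡ 1`; with `q = 1` the
procedure is the plain two-sample log-rank test. The estimator `Σ̂` uses
the pair-pooled Nelson–Aalen increment, which coincides with the classical
hypergeometric (O−E) variance when no event times are tied.

**Adjusted mdir.** Per pair, the studentized quadratic form
`Z = T' Σ̂⁻ T` over the m weights, with `Σ̂⁻` the Moore–Penrose inverse.
Although `Z` is asymptotically `χ²_m`, that calibration is anti-conservative
in finite samples, so the default is a permutation test: labels are
reshuffled *within the two compared groups* (pairwise exchangeability under
the local null), `Z` recomputed for each of `B` permutations, and the
add-one p-value `(1 + #{Z* ≥ Z}) / (B + 1)` compared to `α/q`. The χ²
path is retained for reference (`mdir_chi2_pvalue`). When
`1/(B+1) ≥ α/q` the procedure warns (not errors): no rejection is then
possible, but descriptive p-values may still be wanted.

**MultiWeightedLR.** All m·q statistics are kept as separate coordinates
of an asymptotically centered Gaussian vector. Because the raw `T(w)` are
not unit-variance, each coordinate is studentized by the square root of its
estimated variance before the maximum is taken — the standard
multiple-contrast-test construction; this studentization is an
interpretation choice documented here, as is the use of the induced
correlation matrix for the critical value. Local statistics are per-pair
maxima over weights; the shared critical value is the equicoordinate
`(1−α)`-quantile of `N(0, R)`. Adjusted p-values are
`1 − P(max_i |Z_i| ≤ observed)` under the same fitted Gaussian.

*Joint covariance.* Diagonal m×m blocks are the pairwise `Σ̂` above.
Cross-contrast blocks use a martingale plug-in: each statistic decomposes
into per-group integrals `Σ_j ε(j) ∫ H dÂ_j` with
`H_{a,p}(t) = √(n_a/(n_j1 n_j2)) w_p(F̂_a(t−)) Y_j1 Y_j2/(Y_j1+Y_j2)`, and
the covariance contributed by a shared group j is estimated by
`ε_a(j) ε_b(j) Σ_t H_{a,p}(t) H_{b,s}(t) dN_j(t)/Y_j(t)²`. Blocks for
disjoint pairs are exactly zero. The plug-in is validated in the test
suite against the empirical covariance of the statistic vector over 5,000
null replications (agreement within 3 Monte-Carlo SD entrywise).

**multiCASANOVA.** The contrast statistic pools the CDF and the at-risk
process over *all* k groups (`T̃`, `Ĉov` with `Y(t)` total at-risk and
pooled Nelson–Aalen increment `dÂ`); per contrast the Wald form
`C = T̃' Ĉov⁻ T̃`, globally `C_max = max_a C_a` (no maximum over weights —
they are already combined inside each quadratic form). At `k = 2` the
statistic reduces bitwise to the pairwise mdir quantities. Calibration is
the wild bootstrap for counting processes: i.i.d. multipliers `G_ji` with
mean 0, variance 1 — Rademacher by default, centered Poisson(1) by flag;
both are discrete, matching the discreteness of counting processes — give
`Â*_j(t) = Σ_{s≤t} (Σ_{i: X_ji=s, δ=1} G_ji)/Y_j(s)`. Bootstrap statistics
replace `Â_j2 − Â_j1` by `Â*_j2 − Â*_j1` while `Ĉov` stays fixed at its
data value. One multiplier per subject is drawn per replication and shared
across contrasts, preserving their joint dependence. The critical value
`q*` is the empirical `(1−α)`-quantile — order statistic
`⌈(1−α)B⌉`, a conservative and reproducible rule — of the `C*_max` sample;
both global (`C_max > q*`) and all local (`C_a > q*`) decisions use this
single shared quantile. Reported p-values are add-one bootstrap tail
fractions, descriptive companions to the quantile rule.

## Numerical choices

- **Pseudo-inverse rank cutoff:** singular values below
  `m · √ε_machine · s_max` are treated as zero, making quadratic forms on
  singular covariance estimates reproducible (e.g. the two-subject toy
  dataset, where the two default weights coincide on the grid).
- **Gaussian rectangle probabilities:** `scipy`'s randomized-lattice
  integrator with a fixed seed (deterministic), an absolute tolerance of
  2·10⁻⁴ and a point budget of `min(20000·d, 200000)`. The quantile is
  found by bisection to 10⁻³ inside the Bonferroni sandwich bracket
  `[z_{1−α/2}, z_{1−α/(2d)}]`, which also certifies the result's range.
  Dimension 1 uses the exact normal quantile.
- **PSD repair:** the plug-in correlation matrix need not be jointly
  positive semidefinite in finite samples; negative eigenvalues are
  clipped at zero and the diagonal rescaled to one.
- **Degenerate inputs:** pairs with no events yield zero statistics and
  p-value 1 (never a rejection); in the maximum test such zero-variance
  coordinates are dropped with a warning. Groups of size 1 are accepted
  and exercise the same guards.
- **Seeding:** every resampling procedure consumes a user seed; multi-
  contrast permutation runs spawn one independent stream per pair from the
  master seed, and the simulation harness spawns one stream per run and
  method, so all results are reproducible and order-independent.

## Synthetic-data generator

`survmctp.simulate` draws the four-group settings used throughout:
proportional hazards (Exponential rates 1.2/1.8/2.3/2.9), non-proportional
non-crossing (Lognormal), crossing (Weibull shapes 1.5–4.5, common scale
5), a mixed setting, and the global null (all groups Exponential(1.2)).
Parameter conventions: Exponential(rate), Lognormal(mean, sd of log time),
Weibull(shape, scale) — stated explicitly because the names alone do not
fix the parameter roles. Default group size is 100. Censoring is uniform
on `(0, u)` with `u` calibrated per group law by root finding so that
`P(C < T)` equals the target (0–30%); for an Exponential(λ) group this
solves `(1 − e^{−λu})/(λu) = target`, and the realized censoring fraction
is verified empirically in the tests. The generator emulates the
randomized-trial setting the procedures target: independent arms, a common
censoring mechanism, smooth parametric hazards. It does not emulate
covariate-dependent censoring, dependent arms, discrete/rounded recorded
times at scale, or left truncation — so passing tests certify the
procedures' calibration under the stated sampling model, not robustness to
those violations.

The harness (`run_study`) derives per-contrast truth from the scenario
(a contrast is null iff both groups carry an identical law), estimates
FWER as the fraction of runs with at least one rejection among true-null
contrasts and local power as per-contrast rejection fractions, and reports
the binomial precision band `nominal ± z_{0.975}·√(nominal(1−nominal)/runs)`.
The full cross product of distribution multisets, censoring levels, and
contrast families is deliberately not enumerated by default; the axes are
exposed for the user to combine.

## Problem sizes in the shipped checks

The test suite verifies error control and power ordering at sizes chosen to
give informative Monte-Carlo precision while keeping a full run fast:
10,000 runs for the (resampling-free) adjusted log-rank FWER, 10,000 runs
at B = 500 for the multiCASANOVA FWER, 1,000 shared-data runs for the
crossing-hazards power comparison, 5,000 replications for the covariance
plug-in validation, and a 60-run smoke check for the (computationally
heavier) maximum test. The acceptance script reruns the 10,000-run FWER
study from scratch.

## Known limitations

- The maximum test relies on the Gaussian approximation of the joint
  statistic vector; at small group sizes (n ≈ 50) its FWER can inflate,
  and no small-sample correction is implemented.
- multiCASANOVA's local decisions share one bootstrap quantile; per-
  contrast quantiles might be less conservative but would change the
  procedure's simultaneity structure, so the shared rule is kept.
- The multiCASANOVA wild bootstrap keeps `Ĉov` fixed at its data value and
  so ignores that estimator's own sampling noise; combined with the
  Rademacher multiplier's degenerate square (`G² ≡ 1`, which removes the
  diagonal variability of the bootstrap quadratic form), the Rademacher
  variant can run mildly above nominal at n ≈ 100 while converging to
  nominal as n grows — the test suite measures this directly. The
  centered-Poisson variant is the safer choice at moderate sample sizes.
- The adjusted mdir is known to be slightly liberal for Dunnett-type
  families; interpret borderline rejections with care.
- Statistics are not effect estimators: no confidence intervals on a
  hazard-difference scale are provided, only standardized-statistic
  reports.
- Holm/closed-testing refinements of the Bonferroni procedures are not
  implemented.
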
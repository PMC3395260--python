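# Methods

## Data model

A continuous test result Y is observed in a diseased group (Y₁, size n₁)
and a nondiseased group (Y₀, size n₀); a subject is called positive when
Y ≥ c. Over all cutoffs this yields the ROC curve
ROC(t) = 1 − F₁(F₀⁻¹(1 − t)), where F₁, F₀ are the group distribution
functions and t the false-positive rate, with AUC = P(Y₁ > Y₀)
(+ ½·P(Y₁ = Y₀) in the presence of ties).

## The three estimators

### Binormal (parametric)

Assumes Y₁ ~ N(μ₁, σ₁²), Y₀ ~ N(μ₀, σ₀²), so
ROC(t) = Φ(a + b Φ⁻¹(t)) with a = (μ₁ − μ₀)/σ₁, b = σ₀/σ₁, and
AUC = Φ(a/√(1 + b²)). `fit_binormal` is a pure moment plug-in with
sample SDs on denominator n − 1; at small n this SD's downward bias
inflates â slightly (the benchmark reproduces mean â ≈ 1.465 at n = 15
for true a = 1.4), which is a property of the plug-in itself, not a bug.
Parameter variances use the closed forms

    V(â) = [n₁(â² + 2) + 2 n₀ b̂²] / (2 n₀ n₁),
    V(b̂) = (n₁ + n₀) b̂² / (2 n₀ n₁).

The AUC standard error is the delta method applied to Φ(a/√(1+b²)) with
gradient (g_a, g_b) = (1/√(1+b²), −ab/(1+b²)^{3/2}) scaled by the normal
density, *including* the covariance term cov(â, b̂) = âb̂/(2n₁): both
estimates share σ̂₁ in their denominators and Var(σ̂₁) ≈ σ₁²/(2n₁). The
covariance term was validated two ways — against a 10⁵-replicate
Monte-Carlo of the plug-in AUC's spread at n = 100 (agreement within
15%), and against the benchmark's own mean-SE columns (0.066 vs 0.067 at
n = 15) — and is retained; omitting it overstates the SE by ~15% in that
design.

### Empirical (nonparametric)

`empirical_roc_curve` places one point per distinct observed value used
as cutoff (the ≥ convention), plus an explicit (0, 0) anchor at c = +∞;
the overall minimum cutoff supplies (1, 1), so trapezoidal integration
needs no special-casing. `empirical_auc` is computed from midranks,
which reproduces the pairwise Mann–Whitney kernel (ties scored ½)
exactly and equals the trapezoidal area under the step curve — both
identities are enforced as 1e-12 invariants in the tests against brute-
force pairwise oracles. The variance uses the tie-corrected components

    Q₁ = 1/(n₀n₁²) Σ_y n₀^{=y} [(n₁^{>y})² + n₁^{>y}n₁^{=y} + (n₁^{=y})²/3]

(sum over distinct nondiseased values; Q₂ symmetric with the groups'
roles swapped) combined as

    V = [AUC(1−AUC) + (n₁−1)(Q₁−AUC²) + (n₀−1)(Q₂−AUC²)] / (n₁n₀).

The printed form of this variance in the literature is typographically
ambiguous about whether the leading AUC(1−AUC) term shares the n₁n₀
denominator; the standard Mann–Whitney form above (all three terms
divided) is used, and on tie-free data Q₁ is exactly the probability
that two random diseased subjects both exceed one random nondiseased
subject (checked by triple-loop enumeration). A tiny negative V from
floating-point cancellation is clamped to zero.

### ROC-GLM (semiparametric)

Every pair (i, j) contributes U_ij = I[Y_i1 ≥ Y_j0]; every nondiseased
subject contributes its placement value t_j = #{k: Y_k0 ≥ Y_j0}/n₀ ∈
{1/n₀, …, 1}. Probit regression E(U) = Φ(β₁ + β₂Φ⁻¹(t)) yields smooth-
ROC parameters without assumptions on the raw values; note U uses ≥
(ties count 1) while the empirical kernel scores ties ½ — both exactly
as defined, so the two AUCs can differ on tied data.

Numerical choices:

- Rows with t_j = 1 (the minimal nondiseased value) are excluded:
  Φ⁻¹(1) = +∞ would break the likelihood. The alternative treatments
  (jittering t, or midrank-style placement (rank − ½)/n₀) were
  considered; exclusion perturbs neither U nor the remaining t and is
  standard for interior-FPR ROC-GLM fitting.
- The retained rows are aggregated into binomial counts per distinct
  placement value before fitting — the likelihood is identical and the
  design shrinks from n₁·n₀ rows to at most n₀ − 1, which is what makes
  thousand-replicate studies cheap. The pair-level arrays remain
  available as on-demand views.
- The fit is IRLS (statsmodels GLM, binomial family, probit link) with
  deviance tolerance 1e-12 and at most 100 iterations; tests pin the
  coefficients to an independent from-scratch Newton–Raphson probit ML
  on the disaggregated rows to 1e-8. Separation (all retained U equal)
  is flagged as non-convergence, with the last iterate returned.
- The n₁·n₀ indicators share subjects, so the GLM is fit under working
  independence and *all* inference comes from the bootstrap: subjects
  are resampled with replacement within each disease stratum (groups are
  design constants), the design rebuilt and refit per resample, and SEs
  are the SDs of the replicates; the interval is Wald around the
  original-sample point estimate. Default 200 resamples. Non-convergent
  resamples are dropped; more than 10% of them is an error. A
  consequence worth knowing: bootstrap SEs computed this way track the
  true sampling SD even for small heavy-tailed samples (verified within
  ±30% at n = 25 and ±50% at n = 15 against across-sample SDs) — a
  bootstrap that instead *keeps* separated refits can report SEs several
  times larger, because diverged replicates peg the AUC near 1.

Wald intervals throughout use z = Φ⁻¹(0.975) = 1.959964 at the default
95% level and are deliberately not truncated to [0, 1].

## The simulation benchmark

All scenarios share true (a, b) = (1.400, 0.900): diseased mean a/b =
1.5556 and SD 1/b = 1.1111, nondiseased mean 0 and SD 1, under three
shapes:

- **normal** — both groups Gaussian; true AUC = Φ(a/√(1+b²)) = 0.8510;
- **lognormal** — the exponential of the normal scenario's draws (with a
  shared seed the log of every value reproduces the normal draw bit for
  bit, so any rank-based quantity is identical between the two studies —
  a property the tests assert);
- **uniform** — diseased Uniform(a/b ± √12/(2b)), nondiseased
  Uniform(−√3, √3), preserving the means and SDs. Under these supports
  the true exceedance probability is P(Y₁ > Y₀) = 0.8345 by exact
  piecewise integration (`uniform_exceedance_prob`), cross-checked by a
  10⁶-pair Monte-Carlo. A `literal_uniform` flag widens the nondiseased
  support to (−3, 3) (SD √3) for sensitivity analysis; that variant's
  exceedance probability is ≈ 0.754 and it is not the benchmark default
  because it breaks the unit-SD convention shared by every other
  scenario.

The study engine replicates a scenario (default 1000 times), applies all
three estimators to each replicate, and summarizes per method: means of
the parameter estimates and their SE estimates, mean AUC, bias = nominal
− mean AUC (displayed unsigned), mean of the per-replicate SE
*estimates* (formula-based for the binormal and empirical methods,
bootstrap for the ROC-GLM — not an across-replicate SD), RMSE about the
nominal AUC computed once across replicates, and mean Wald interval
endpoints. Bias uses the normal-scenario nominal 0.8510 in *all*
families, including uniform — the benchmark measures departure from the
normal-theory target, not from each family's own truth. The identity
RMSE² = bias² + var(AUC replicates) holds to 1e-12 by construction and
is asserted. A Monte-Carlo SE of the mean AUC (sd/√n_reps) is carried in
each summary for tolerance-aware testing.

Per-replicate seeds are spawned from the scenario seed via numpy's
`SeedSequence`, two independent streams per replicate (data, bootstrap),
so studies are fully reproducible and every method sees identical data
within a replicate. If a replicate's semiparametric bootstrap fails its
<10%-separated-resamples guard (which happens for a few percent of
replicates at n = 15), the study keeps that replicate's point estimates
with NaN SEs (excluded from SE-column means), logs the count, and
continues; any other estimator failure aborts with the replicate index.
Without this the small-sample rows of the benchmark could not be
produced at all.

## Synthetic biomarker application

The application-style driver analyzes a synthetic stand-in for a
right-skewed clinical biomarker (62 diseased vs 20 nondiseased):
lognormal groups with log-scale means ln 104 and ln 33.95 and log-SDs
1.0 and 0.9, chosen so the group medians sit near 104 and 34 and the
means well above the medians (the skew signature). It emulates the
sample sizes and skew of a real serum-marker setting but none of its
clinical structure — no assay floor/ceiling, no measurement rounding, no
case-mix covariates — so results on it demonstrate estimator behaviour
under skew, not clinical performance. On such data the expected ordering
(binormal AUC below the two distribution-free estimates) holds for the
large majority of seeds and is asserted for fixed seeds in the tests.

## Problem sizes

The committed demonstration tables under `results/` were produced with
300 replicates and a 100-resample bootstrap (recorded in the file's
`run_info`), a deliberate demonstration-scale choice; the acceptance
script and the acceptance-level tests run the full 1000-replicate
studies (bootstrap disabled there, since only mean columns are checked —
mirroring how those summaries are defined). The Monte-Carlo oracle for
the delta-method SE uses 10⁵ replicates; generator moment checks use
10⁶ draws.

## Known limitations

- The binormal SE of the AUC depends on an assumed (â, b̂) covariance;
  the closed forms ignore O(1/n²) terms and are anti-conservative for
  n ≲ 10.
- The ROC-GLM drops t = 1 rows rather than reweighting; with very small
  n₀ this discards a visible fraction of pairs (and n₀ = 1 is
  unusable).
- Bootstrap inference assumes the resampled GLM converges for ≥ 90% of
  resamples; very small samples with AUC near 1 can fail that guard.
- No covariate adjustment, no partial AUC, no kernel-smoothed empirical
  curve, no links other than probit, no optimal-cutoff criterion.
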
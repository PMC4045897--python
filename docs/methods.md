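# Methods

## Setting and notation

A closed population of unknown size N is sampled on t occasions within a
primary period; the robust design nests such closed blocks inside an open
multi-period study. Capture histories are binary individual × occasion
matrices. Reductions: f_k = number of animals caught exactly k times,
S = Σ f_k distinct animals, n = Σ k f_k total detections, n_j detections on
occasion j. Point estimates are kept real-valued and rounded half away from
zero only at report time (frequency-based estimators report integers,
Petersen/coverage estimators two decimals, matching the conventions of the
original analysis programs).

## Petersen family

Chapman's adjustment of the Lincoln–Petersen estimator is used throughout:
N̂ = (n₁+1)(n₂+1)/(m+1) − 1 with variance
(n₁+1)(n₂+1)(n₁−m)(n₂−m)/((m+1)²(m+2)); it is defined even with no
recaptures. For a single two-sample estimate the occasions are split at the
contiguous cut minimizing the difference in total detections between the two
blocks (ties to the shorter prefix); contiguity preserves the
mark-then-recapture chronology, and "detections" rather than distinct
animals matches the balancing objective. Samples are always counts of
*distinct* animals in a block — Petersen arithmetic requires samples of
individuals, which is also why pooled occasions use the union indicator.

MPE averages the k−1 per-stage Chapman estimates (marked pool from occasions
1..j−1 versus occasion j); MLP averages the k−1 prefix/suffix pooled
estimates (occasions 1..i versus i+1..k). Pooling raises per-sample capture
probability and narrows its spread across individuals, which is the
mechanism that lets MLP tolerate moderate heterogeneity. Both use
var = Σ stage variances/(k−1)², ignoring the (small) covariances between
stages, and symmetric intervals N̂ ± 1.96·SE — the multi-stage estimators'
published intervals are symmetric, consistent with this choice.

## Frequency-based heterogeneity estimators

**Chao moment.** N̂ = S + f₁²/(2f₂); with no doubletons the bias-corrected
form S + f₁(f₁−1)/2 avoids the zero division. Variance (for f₂ > 0)
f₂(r⁴/4 + r³ + r²/2) with r = f₁/f₂; the 95% interval is log-normal on the
unseen count N̂ − S, so the lower bound can never fall below S. Under
heterogeneity the estimator is negatively biased and is read as a lower
bound.

**Interpolated jackknife.** Burnham–Overton orders 1..min(5, t−1) as linear
combinations Σ a_kj f_j; successive differences are tested (two-sided
normal, α = 0.05, variance (S/(S−1))(Σ(Δa_j)²f_j − d²/S)). The estimate
interpolates between the highest supported order m and m+1 with weight
|z_m|/z_crit, so a difference just short of significance leans toward the
higher order; if every difference is significant the top order is used.
Variance of the interpolated combination is Σ a_j²f_j − N̂. On very dense
data (f₁ = 0) the negative f₂ coefficients can push the combination below
S; the estimate is floored at S, since no population can be smaller than
the animals actually seen. The jackknife requires t and therefore refuses
frequency tables whose occasion count is unrecorded.

**Truncated geometric.** Capture counts are modelled as geometric,
P(X = j) ∝ (1−q)qʲ on support {0..t} (right truncation at the occasion
count: an animal cannot be caught more often than there are occasions;
truncation defaults to t and may be set to ∞). q is estimated by maximizing
the zero-truncated likelihood (bounded scalar search, tolerance 1e−10), and
N̂ = S/P(X ≥ 1 | q̂). Without right truncation this collapses to the closed
form N̂ = S·n/(n−S); numerically the truncated MLE matches it once the
truncation point exceeds ~50. The interval is a χ²₁ profile-likelihood
interval on N under the unconditional likelihood (the published intervals
for this estimator are asymmetric and their exact construction is not
recorded; the profile interval is the standard likelihood-based choice).
Data with n = S (all singletons) are refused: q̂ → 0 and N is unbounded.

## Sample-coverage estimators

Coverage Ĉ = 1 − f₁/n estimates the probability mass of catchabilities
represented in the sample. The squared CV of individual catchability is
γ̂² = max{(S/Ĉ)·Σk(k−1)f_k / (2Σ_{j<k} n_j n_k) − 1, 0}; the pairwise-effort
denominator handles unequal per-occasion sample sizes and reduces to the
equal-effort textbook form when n_j are equal. CV = 0 iff animals are
equally catchable. SC1 is N̂ = S/Ĉ + f₁γ̂²/Ĉ; SC2 replaces Ĉ by the
bias-corrected Ĉ₂ = 1 − [f₁ − 2f₂/(t−1)]/n (clamped into (0, 1]; refused
with a diagnostic when non-positive) and recomputes γ̂² with S/Ĉ₂ — finer
correction terms of the original derivation are an acknowledged
approximation. The estimating-equation Mh variant solves the same relation
self-consistently, iterating N ← S/Ĉ + (f₁/Ĉ)·γ̂²(N) where γ̂²(N) uses the
current N in place of S/Ĉ, to a relative step below 1e−8 (at most 500
iterations; non-convergence is flagged in the diagnostics, never silent).

Standard errors for all three use the asymptotic delta method over the
frequency vector with multinomial covariance cov(f_i, f_j) = f_i(δ_ij −
f_j/N̂), the pairwise effort term held fixed as a design quantity, and
log-normal intervals on N̂ − S.

A caveat worth knowing: Ĉ = 1 − f₁/n targets 1 − (1−p)^{t−1} rather than
the unseen-animal probability 1 − (1−p)^t, so at moderate p and t the
coverage family overestimates slightly even under equal catchability
(≈ +2.7% at p = 0.3, t = 8). Two consequences are visible in the test
suite: the CV estimate has a small positive mean under exactly equal
catchability (the floor at zero makes the square root one-sided), and in
very-high-capture regimes the skewed interval's lower bound can sit above
the true N, depressing coverage. Both are properties of these classical
estimators, not of this implementation.

## Likelihood models

**Finite mixture.** G ∈ {1, 2, 3} latent catchability classes with weights
π; the full unconditional likelihood lnΓ(N+1) − lnΓ(N−S+1) + (N−S)lnP₀ +
Σᵢ lnP(hᵢ) is maximized over (N, π, p[, c]) on unconstrained scales (log
for N−S, softmax for π, logit for probabilities), from ≥5 seeded random
starts with the best kept. Optional additive-logit occasion effects and a
shared post-first-capture logit offset (behaviour); the behaviour clock
resets at primary-period boundaries. G = 1 without effects is the classical
M0 likelihood and matches an integer-N grid search. N gets a χ²₁
profile-likelihood interval. AIC = −2ℓ + 2K counts every free parameter
including N; ties go to fewer parameters. The default candidate set is
{π(.)p(.), π(.)p(t), π(.)p(.)c(.)} × G ∈ {1, 2} — a deliberately reduced
family, since the fully time-varying mixture family is unbounded.

**Huggins–Horvitz–Thompson.** Occasion-level logistic capture model fitted
by the likelihood conditional on being caught at least once; design terms
are `time` (occasion factors), `behaviour` (previously-captured indicator)
and categorical individual covariates (e.g. 3-level age, 5-level site/hut),
parsed from formulas like `"~ age + hut + time"`. N̂ = Σᵢ 1/p*ᵢ with p*ᵢ
evaluated at first-capture probabilities (behaviour indicator off).
Variance is the Horvitz–Thompson term Σ(1−p*ᵢ)/p*ᵢ² plus the delta-method
propagation of the coefficient covariance (inverse Hessian). Complete
separation (a covariate level caught always) is flagged, not fatal; missing
covariate values are errors.

## Reference populations and ranking

For each primary period except the last (which supports no reference), the
reference set contains all animals captured in that or any later period,
minus juveniles whose recorded birth period is later (they were not yet in
the population). The `partly` independent variant stops there; the `fully`
independent variant additionally removes animals captured in the focal
period but never again — from the reference *and* from the estimation data,
so no capture is used on both sides. The occasion count feeding
p_tr = 1 − 0.05^(1/n) is the number of occasions from the focal period to
the study end (`partly`) or strictly after it (`fully`).

With ratios rᵢ = N̂ᵢ/N_ref,i: bias = mean(rᵢ − 1), precision =
mean((rᵢ − r̄)²), accuracy = mean((rᵢ − 1)²). The 1/n (population)
convention is used for all three so the decomposition accuracy = precision
+ bias² is exact. Precision about the mean ratio (rather than about 1) is a
deliberate choice — it is what makes the mean-square decomposition hold —
and alternative conventions circulating in the literature (e.g. the squared
CV of the raw estimates) order estimators differently when references vary
across periods. CI coverage is counted strictly (bound inclusive); ranking
per criterion is by |value| ascending (CI width by value), ties share a
rank with label order for presentation, and estimators within 50% of the
best are flagged.

## Simulator

Each animal draws a base catchability from a configurable law — constant p;
beta(α, β); or a two-point mixture placing mass on a low catchability to
create the long tail that challenges every estimator. Per-occasion detection
is an independent Bernoulli at base × occasion multiplier × site multiplier
(products above 1 are clamped with a warning); a behavioural odds multiplier
applies after first capture within a period and resets at period boundaries
(closed-population models treat periods independently). Between periods,
survival thins the alive set and a fixed number of juvenile recruits enter
with their birth period recorded, so the reference rules can be exercised
against exact truth. Identical seeds give byte-identical output. The
observed data omit never-captured animals, exactly as field data would.

What the simulator does *not* emulate: spatial structure (home ranges,
trap locations), continuous-time capture, tag loss, or dependence between
animals. Passing tests therefore certify the estimators' statistical
behaviour under the assumed heterogeneity laws, not robustness to spatial
or observational artefacts of real field work.

## Bundled data and problem sizes

The packaged gecko tables carry, per primary period, the frequency rows
f₁..f₈, S, the reference sizes of both constructions, the occasion counts
used for the thresholds, p_tr and the CV — plus the abundance estimates the
original analysis programs produced, as evaluation inputs. The number of
pooled estimation occasions per period was not recorded (≤ 8, from the
frequency support), so these tables carry t as unknown and estimators
needing t or n_j refuse them explicitly.

Monte-Carlo test sizes were chosen to make the checks sharp but quick: the
closed-form estimator properties run at 500 replicates (N = 200, t = 8),
Petersen unbiasedness at 300, and the likelihood-model AIC-selection checks
at 15–25 seeded replicates (each mixture fit multiplies out to ~1–2 s);
selection rates in those regimes are far from the 80% thresholds tested.

## Known limitations

* The coverage-family bias described above; SC2's γ̂² reuses the SC1
  quadratic form with Ĉ₂ substituted.
* The estimating-equation Mh implements the coverage-based fixed point, the
  simplest member of that family; time and behaviour extensions are out of
  scope.
* The jackknife interpolation weight |z|/z_crit is one reasonable reading of
  the classical sequential procedure; order selection matches it exactly,
  interpolation details may differ from other implementations.
* Published truncated-geometric and CARE-2 values are not exactly
  reproducible (their internal variants and per-occasion sample sizes were
  never published); the closed-form untruncated limit does match the first
  period's published value.
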
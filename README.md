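# closedcmr

Closed-population capture–mark–recapture (CMR) abundance estimation, with a
framework for judging estimators against *reference populations* built from
intensively sampled field data, and a robust-design simulator with known
truth.

Counting every animal in a wild population is rarely possible, so population
size N is estimated from repeated capture sessions in which marked
individuals can be re-identified. The hard part is *individual
heterogeneity*: animals differ in how catchable they are, and estimators
that ignore this are biased low. This package implements the classical suite
of closed-population estimators that a field ecologist would compare,
supports both occasion-level capture histories and published
capture-frequency tables, and ships the summary tables of a two-year gecko
(*Gehyra variegata*) field study as a worked benchmark.

## Estimators

All estimators are small model objects whose `fit()` returns an
`EstimateResult` (point estimate N̂, SE, 95% CI, diagnostics, `summary()`);
one-line functional wrappers are provided throughout.

| Method | Idea |
|---|---|
| `chapman` / `lp` | Chapman-adjusted Lincoln–Petersen, N̂ = (n₁+1)(n₂+1)/(m+1) − 1, on the capture-balancing two-block split |
| `mpe` | mean of per-stage Chapman estimates against the growing marked pool |
| `mlp` | mean Chapman estimate over all prefix/suffix occasion poolings (pooling raises capture probability and shrinks heterogeneity) |
| `chao_moment` | Chao's moment (lower-bound) Mh estimator, N̂ = S + f₁²/(2f₂) |
| `jackknife_interpolated` | Burnham–Overton jackknife orders 1–5 with CAPTURE-style sequential order selection and interpolation |
| `sc1`, `sc2` | Lee–Chao sample-coverage estimators, N̂ = S/Ĉ + f₁γ̂²/Ĉ with Ĉ = 1 − f₁/n and the CV² of catchability γ̂² |
| `ee_mh` | estimating-equation Mh: the coverage relation solved self-consistently in N |
| `trunc_geom_fit` | zero-truncated, right-truncated geometric fit to capture frequencies; N̂ = S/P(X ≥ 1) (closed form S·n/(n−S) without truncation) |
| `FiniteMixture` | Pledger-style finite-mixture full likelihood over (N, π, p[, c]), AIC selection |
| `HugginsHT` | Huggins conditional likelihood with covariates + Horvitz–Thompson N̂ = Σ 1/p*ᵢ, AIC selection |

Here f_k is the number of individuals captured exactly k times, S = Σf_k the
number of distinct animals, n = Σk·f_k the total detections.

## Evaluation framework

`build_reference` implements the reference-population construction: for each
primary period except the last, all animals known alive from captures in
that or any later period, minus juveniles born later — in a `partly`
independent variant (period-only captures reused) and a `fully` independent
one (period-only animals dropped from reference *and* estimation data).
`p_threshold(n)` = 1 − 0.05^(1/n) gives the daily capture probability above
which an animal is detected at least once in n occasions with 95%
probability. `performance_metrics` / `rank_estimators` score estimators by
relative bias, precision, accuracy (mean, variance and mean-square of the
ratios N̂/N_ref − so accuracy = precision + bias² exactly), CI coverage and
CI width. `simulate_robust_design` generates capture histories with
configurable heterogeneity (constant, beta, two-point mixture), time/
behaviour/site effects, survival and juvenile recruitment, returning exact
truth for every pipeline stage.

## Worked example

Chao's moment estimator on the first primary period (November 1985) of the
bundled partly-independent gecko frequency table (f₁ = 53, f₂ = 19, S = 77):

```python
>>> from closedcmr import chao_moment
>>> from closedcmr.datasets import load_gecko_frequencies
>>> res = chao_moment(load_gecko_frequencies("partly")["1985_11"])
>>> print(res.summary())
Population size estimate [ME]
--------------------------------------------
  N-hat           150.92
  SE               27.82
  95% CI    (113.22, 227.86)
  f1             53.0000
  f2             19.0000
  S              77.0000
```

77 distinct geckos were caught; the 53 singletons against 19 doubletons
imply about 74 animals were missed, giving N̂ ≈ 151 with a right-skewed
(log-normal) interval of roughly 113–228 — the reference population for that
period was 194, inside the interval. The same frequencies fitted by an
untruncated geometric give `275 (195–400)`: the geometric's long tail of low
catchabilities pushes the estimate far above the heterogeneity lower bound.

The full benchmark (every estimator × period × reference mode, with rank
tables) runs from the command line:

```sh
closedcmr run --config benchmark.yaml      # files or simulation input
closedcmr simulate --config sim.yaml --out data/
closedcmr estimate --input captures.inp --method ME
```

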
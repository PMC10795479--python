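# Methods

## Life-table construction

Abridged period life tables use the standard rate-to-probability conversion
`nqx = n·nmx / (1 + (n − nax)·nmx)`, survivorship as the running product of
`npx = 1 − nqx` with radix `l0 = 1`, person-years
`nLx = n·l(x+n) + nax·(l(x) − l(x+n))` in closed groups, and `l/m` in the
open-ended group, where `q = 1` and `e = 1/m` by construction. The
separation factors `nax` are inputs; when a file omits them we fall back to
`n/2`, except `a0 = 0.07 + 1.7·m0` and `a(1–4) = 1.5` for grids starting at
birth. Those defaults exist for synthetic and exploratory data only —
observed `nax` should always be supplied, and the bundled example carries
its published values verbatim (how its infant-age values were produced is
not documented in the source, so we do not recompute them).

`q` is clamped at 1 (with a warning) for extreme rates so downstream columns
stay defined; schedules whose open-group rate is zero are rejected, since
the open-group expectancy `1/m` is undefined. All columns are stored at
radix 1; published-scale values (per 100,000) are derived, never stored.

## The decomposition

Arriaga contributions are computed from life-table columns
(`l`, `nL`, `e`, `np`) rather than by chaining raw probability products —
the two forms are algebraically identical, but the column form is better
conditioned. Population 1 is always the baseline (minuend); reversing the
argument order negates the total. No symmetrized (two-direction average)
variant is implemented.

The cause split multiplies each age contribution by
`(nm²xi − nm¹xi) / (nm²x − nm¹x)`. When the all-cause rate change in a group
is below 1e-15: if the age contribution is itself ≈ 0 the whole row is set
to zero (the 0/0 case); otherwise the split is mathematically undefined
there and we raise rather than return unstable ratios.

## Delta-method standard errors

Parameters are the closed-group survival probabilities of both populations
plus the two open-group death counts, all treated as independent —
binomial variance `(1−p)²p/D` for probabilities, Poisson variance `D` for
the open-group counts, with exposures fixed. Survey-estimated inputs
substitute the supplied squared standard errors instead (rate-scale SEs are
converted to the probability scale through the exact derivative
`dq/dm = n/(1 + (n−a)m)²`).

The closed-form Jacobian is derived directly from the implemented
decomposition. One printed rendering of the derivative of `e(x+n)` with
respect to an older-age survival probability is index-ambiguous in the
source material; we resolved it by differentiating the implemented function
(the term reads `(l_i/l_{x+n})·((n_i − a_i) + e_{i+n})`) and let central
finite differences arbitrate: the test suite checks every entry of the
Jacobian against numerical differentiation at relative tolerance 1e-5, and
checks the sparsity pattern (zero blocks) exactly.

The total's standard error uses the column sums of the Jacobian as the
total's gradient, which is what captures the cross-age covariance induced
by shared parameters. Because the contributions sum identically to
`e0² − e0¹` and the populations are independent, this total SE must equal
`sqrt(var(ê0¹) + var(ê0²))` from the independent single-population delta
variance implemented in `lifetable.e0_variance_delta`; the suite asserts
that identity at 1e-8 relative, which is a strong end-to-end check on both
code paths. Groups with zero observed deaths contribute zero variance —
no engine here can assign positive variance to an empty group, and a
warning flags the caveat.

## Simulation engines

- **Monte Carlo** (recommended general-purpose engine): every input rate is
  drawn from an independent normal with mean the observed rate and variance
  `m/N` (count-implied) or a supplied squared SE (survey mode). The
  estimator is any pure function of the rate vectors; the built-in
  decomposition estimator is vectorised so 10,000 replicates evaluate in a
  single array pass. Negative rate draws are truncated to zero and counted
  in the result's `n_truncated` — the normal-on-rates approximation is only
  endorsed when groups have roughly ≥ 5 expected deaths, where truncation
  is vanishingly rare, and the counter makes violations visible.
- **Poisson bootstrap**: deaths drawn `Poisson(D)` per group, open group
  included; rates re-derived with exposures fixed.
- **Binomial bootstrap**: closed groups draw `Binomial(round(D/q), q)`
  (trials floored at 1; the source does not specify the integerization);
  the open group stays Poisson because its death probability is 1 and a
  binomial there would contribute zero variance.
- **Jackknife**: delete-one over micro-data rows, variance
  `(N−1)/N · Σ (θ̂_(j) − θ̂)²` around the full-sample estimate; SE only, no
  percentile CI (replicates are not a sampling distribution). Intended for
  modest N; survey designs with primary sampling units are out of scope, as
  is the nonparametric bootstrap with replicate weights.

Replicate summaries are uniform: SE is the sample SD (denominator
reps − 1), confidence intervals are percentile intervals with linear
interpolation between order statistics (numpy's default quantile
definition, fixed permanently). Replicates where the estimator fails or
returns non-finite values (e.g. a zero-death open-group draw) are recorded
and excluded; more than 1% failures aborts the run rather than report
silently biased SEs. Draw order is fixed (population 1 then 2, ages — and
causes — ascending) so a seed fully determines the output; stochastic CLI
commands require an explicit seed. The default of 1,000 replicates is
adequate for this estimator — the suite checks per-age SEs move by < 5%
when reps grow tenfold.

## Synthetic data

The generator integrates a Gompertz–Makeham hazard with an infant bump,
`μ(x) = c + b·e^{θx} + h·e^{−kx}`, to exact stationary-population group
rates (midpoint quadrature at 1/32-year steps, open group capped at age
130), then draws deaths Poisson or binomial around `N·m`, or returns exact
expectations with `noise="none"`. Defaults (`c = 2e-4`, `b = 3e-5`,
`θ = 0.095`, `h = 0.025`, `k = 4`) describe a contemporary low-mortality
female population (e0 ≈ 84); tests pair it against a higher-mortality
variant so the true decomposition is known. Synthetic-data tests exercise
sampling behaviour under exactly the assumed generating processes; real
data add heterogeneity, migration, and measurement error that none of these
engines model, so passing tests demonstrate correctness of the estimators,
not robustness to misspecification.

The published worked example prints only rates and separation factors, not
counts. The bundled loader can attach a clearly-labelled synthetic exposure
profile (90k–650k person-years per group, plausible for a 50% sample of the
population in question, chosen once) so that count-based engines run; this
fixes the absolute SE scale but leaves all cross-method comparisons
meaningful because every engine sees the same counts. Problem sizes used in
the verification suite — 10,000 replicates for cross-method concordance,
2,000 simulated pairs for parameter recovery, 500 pairs × 1,000 replicates
for CI coverage — were chosen as the smallest sizes at which Monte Carlo
noise is comfortably below the tolerances being asserted.

## Known limitations

- Exposures are treated as nonrandom everywhere; uncertainty in population
  denominators is not modelled.
- Parameter independence across age groups is assumed by all engines;
  smoothed or model-based rate estimates with cross-age covariance need the
  survey pathway (supply SEs) and will still ignore covariance terms.
- Percentile CIs are plain (no bias correction/BCa).
- With fewer than ~5 deaths in a group no method here yields trustworthy
  standard errors; results in that regime should be read qualitatively.
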
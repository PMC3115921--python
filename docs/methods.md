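# Methods

## Model and assumptions

`pairback` inverts large-sample Wald tests. Throughout, a reported
two-sided p-value is assumed to satisfy `p = 2(1 − F(|T|))` where `F` is
the CDF of the test's null reference distribution — standard normal for the
paired z-test, McNemar test, and the log-scale risk-ratio and odds-ratio
Wald tests; Student-t with n − 1 degrees of freedom for the paired t-test.
One-sided p-values, exact/mid-p tail probabilities, and
continuity-corrected statistics are outside the model: inverting them
through the normal quantile gives a wrong deviate, and nothing in the
reported summary reveals the discrepancy. For that reason the continuous
scheme requires the caller to state which test (z or t) produced the p; it
never guesses.

All derived intervals are Wald intervals — `estimate ± q·se` on the
identity scale for the mean difference and risk difference, exponentiated
from the log scale for the risk and odds ratios. Risk-difference limits are
truncated to [−1, 1] since Wald limits can exit the parameter space.

### Continuous outcomes

From the test identity `T = |d̄|/se`, the standard error is `se = |d̄|/T`
with `T` recovered from p. The standard error is computed from |d̄| but the
CI is centred on the signed d̄: the reported p is taken to belong to the
reported difference. The standard deviation of the within-pair differences
is `s_d = se·√n`; it absorbs the (unreported) between-arm correlation,
which is exactly why it cannot be computed from the two group SDs alone.

### Binary outcomes: variance estimators

For pair-type counts (a, b, c, d), the package uses the standard
matched-pairs forms:

* risk difference, general (CI): `v = [(b+c) − (c−b)²/n]/n²`. This is the
  multinomial plug-in variance of (C−B)/n evaluated at the observed cell
  frequencies — the test suite verifies it against exhaustive enumeration
  of the four-cell multinomial at n ≤ 6.
* risk difference, null (test): `v₀ = (b+c)/n²`. The two are linked exactly
  by `v = v₀ − δ̂²/n`, and `√v₀` satisfies the McNemar identity
  `T·√v₀ = |δ̂|`, both checked property-wise on arbitrary tables.
* log risk ratio: `(b+c)/[(b+d)(c+d)]`, verified against the delta-method
  variance assembled from the multinomial covariance matrix.
* log odds ratio (conditional on the discordant total): `1/b + 1/c`.

No continuity corrections are applied anywhere.

### Table reconstruction

Each scheme is a linear system. The p-value (or the odds ratio) fixes the
discordant total b + c (or the ratio b/c); the marginal difference fixes
c − b; the known marginal then gives d, and a is the remainder. The system
is non-singular whenever b ≠ c, so feeding a scheme the exact summaries of
a table returns that table — the exact-recovery property asserted over
1000 random tables in the acceptance suite.

Rounding order, where summaries are only printed to a few digits: b and c
are rounded first (half away from zero) because they carry all the
variance information; then d = round(n·known marginal) − b (or − c); then
a = n − b − c − d, forcing the cells to sum to n exactly. Raw cells in
(−0.5, 0) are treated as reporting-rounding noise and clamped to zero with
a warning; a raw cell below −0.5 means no non-negative table is consistent
with the summaries and raises an infeasibility error. When n·marginal is
not integral the full-precision product is used until the final rounding
step; the marginal is never "repaired".

The risk-ratio scheme assumes the published p came from the risk-ratio
Wald statistic, which is rare; its output is flagged accordingly, and the
recommended route for a risk ratio from a McNemar p-value is
`rr_via_rd_route` (reconstruct via the risk-difference scheme, then compute
the risk ratio from the recovered cells).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `level` | 0.95 | confidence level of all intervals |
| `legacy_196` | off | use the literal 1.96 instead of 1.959964…; only affects digits below reporting precision, provided for digit-for-digit textbook arithmetic |
| p floor | 1e-300 | smallest accepted p; below it the quantile overflows |
| sparse thresholds | n ≤ 50, min(b,c) ≤ 5, (b+c)/n ≤ 0.05 | emit a warning (never an error): with few pairs or skewed tables different CI methods diverge and a back-calculated Wald interval is only one of them |

Sensitivity sweeps build their grid as multiples of the step from p_min
(no floating accumulation), include p_min, and reconstruct + integer-round
the binary table at every grid point before computing the CI — the
convention that corresponds to what a reader applying the scheme at that p
would do, and the one under which the sweep's endpoint intervals match the
direct desk calculations. `digit_perturbation` sweeps the half-open
rounding interval of the printed p at a given number of significant digits
(default resolution 1e-4).

## What the simulator emulates — and what it does not

`simulate` draws binary tables from a four-cell multinomial over pair-type
probabilities given in cell order (p_a, p_b, p_c, p_d), and continuous
differences as i.i.d. normal with a specified mean and SD of differences.
It then degrades the exact summaries the way journals print them:
proportions rounded half-away-from-zero to a fixed number of decimals
(default 3), p rounded to 1–3 significant digits (default 2). The default
binary scenario uses n = 60 pairs with cell probabilities
(1/6, 2/15, 1/3, 11/30) — expected table (10, 8, 20, 22), matching the
worked mortality example — and 1000 replicates, which runs in well under a
minute on one CPU. Replicates whose exact summaries are already degenerate
(no discordant pairs, b = c, or p rounding to 1) are skipped and reported
separately, not folded into accuracy denominators. Seeds are mandatory;
there is no global RNG state.

What passing round-trip tests shows: the schemes are exact inverses of the
stated tests, and robust to the stated reporting precision at moderate n.
What it does not show: behaviour when the published p came from a
different test than assumed (exact, score, non-parametric), when the
marginals were themselves mis-reported, or when pairs were broken or
post-hoc matched — none of which the generator models. The continuous
generator draws normal differences only; heavy-tailed or skewed outcome
distributions (common for length-of-stay data) affect the original test's
validity, not the inversion arithmetic, but they are likewise not
emulated.

## Numerical choices

* Deviates are carried at full floating precision; printed three-digit
  deviates in desk arithmetic are never imitated internally.
* p = 1 maps to deviate 0. It is accepted by the deviate conversions but
  rejected (as degenerate) by every recovery scheme, since se = |d̄|/0 is
  undefined.
* Quantiles come from `scipy.stats.norm`/`scipy.stats.t` inverse survival
  functions; round-trips hold to at least 10 significant digits over
  p ∈ [1e-10, 1].
* Cell rounding is half away from zero (0.5 → 1), matching how printed
  proportions are rounded.
* NNT keeps the raw reciprocal in the data object; integer NNTs are a
  display convention (text renderer only). Its CI is the reversed
  reciprocal of the risk-difference CI and is refused when that CI spans
  zero — the interval would be a disjoint union of two rays, which the
  Wald framework does not represent.

## Known limitations

* Everything is large-sample theory. Below ~50 pairs, or with very sparse
  discordance, the recovered Wald CI can differ materially from exact or
  score intervals; the package warns but does not correct.
* A p-value printed as an inequality ("p < 0.05") cannot be inverted; the
  sensitivity module can bound the consequences of a p known only to an
  interval, but the point schemes need a point p.
* Reconstruction trusts the reported marginals. If they were rounded
  aggressively (whole percents at small n), the ±1-cell guarantee observed
  at 3-decimal precision degrades; rerun `simulate` with
  `report_decimals_marginals` matching the actual reporting to calibrate.
* Stratified designs, 1:m matching, and multi-category matched tables are
  out of scope.
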
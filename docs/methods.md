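# Methods

## Model and assumptions

The package implements a comparative risk assessment of cancer healthcare
costs attributable to excess body weight (EBW, BMI ≥ 25 kg/m²). Exposure
is categorical: a population is described by the proportions `P_i` of
adults in ordered BMI strata (default: <25 reference, 25–<30, 30–<35,
≥35 kg/m²). Risk is log-linear in BMI: a relative risk `RR_x` reported
per `x` kg/m² converts to `RR₁ = exp(log(RR_x)/x)` and expands to
category risks `RR_c = RR₁^(M_c − ref)`, where `M_c` is the category
median. The burden contrast is the potential impact fraction

    PIF = (Σ P_i RR_i − Σ P'_i RR_i) / Σ P_i RR_i

between the baseline distribution `P` and a counterfactual `P'`, reducing
to the population attributable fraction when `P'` is the all-reference
distribution (the theoretical minimum risk exposure level). Attributable
cost is PIF × the OLS-projected cost of the cancer in the target year,
after purchasing-power-parity conversion (2.281 R$ per international US$
for 2019). Prevalence years and cost years are paired under a 10-year
exposure–outcome lag — (2019, 2030) for attribution and (2030, 2040) for
scenario savings by default; the pairing is validated, not hard-coded.

Key simplifying assumptions: risks are multiplicative and log-linear in
BMI within and across categories; the population is homogeneous within a
stratum (sex) and category; cost trends are linear in calendar time; no
recurrence dynamics, lifetime BMI trajectories, or competing risks.

## The reference value in the categorical expansion

Only the interval "< 25 kg/m²" defines the reference category, not the
value `ref` subtracted in the exponent. The package takes `ref` as the
reference category's median (configurable) and then normalizes the
profile by the reference category's own RR. Because the PIF is invariant
to rescaling all `RR_i` by a common constant, this makes the choice of
`ref` immaterial downstream while guaranteeing the reference RR is
exactly 1; a test asserts this invariance.

## Counterfactual scenarios

* `target_distribution` — replace the distribution with a supplied table
  (e.g. the 2008/09 household-budget-survey distribution).
* `hold_reference` — freeze at a designated reference-year table; with no
  reference table the counterfactual is the baseline itself and the PIF
  is identically zero.
* `truncate_above` — remove categories whose lower bound is at/above a
  threshold (default 35 kg/m²). The displaced mass moves to the adjacent
  category just below the threshold — a minimal-change assumption —
  with an option to send it to the reference category instead. A
  threshold eliminating no category is a no-op with a warning signal.
* `mean_shift` — a 1 kg/m² (configurable) reduction in mean BMI among
  people at/above 25 kg/m². Because exposure is categorical, this is
  realized on the risk side: counterfactual RRs are evaluated at medians
  `M_c − shift` for eligible categories while prevalences stay at
  baseline. Under the log-linear model this is equivalent to shifting
  every exposed person's BMI down by the same amount; re-binning mass
  across category boundaries is deliberately not attempted.

For analyses needing a future baseline distribution (the 2040 savings
analysis uses a 2030 baseline), proportions are extrapolated linearly per
category between two observed surveys, clipped to [0, 1] and
renormalized. This is a transparent stand-in for demographic projection
models; results of the savings analysis depend on it and it is flagged in
reports by the projected year.

## Uncertainty propagation

Monte Carlo with 10,000 iterations by default. Per iteration:

* prevalence — per-category binomial draws `Bin(n_eff, P_i)/n_eff`
  renormalized to the simplex (independent binomials alone would break
  the sum-to-one constraint; renormalization is the minimal fix), with a
  single-multinomial mode as an alternative;
* log-RR — one normal draw per subtype on the published increment scale,
  with `se = (ln ci_high − ln ci_low)/(2 × 1.959964)` (the exact normal
  quantile rather than 1.96, so CI↔SE round trips are exact), rescaled
  and expanded to categories inside the iteration so all category RRs of
  a subtype share one dose-response draw (perfectly correlated within
  subtype);
* distribution-derived counterfactuals (truncation, mean shift) are
  recomputed from each prevalence draw; externally supplied tables
  (historical target, frozen reference year) are held fixed — only the
  two stochastic inputs above are drawn.

Summaries are the 2.5th/50th/97.5th percentiles, the median being the
central estimate. Negative PIF draws are truncated to zero draw-by-draw
(BMI reduction is assumed not to increase risk); truncation can be
disabled. Fixing the seed fixes every draw; reports are byte-identical
under a fixed seed and config.

Attribution intervals multiply the PIF interval by the fixed point cost:
the published site-level bounds are exactly PIF bounds × point cost, so
cost-projection uncertainty is reported separately (the projection's own
OLS prediction interval) rather than convolved into the PIF interval.

## Cost projection

Ordinary least squares of annual cost on calendar year, with the year
covariate centered before fitting (identical estimates, better
conditioning). Intervals are standard t-based OLS prediction intervals at
95%; an exactly linear noiseless series projects exactly with zero
interval width. Negative projections are floored at zero with a warning.
Currency conversion divides by the PPP factor after projection; for a
linear model the order is irrelevant beyond rounding.

## Random-effects pooling

Where a published pooled RR mixes incidence and mortality outcomes,
per-study log-RRs can be re-pooled on incidence only. The estimator is
DerSimonian–Laird — the standard default when no random-effects estimator
is named: moment estimate `τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw))` with
inverse-variance weights, re-weighted pooling with `1/(se² + τ²)`. With
`τ² = 0` this reduces to fixed-effect inverse-variance pooling; tests
verify both the longhand arithmetic and agreement with an independent
meta-analysis implementation.

## Synthetic data generator

The generator stands in for the national survey and cost registries so
the full pipeline is testable offline. Defaults describe a Brazil-2019-
like population: category proportions (0.397, 0.344, 0.189, 0.070) —
about 60% of adults above the reference category and 26% with obesity —
an effective sample size of 5,000 per sex stratum (a large national
survey's effective size; the true per-stratum design effects of such
surveys are not public, so this is a free parameter), twelve years
(2008–2019) of linear cost series in million R$ with additive Gaussian
noise floored at zero, and a small RR table spanning strong
(endometrium), moderate (kidney) and weak (colorectal) associations.
Prevalence counts are drawn as one multinomial partition of the effective
n, so generated tables satisfy the sum-to-one invariant exactly, and
per-category CIs are Wilson score intervals. The generator does **not**
emulate complex survey design (weights, clustering, stratification),
self-report measurement error, or nonlinear cost dynamics — passing tests
therefore demonstrate correctness of the estimator arithmetic and
calibration under the stated sampling model, not robustness to
design-based variance or reporting bias in real surveys.

`ground_truth_pif` evaluates the impact fraction exactly from the
generating parameters, which anchors the parameter-recovery tests: with
10,000 iterations the Monte Carlo median falls within twice the median's
Monte Carlo standard error (1.2533·σ/√n) of the truth, and across 200
replicate datasets the 95% intervals cover the truth at a rate consistent
with nominal (90–99%).

## Numerical choices and degenerate inputs

* Proportion vectors must sum to 1 within 1e-9; schemas must be ordered,
  non-overlapping, with exactly one reference category.
* `Σ P_i RR_i = 0` raises rather than returning an indeterminate PIF.
* All-zero binomial draw rows (possible only when every proportion is
  tiny) fall back to the point proportions.
* Rounding to 2 decimal places happens only in reports; intermediate
  computation keeps full precision.
* Deterministic (non-Monte-Carlo) PIFs may be negative and are reported
  as computed; truncation applies only to simulation draws.

## Problem sizes

Default runs use 10,000 Monte Carlo iterations per subtype×scenario; the
recovery study in the test suite uses 200 replicate datasets of 10,000
iterations each at effective n = 5,000, and the oracle-equivalence checks
use 300 random instances of up to six categories. These sizes were chosen
to make Monte Carlo error negligible relative to the reported precision.

## Known limitations

* Scenario savings depend on the linear prevalence projection rule; any
  external projection can be supplied instead via a prevalence table for
  the baseline year.
* The per-stratum effective sample size drives interval widths; when it
  is unknown, intervals are qualitative.
* Fixed-cost attribution ignores cost-projection uncertainty in the
  attributable-cost interval (by design, matching the reporting
  convention; the projection interval is available separately).
* Site-level PIFs assume subtype attributable costs never exceed the
  site total; inputs violating this are rejected rather than clipped.
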
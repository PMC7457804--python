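# Methods

This note documents the models, conventions and numerical choices behind
`hcal`, and what the synthetic tests do and do not establish about real
data.

## Life tables

All tables use one-year age intervals [x, x+1) over completed ages
0..ω, with ω = 100 by default. Central death rates convert to
probabilities by

    q(x) = m(x) / (1 + (1 − a(x)) · m(x)),

clamped to [0, 1] with a logged warning (raw rates at extreme ages can
push the formula past 1). The separation factor a(x) — the mean fraction
of the interval lived by those dying in it — is 0.5 at all ages except
infancy; a(0) follows either the Keyfitz–Flieger rule
a(0) = 0.07 + 1.7·m(0), capped at 0.5 (default), or a constant 0.3.
Source data for these indicators never state their separation factors,
so both standard options are exposed (`a0_rule`) and logged.

The terminal age is closed, q(ω) = 1, with two selectable conventions
for the open-ended person-years:

* `close_with_exposure=True` (default): L(ω) = l(ω)/m(ω) when
  m(ω) > 0, else 0 — the stationary-population identity;
* `close_with_exposure=False`: L(ω) = 0, i.e. the table is truncated
  at exact age ω. This is the convention under which a constant-hazard
  table converges to the truncated exponential integral
  (1 − e^{−μω})/μ.

Both must be used consistently across a period/CAL comparison; mixing
them breaks the stationarity identities. A terminal rate so small that
l(ω)/m(ω) overflows is treated as m(ω) = 0 (L(ω) = 0) rather than
propagating an infinite tail.

## Cross-sectional cohort survivorship and CAL

For reference year t, the cohort reaching exact age x at t is labelled
t−x and its survivorship is the product of one-year survival
probabilities read from the period-rate cells (a, t−x+a), a = 0..x−1 —
period-rate chaining along Lexis diagonals, each year of age attributed
wholly to one calendar year. True cohort triangle rates are a
non-goal: the chaining reconstruction is the standard approach when
long period series exist but cohort series do not. Computing CAL(t)
with ω = 100 therefore needs rates back to year t−100; shorter
histories are a hard error unless an explicitly truncated CAL over
0..AGE is requested (`allow_truncated_to`), which is labelled as such
in the result.

Person-years per age interval are built from adjacent values of the
cross-sectional survivorship, L_c(x) = p_c(x+1) + a(x)·(p_c(x) −
p_c(x+1)), with a(0) evaluated at m(0, t) and the terminal closure at
m(ω, t). Two consequences are deliberate:

* on a time-constant surface the reconstruction reproduces the period
  life table column-for-column, so CAL(t) = e₀ᵖ(t) *bit for bit* (all
  aggregation runs oldest-age-first, matching the T(x) accumulation);
* Σₓ L_c(x) is midpoint-consistent with the trapezoidal integral of
  p_c, so the discrete CAL tracks the continuous definition to second
  order even though p_c is not monotone.

## Sullivan weighting

HE and HCAL share one prevalence schedule π(x, t); they differ only in
the person-years being weighted. Prevalence and person-years must be on
the same single-age grid — there is no silent regridding; mismatched
grids raise with both grids named. Survey schedules usually start at
age 16: ages below the youngest observed age take the youngest observed
value held constant (default) or zero (`extend_below`), and ages above
the oldest observed age hold the oldest value. Both extensions are
recorded in the schedule metadata and contribute zero sampling variance
(their values are carried over, not estimated afresh).

## Prevalence smoothing

Single-age survey prevalence is noisy; `smooth_prevalence` fits a
penalized B-spline (P-spline) to the per-age unhealthy counts with the
per-age totals as binomial trials, on the logit scale. The binomial
family is the exact likelihood for a proportion and coincides with the
Poisson count treatment used by mortality-smoothing packages when π is
small; the divergence matters only at high prevalence ages and is a
deliberate choice.

Numerical details: cubic B-splines on equally spaced knots (one per 5
ages/years) extended beyond the data boundaries rather than clamped, so
the second-order difference penalty's null space is exactly the
straight lines on the link scale — the infinite-penalty limit is a
plain logistic GLM in age. Spans shorter than two knot intervals (e.g.
a two-point year axis) fall back to a clamped low-order basis that
saturates the observed points, which makes a two-year 2D fit separate
exactly into per-year 1D fits. The penalty is chosen by BIC over a
13-point log-spaced grid 10⁻²..10⁴ (each dimension independently in the
2D tensor-product fit); a fixed penalty can be supplied instead. The
fit runs penalized IRLS to a relative deviance tolerance of 1e-9 (100
iterations maximum; non-convergence raises with diagnostics), and
fitted proportions are clipped to [1e-6, 1−1e-6]. Ages with zero totals
are excluded from the likelihood and predicted from the fitted spline.

Series breaks and outliers (a real problem in multi-country survey
panels) are not detected automatically; excluding affected
country-years is the caller's curation decision, and the 1D smoother
exists precisely for series where pooling years is unsafe.

## Uncertainty

All sampling uncertainty is attributed to the health survey; death
rates are treated as fixed. Per-age variance is the binomial
approximation Var(π̂ₓ) = πₓ(1−πₓ)/Nₓ using the *smoothed* proportion
with the *observed* unweighted count (a raw-proportion option exists
for sensitivity), and

    Var(HE) = (1/l₀²) Σₓ L(x)² Var(π̂ₓ),

identically with L_c(x) for HCAL — the natural extension, since the two
sums differ only in their weights. Ages are treated as independent;
smoothing induces cross-age correlation that this ignores, which is why
the test-suite checks the approximation against a survey bootstrap
(agreement within 15% at 500 respondents per age) and its empirical
95% coverage (≥ 90% over 200 replicates). Intervals are normal,
point ± 1.96·SE.

Whether the HE and HCAL intervals overlap is a property of the data,
not of the method: the gap between the two indicators is driven by the
mortality history (which carries no sampling variance here), so with a
strong secular improvement the gap exceeds any realistic survey noise
and the intervals separate. The suite asserts overlap only in the
regime where its premise holds — near-stationary mortality with a
survey of ~120 respondents per single age, the premise being verified
inside the test.

## Synthetic scenarios

The generator stands in for a national mortality database and a health
survey. Mortality is Gompertz–Makeham with a constant annual
improvement factor,

    m(x, t) = (c + a·e^{bx}) · ρ^{t−t₀},

deterministic by design (observed death rates are treated as fixed), with
an optional cohort shock multiplying the rates on one birth cohort's
diagonal over a chosen age range — this is what produces the
non-monotone p_c that distinguishes CAL from a life table. True
prevalence is a logistic in age between a floor and a ceiling; surveys
draw n Bernoulli respondents per single age with optional lognormal
weights, reproducibly under a fixed seed.

The packaged `france_like` scenario (a = 9.762e-5, b = 0.105, c = 0.010,
ρ = 0.98 on years 1905–2015, ω = 100) was calibrated once so that the
final-year period e₀ ≈ 79 and CAL ≈ 74 — a Western-European male scale
with a realistic LE−CAL gap; the large background term supplies the
historical young-age mortality that such a gap requires. These are
generator truths for documentation and testing, not estimates of any
real population.

What passing the synthetic suite shows: the estimators implement their
definitions (verified against brute-force re-derivations and closed
forms), the smoother recovers a smooth monotone curve at survey sample
sizes (MAE < 0.02 at 500 per age), and the variance approximation is
honest under binomial sampling with independent ages. What it does not
show: robustness to real-survey pathologies (panel breaks, mode
effects, harmonization drift, design effects beyond weights), to
mortality-data revisions, or to prevalence curves that are not smooth
in age. Problem sizes throughout (ω = 100, 111-year surfaces, 20–500
replicate Monte-Carlo runs) were chosen as the smallest that exercise
every code path at realistic scale.

## Known limitations

* Single-year age intervals only; no abridged tables, multi-decrement
  tables or forecasting.
* Period-rate chaining, not true cohort triangle rates; the two differ
  slightly in years of rapid within-year mortality change.
* Prevalence-based (Sullivan) measures cannot capture sudden short-term
  health changes regardless of the survivorship used; they describe the
  current stock of health, not transitions.
* The HMD-style reader approximates the open-interval rate by the rate
  at the terminal age, since exposures are not available from a rates
  file.
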
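# Methods

## The problem

Under CD4-threshold eligibility rules, an HIV-positive patient qualifies
for antiretroviral therapy (ART) when their first CD4 count falls below a
cutoff c0 (350 cells/mm^3 in the regime this package models by default)
or when they have advanced clinical disease (WHO Stage III/IV) or are
pregnant. Raising or eliminating the cutoff makes patients presenting at
higher CD4 counts eligible — but eligibility is not initiation: a large
share of eligible patients never start therapy within six months of
diagnosis. The question the package answers is: *if the threshold is
raised to 500, or removed, how many additional patients will actually
start ART within six months?*

## The potential-outcomes model

Three functions drive everything:

- `f_CD4(c)` — the probability mass of first CD4 counts among patients
  presenting for care, estimated empirically on the integer grid 0–999
  (counts are top-coded at 999);
- `f_ART(1)|CD4` — the probability of six-month initiation *if the
  patient's CD4 count is eligible*;
- `f_ART(0)|CD4` — the same probability *if it is not* (initiation then
  happens only through the staging/pregnancy pathway).

The expected number of new initiators when a CD4 range R becomes
eligible is the exact sum over the empirical pmf

    sum_{c in R} f_CD4(c) * [ f_ART(1)|c − f_ART(0)|c ].

No kernel smoothing is applied to `f_CD4`: the estimand is an average
over the empirical presentation distribution, so the integral is a sum.

## Global regression discontinuity

`f_ART(1)` and `f_ART(0)` are both identified from data collected under
a single regime by a *global* regression discontinuity design: a
logistic model over the full CD4 support with an intercept shift at the
threshold and separate slopes per side,

    logit P(start | c) = α + γ·1[c < c0] + β_b·(c − c0)·1[c < c0]
                           + β_a·(c − c0)·1[c ≥ c0].

Centering at c0 makes α the ineligible-side level at the threshold and γ
the eligibility discontinuity — the jump in probability at c0 is
expit(α + γ) − expit(α). The below-side line extended above c0 is the
counterfactual "if eligible" curve; this extrapolation is the model's
load-bearing assumption (linearity in logits away from the observed
eligible range). The fit is the individual-level Bernoulli MLE (Newton,
gradient tolerance 1e-8, max 100 iterations, via statsmodels), with the
covariance from the inverse observed information. One-sided degenerate
outcomes (all initiate / none initiate on a side) are rejected
explicitly as separation. Top-coded records are retained in the global
fit by default (`drop_topcoded` flag available).

Pointwise confidence bands are delta-method on the logit scale:
se(η(c))² = x(c)' V x(c), band = expit(η ± z·se). Built on the logit
scale the band always lies inside (0,1) and its width is monotone in
extrapolation distance; on the probability scale the width also grows
with distance through the policy-relevant range but is eventually
compressed where p approaches 0 — the logit scale is the one on which
monotonicity is a theorem.

A sensitivity upper bound replaces the declining extrapolation with a
flat curve: uptake above c0 held at the eligible prediction *at* c0.
With a negative below-side slope this dominates the extrapolated curve
everywhere above the threshold.

## Local regression discontinuity

For comparison at the threshold only, a *local* estimator: unweighted
(rectangular-kernel) linear probability fits on [c0 − h, c0) and
[c0, c0 + h), gap = difference of the two predictions at c0,
heteroskedasticity-robust (HC1) standard errors, top-coded records
excluded. A count exactly at c0 is ineligible, hence in the above-side
window. Least squares (not logistic) is used locally, matching standard
local-linear RD practice.

The bandwidth h comes from the Imbens–Kalyanaraman plug-in selector:
a Silverman-style pilot window (1.84·sd·n^(−1/5)) gives the running
variable's density and the outcome variance at the cutoff; a global
cubic with a jump estimates the third derivative, setting side-specific
windows for quadratic fits that estimate the second derivatives; the
final rule combines these with the published regularization terms
(2160·σ²/(N·h⁴)) and scales as n^(−1/5). The kernel constant is derived
for the uniform kernel, CK = 144^(1/5) ≈ 2.702, from the boundary
local-linear bias constant C1 = −1/6 and variance constant C2 = 4
(the familiar 3.4375 is the triangular-kernel value). When the cubic's
third derivative is ≈ 0 the second-stage windows are capped at the data
span rather than allowed to diverge.

On real programme data the local gap is attenuated relative to the
global one by *eligibility crossover* — patients just above the
threshold who re-test below it and initiate. The synthetic generator
does not model re-testing, so on generated data the two estimators
agree; the package makes no attempt to reproduce crossover attenuation.

## Policy quantities and uncertainty

For a newly eligible range, the report rows are: (1) percent of
presenters in the range; (2) uptake under the old regime
(pmf-weighted mean of the ineligible curve, conditional on the range);
(3) uptake under expanded criteria (same with the eligible curve);
(4) = (3) − (2) "new initiators"; (5) = 100 − (3); and (6) the percent
increase in programme initiators, (4)/100 × (1)/100 × presenters /
initiators × 100. National projections multiply (6) by the national
initiator count (default 614,000/year) and divide by the national
on-ART population (default 3,000,000). Identities (2)+(4)=(3),
(3)+(5)=100, and additivity of absolute new initiators across adjacent
ranges hold to 1e-9 before any display rounding; rounding (nearest
1,000 for national counts) is display-only.

Interval estimates for rows (3)–(6) come from parametric simulation:
draw coefficient vectors from N(θ̂, V̂), recompute the rows per draw,
report percentile intervals (default 10,000 draws, seeded). Percentile
intervals were chosen over normal approximation because the rows are
nonlinear in the coefficients; they are asymmetric, matching the shape
though not the exact values of intervals obtained on real data.

## The synthetic-data generator

The generator is first-class, tested code; it defines the conditions
under which every calibration claim is made. Defaults emulate the
350-cell regime in a rural South African treatment programme:

- **First CD4**: two-component gamma mixture, weights 0.6301/0.3699,
  shapes 2.5/7.0, scales 135.27/95.0 cells — solved (not fitted to any
  test outcome) so the range masses below 350 / 350–499 / ≥500 are
  exactly 0.411 / 0.200 / 0.389, with a mode near 240 cells and ~4% of
  mass top-coded at 999.
- **Eligible uptake**: logit-linear, 40.8% at the threshold, slope
  −0.00199 per cell solved so mean uptake below 350 is 47.8%.
- **Ineligible uptake**: flat 8% (the staging/pregnancy pathway,
  aggregated rather than simulated via explicit WHO stages).
- **Six months** is fixed as ≤183 days. A CD4 count exactly at the
  threshold is ineligible.
- Presentation dates uniform over 2011-08-12 – 2013-12-31; sex (68.5%
  female), log-normal age (median 30), and ~2.3% missingness are
  cosmetic marginals that play no role in estimation; a small share
  (3.5%) of six-month non-initiators start later when the window
  allows, so that "started by window end" exceeds six-month uptake.

Probability-scale (`LinearUptake`) curves are supported for experiments
needing locally linear truth; parameters whose curves leave [0,1]
anywhere on the integer grid are rejected with the offending CD4 value.

What the generator does *not* emulate: repeat CD4 testing and
eligibility crossover, migration, mortality, temporal trends in
presentation, or any real-data departure from logit-linearity. Passing
recovery and coverage tests therefore demonstrates that the estimators
are correct and calibrated *under the model's assumptions*, not that
the extrapolation assumption holds in any particular programme.

## Problem sizes and numerical choices

Calibration experiments use 200 replicate cohorts of n = 15,000
(coefficient bias, 95% CI coverage accepted in [92%, 98%], band
coverage at CD4 = 500 in [90%, 99%]); local-gap recovery uses one
cohort of n = 50,000 with a true 0.25 gap and bandwidth 100. The
pipeline's end-to-end demonstrations use n = 15,000–19,279. All
randomness descends from a single root seed split per stage with
`numpy.random.SeedSequence`; reruns of the same configuration are
bit-identical (manifests deliberately exclude wall-clock time).

Known limitations: the extrapolation is untestable from within-regime
data (the constant-uptake bound brackets it from above only); the local
estimator's published bandwidth constant is kernel-specific and this
implementation supports the rectangular kernel only; no covariate
adjustment; no fuzzy-RD instruments; no transmission or cost modelling.
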
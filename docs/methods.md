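# Methods

## Effect sizes and pooling

Studies carry a Pearson correlation r and sample size n. Pooling follows
the Hedges–Olkin tradition: analysis on Fisher z = arctanh(r) with
sampling variance 1/(n − 3); inverse-variance weights; the
random-effects model adds the DerSimonian–Laird (DL) τ² (truncated at
zero) to each variance. Means, confidence intervals and prediction
intervals are back-transformed to the r metric; τ² and τ are reported on
the z scale. DL is the default because it is the convention of the
commercial meta-analysis software this battery emulates; a restricted
maximum-likelihood estimator is available via `pool(..., tau2_method="REML")`.

The 90% prediction interval uses a t critical value with k − 2 degrees
of freedom (the Higgins convention): mean ± t₀.₉₅,ₖ₋₂ · √(τ² + se²) on
the z scale.

Two operations deliberately leave the z scale. Outlier/influence
diagnostics run on raw correlations with the large-sample variance
(1 − r²)²/(n − 1), and PET-PEESE runs on raw correlations as well (see
below). An `se_override` on a study replaces the formula variance on
either scale.

The between-group Q test pools each subgroup under the random-effects
model and compares the subgroup means with weights 1/se²; p comes from a
chi-square with (groups − 1) degrees of freedom.

## Influence diagnostics and the outlier rule

For each study the random-effects model is refit without it. Recorded
per study: the externally standardised deleted residual
(y_i − μ̂₍₋ᵢ₎)/√(v_i + τ²₍₋ᵢ₎ + se(μ̂₍₋ᵢ₎)²), DFFITS, Cook's distance
(μ̂ − μ̂₍₋ᵢ₎)²/Var(μ̂), the covariance ratio, τ² and Q without the study,
the leverage h_i = w_i/Σw (which sums to one), and the leave-one-out
pooled mean. These definitions were cross-checked against an independent
reference implementation of the same framework and agree to six decimal
places on a fixture.

A study is flagged as an outlier when its |deleted residual| exceeds the
two-sided normal critical value at α = .05 — Bonferroni-corrected across
the k studies, because with k = 30 clean studies an uncorrected 1.96
cutoff is exceeded by chance in most datasets — AND at least one
influence criterion fires: |DFFITS| > 3·√(1/(k−1)), Cook's distance
above the chi-square(1) median, or leverage above 3/k. Every threshold
is configurable (`OutlierRule`), including pinning an explicit z cutoff.
On clean simulated corpora (τ = 0, k = 30) the rule's per-dataset
false-flag rate is under 10%.

## The publication-bias battery

**Trim-and-fill** (Duval–Tweedie, L estimator) on the z scale. The side
with suppressed studies is either given or chosen automatically from the
sign of the Egger-type small-study slope (weighted meta-regression of
effect on SE). Iteration: fixed-effect center of the currently trimmed
set, Wilcoxon rank statistic of the positive centered deviations
(midranks for ties, so exactly mirror-symmetric data give L0 = 0),
L0 = (4T − k(k+1))/(2k−1) rounded and floored at zero, until stable.
The k0 trimmed studies are mirror-imputed about the final center and the
adjusted mean is the DL random-effects pool of observed plus imputed
studies. FE centering during trimming with an RE final estimate mirrors
common practice in the commercial implementations; the auto-side rule
and rank conventions were verified against an independent rank-based
implementation (identical k0 and adjusted means on a suppressed
fixture).

**A-priori selection models.** The probability that a study is observed
is a fixed step function w(p) of its one-tailed p-value. Two presets are
shipped as versioned constants — the standard "moderate" and "severe"
one-tailed weight vectors over 14 p-intervals with cut-points .005, .01,
.05, .10, .25, .35, .50, .65, .75, .90, .95, .99, .995, 1 — and both
cut-points and weights are user-overridable. The likelihood in (μ, τ²)
on the z scale multiplies each study's normal density by its interval
weight and divides by the per-study normalising constant
Σⱼ wⱼ·P(p ∈ interval j | μ, τ², v_i); it is maximised by Nelder–Mead in
(μ, log τ²). With all weights equal the fit reduces to the ordinary
maximum-likelihood random-effects mean (tested). Fits were verified
against an independent step-function selection-model implementation
(μ, τ², log-likelihood to ~6 decimals). A fit whose variance component
exceeds τ² = 0.25 on the z scale (τ > 0.5, absurd for correlation data)
is marked not-applicable, mirroring the "n/a" convention for nonsensical
solutions.

An important, intentional property: a fixed-weight selection model is a
*sensitivity analysis*, not an unbiased estimator. Fitted to data with
no suppression at all, the moderate one-tailed model shifts the mean
down by about .02 when roughly half the studies are nonsignificant — the
model attributes the observed nonsignificant studies to a filter that
was never applied. The test suite measures and reports this gap rather
than hiding it; under suppression that matches the assumed weights the
model recovers the true mean to well within .02.

**PET-PEESE.** Weighted least squares on raw correlations: PET regresses
r on SE (weights 1/SE²) and PEESE regresses r on SE²; each intercept
estimates the effect of an infinitely precise study. PEESE is selected
when PET's intercept is significantly positive at one-tailed α = .05
(configurable). The SE here uses a common-ρ plug-in variance
(1 − r̄²)²/(n − 1) with r̄ the fixed-effect pooled mean rather than each
study's own r: the per-study formula makes SE a decreasing function of
r, which mechanically induces a negative effect–SE correlation and a
spurious small-study slope (about −0.3 in null simulations) even in
unbiased data. With the plug-in variance the null slope centres on zero.
`se_override` takes precedence, which is also how exact textbook (r, SE)
examples are reproduced.

**p-uniform** (Irwin–Hall moment form). Only studies significant at the
one-tailed .05 threshold enter. At the true μ each conditional
exceedance probability q_i(μ) = P(Z > z_i | Z > z_crit,i) is uniform, so
Σ −ln q_i ~ Gamma(k_sig, 1); the estimate solves Σ −ln q_i = k_sig and
the CI bounds solve the 97.5%/2.5% gamma-quantile equations (bisection
on a bracketed, provably monotone objective; tails computed in log
space). Known behaviour, reproduced in simulation: under heterogeneity
p-uniform overestimates the mean, which is why triangulation excludes it
by default.

**Test of excess significance.** Per-study power of a two-sided α = .05
test given a true effect equal to the RE pooled mean (both the α and the
ρ̂ convention are arguments). E = Σ power_i, O = observed significant
count, A = (O−E)²/E + (O−E)²/(k−E), p from the chi-square(1) upper tail;
p < .1 is the conventional alarm. O = E gives p = 1.

**Cumulative meta-analysis by precision** re-pools after each study,
ordered by n descending (ties broken by id); the final step equals the
full-dataset result. Upward drift as small studies enter is the
suppression signature. **Contour-enhanced funnel data** classifies each
study as clear (p > .10), marginal (.05–.10) or significant (p < .05)
and provides the two-sided boundary geometry for any y-axis
(SE, precision, or 1/SE).

Distributions with fewer than 10 studies are not subjected to the bias
battery (second-order sampling error makes the answers untrustworthy);
their report rows keep the pooled statistics and leave the battery cells
blank. The gate is configurable.

## Triangulation

The estimate set contains the RE and FE means, the min/median/max
one-sample-removed means, trim-and-fill, both selection models, and the
selected PET-PEESE value — nine members when everything is available.
TES never enters (it is a probability); p-uniform joins only on request.
Members marked not-applicable are dropped. BRE and MRE are computed from
the estimates rounded to two decimals (the unrounded percentages are
retained alongside), with the RE mean as the 100% base; percentages are
rounded half-up to integers for reporting. Classification: < 20%
negligible, 20–40% moderate, ≥ 40% large. The boundary at exactly 40% is
assigned to "large" — reporting practice and the verbal rule disagree
here, and the implementation follows reporting practice. Conclusions
read "X difference" when both classes agree, otherwise
"X to Y difference" ordered mild to severe.

The utility helper converts a validity difference into dollars via the
Brogden–Cronbach–Gleser form ΔU = n_hired · years · SDy · Δvalidity ·
z̄_selectees, with SDy = 40% of salary by default and the mean selectee
standard score defaulting to the 85th-percentile value 1.0364 (a plain
z = 1.0 is equally defensible; both are exposed).

## The synthetic-data generator

Candidate studies draw a true effect θ ~ N(μ_z + subgroup offset, τ²) on
the z scale, a sample size from a lognormal with a floor, an observed
z ~ N(θ, 1/(n−3)); the candidate survives with the retention probability
of its one-tailed p-value interval (two-tailed selection is an option).
Rejection sampling continues until exactly k studies are retained, so
the retained corpus is what a literature looks like when authors shelve
null findings; a projected draw count above 10⁶ aborts with a
diagnostic. Same seed, same corpus, bitwise.

Shipped selection presets: none; mild (70% of nonsignificant results
survive); moderate and severe — the a-priori step functions reused as
generating mechanisms, which makes the matching selection model
correctly specified; and a hard journal filter (10% of nonsignificant
results survive).

`paper_like_corpus(seed)` emulates a 113-study validity literature:
μ_z = 0.114, τ = 0.09, lognormal n (median 120, σ = 0.75, floor 30)
targeting a total N near 19.6k, a 60% "journal" subgroup under the hard
journal filter and a 40% "non-journal" subgroup under mild suppression,
plus an 80/20 non-contextualized/contextualized frame-of-reference
label. μ_z was calibrated once so the suppressed corpus's expected
naive RE mean sits near .16; the same calibration then reproduces the
journal vs non-journal contrast (≈ .19 vs ≈ .13) without further tuning.
`suppression_experiment_config(seed)` is the benchmarking preset: true
r = .10, τ = 0, k = 200, severe selection, and a small-study size
distribution (lognormal median 60, σ = 0.6, floor 10) — suppression
only meaningfully biases literatures whose studies are small, so that
is the regime in which estimator recovery is measured.

What the generator does *not* emulate: dependent effect sizes (multiple
correlations per sample), time-lag bias, moderator-correlated sample
sizes, or non-normal true-effect distributions. Passing tests therefore
show that the estimators behave correctly under textbook random-effects
truth with step-function suppression — not that any particular real
literature satisfies those assumptions.

## Numerical choices and conventions

- Rounding for reports: correlations to two decimals, percentages to
  integers (half-up), τ to three decimals; all configurable.
- Selection-model optimisation: Nelder–Mead, x-tolerance 1e−8, start at
  the naive RE fit; τ² parameterised on the log scale.
- p-uniform roots: Brent's method after bracket expansion; failure to
  bracket raises with diagnostics rather than returning a guess.
- Trim-and-fill k0 is capped at k − 2 so at least two studies remain.
- Degenerate influence records (zero residual variance) are flagged and
  skipped by the outlier rule, not dropped from the report.
- Pipeline determinism: identical (input, config, seed) produce
  byte-identical reports.

## Problem sizes used by the test suite

Stochastic checks run at deliberately modest scale chosen to keep the
full suite fast while leaving comfortable Monte-Carlo margins: 500
replicates (k = 100) for null calibration, 200 replicates (k = 200) for
recovery under severe suppression, 25 seeds for the end-to-end corpus
signature, and 150 replicates for the outlier false-flag rate. The
margins quoted in the test docstrings are three Monte-Carlo standard
errors unless stated otherwise.

## Known limitations

- Fixed-weight selection models shift the mean down on truly unbiased
  data (documented above); interpret them as sensitivity bounds.
- Trim-and-fill under real heterogeneity finds spurious asymmetry on
  whichever side noise leans; with τ near the observed-variance scale,
  side="auto" should be read cautiously (the null-calibration test
  fixes the side for exactly this reason).
- p-uniform is reported but excluded from triangulation by default.
- PET-PEESE intercepts extrapolate far outside tiny sub-distributions;
  the k ≥ 10 gate protects reports, but directly calling `pet_peese` on
  a handful of studies can return estimates outside the observed range.
- No psychometric corrections (measurement error, range restriction) —
  the battery operates on observed correlations only.
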
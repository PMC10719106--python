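# Methods

This note documents the models, calibrations and numerical conventions the
package commits to, and what its synthetic-data tests do and do not
establish.

## 1. The randomization law

Stage one is blocked and population-weighted. Within a district, villages
are ranked by **descending** population (ties broken by village id, so the
plan is a pure function of the input table and the seed); consecutive blocks
of four form quadruplets; leftover villages when the count is not divisible
by four are excluded and reported, never silently dropped. Quadruplets are
sampled without replacement by **sequential weighted draws**: at each step a
quadruplet is drawn with probability proportional to its share of the
district population among those remaining, and weights are renormalized.
This particular without-replacement law matters because randomization
inference must re-draw assignments under exactly the law that produced the
data; it is implemented once and shared between the randomizer and the RI
module. Arms are assigned by a uniform permutation of the four arms over the
four villages of each selected quadruplet.

Stage two assigns videos within villages. A placebo village shows everyone
the placebo. A treated village of n participants embeds exactly
`round(0.25·n)` placebos (halves round up; n = 21 gives 5), positions drawn
uniformly without replacement. A fixed count rather than per-participant
Bernoulli draws guarantees the stated 75/25 split in every village and
removes one source of randomization-inference variance. How a field team
resolved the fractional expectation (5.25 of 21) is not documented anywhere;
the count rule is this package's declared convention.

Real-world adjustments of the quadruplet sample "in consultation with
district officials" (travel cost, vaccine availability) are deliberately not
modelled; the package implements the pure weighted draw.

A single master seed spawns independent per-district substreams
(`numpy.random.SeedSequence`), so the plan does not depend on the row order
of the village table.

## 2. The synthetic population

The generator's defaults state the world the analysis suite is tested in.

**Villages.** Populations are log-normal truncated to [30, 5428] with median
1,040 (log-sd 0.7). The log-sd is the one free parameter; 0.7 puts the
truncated mean near 1,290, close to the ~1,268 average reported for the
sampled villages. Six districts of 200 eligible villages each give the
"about 50 quadruplets per district" regime; 13 quadruplets per district
yield 312 trial villages of 21 participants (the real trial had 310 from
uneven district lists).

**Covariates** are drawn independently from marginals matched to the
published phase-I summary table (57.1% female; age truncated at the 18-year
eligibility floor with the underlying normal solved numerically so the
truncated mean/SD equal 37.4/16.4; household size, children, employment,
spending, education, WhatsApp use, clinic distance likewise). No copula is
used: only marginal moments are published, and covariate correlation is not
load-bearing for any estimator under test.

**Outcomes** follow a logistic random-intercept GLMM. For individual i in
village c (district d),

    logit P(Y_ic = 1) = b + β[video_i] + γ_emb[arm_c]·1{embedded placebo}
                        + γ_unt[arm_c]·1{untreated resident}
                        + ω'X_ic + u_c + u_d,

with u_c ~ N(0, σ_v²) and an optional district intercept u_d ~ N(0, σ_d²).
This is the simplest mechanism consistent with the reported logistic
analysis plus village-level ICCs; the source never states its data
generating process.

*ICC calibration.* A village intercept on the logit scale produces a binary
outcome whose ANOVA-scale ICC is smaller than the latent
σ²/(σ² + π²/3). The package computes the observed-scale ICC exactly as
Var(p(U))/(p̄(1−p̄)) by 80-node Gauss–Hermite quadrature and inverts it
(`calibrate_glmm`), solving jointly for the conditional intercept and σ_v
that hit a requested marginal rate *and* observed ICC. Arm effects are
likewise stated as target marginal rates and converted to conditional
log-odds (`OutcomeParams.from_marginal_rates`), so simulated arm rates
reproduce their targets without manual attenuation corrections. Defaults:
intention rates 71.0/72.5/81.7/78.2% at observed ICC 0.15; reported rates
36.3/38.5/41.9/38.1% at ICC 0.06.

*Verified status.* By default the register-verified outcome is the reported
outcome passed through directional misreporting flips (1→0 with probability
0.29, 0→1 with 0.03), chosen so verified (~29%) sits below reported (~38%)
as observed. An `independent` mode instead simulates verification from its
own GLMM — used when a test needs a known verified-arm effect — and adds a
district-level intercept (σ_d = 1.8 by default in that mode): the published
verified ICC of 0.64, far above the other outcomes, plainly reflects
district-level verification heterogeneity (district odds ratios as extreme
as 0.01), which a village intercept alone cannot produce. That reading is
an interpretation, recorded here as such.

**Spillover strata.** Embedded placebos may receive arm-specific spillover
log-odds (default: the verified low-cash stratum is positive, matching the
38.3% vs 26.8% pattern; others null). A never-treated spillover sample
(Poisson mean 3.7 residents per village, ~1,100 overall) carries its own
intercept shift — these residents were not screened to be unvaccinated, so
their reported vaccination is far higher (≈54%).

**Attrition** is missing-at-random given arm and covariates: logit models
with intercepts at the observed retention rates (recontact 4,101/5,900 ≈
0.695; verification 3,075/5,900 ≈ 0.521) and zero arm/covariate effects by
default. Arm-specific covariate coefficients (`recontact_arm_covariates`)
provide a selective-attrition stress mode: additive arm and covariate
effects barely bias an arm contrast, so the mode that matters for testing
inverse-probability weighting is the interaction. A not-at-random mode is
deliberately absent; IPW cannot fix it and a test built on it would not
establish anything.

Reported status is masked unless recontacted; verified status unless found
in the register; the two are independent draws, as phase IV verification did
not depend on phase II/III recontact.

## 3. Estimators

**Contrasts.** Arm groups follow the video actually shown (the published
tables pool embedded placebos into the placebo column). The difference in
proportions uses size-weighted cluster means: per arm, p̂ = Σ n_g ȳ_g / N
with variance G/(G−1)·Σ (n_g/N)²(ȳ_g − p̂)², SE of the difference by
summation, two-sided t with df = G_a + G_b − 2. This reproduces
cluster-adjusted two-sided t-tests without individual-level likelihood
assumptions. The same core (`diff_from_cluster_means`) backs the power
simulator and the RI statistics.

**ICC.** One-way ANOVA estimator on the 0/1 scale with the ANOVA mean
cluster size m̄₀ = (N − Σn_g²/N)/(G−1) — the convention under which the
published 0.15/0.06/0.64 are comparable. The default CI is the
Smith/Swiger large-sample normal interval
Var(ρ̂) = 2(N−1)(1−ρ)²(1+(m̄₀−1)ρ)² / (m̄₀²(N−G)(G−1)); a cluster
percentile bootstrap is available as a fallback for small G. The
latent-scale ICC σ²/(σ²+π²/3) is exposed separately and never mixed with
the observed scale.

**Cluster-robust logit.** IRLS to the binary-logit MLE (relative
log-likelihood tolerance 1e−12), CR1 sandwich with score sums per cluster
and small-sample factor G/(G−1). Which small-sample correction the original
analysis used is unstated; CR1 with a t(G−1) reference for p-values is the
common convention for village-clustered trials and both choices are
switchable (`small_sample`, `use_t`). Odds-ratio CIs use normal quantiles
on the log-odds scale. Quasi-separation (fitted probabilities numerically
0/1) raises a warning rather than an error; rank deficiency names the
offending columns. Covariate scalings follow the published convention (age
per 10 years, weekly food spend per 50 cedis). No multiple-testing
adjustment is applied anywhere, matching the unadjusted reporting.

**IPW.** Retention logits on arm + covariates (optionally arm×covariate
interactions); weights 1/p̂ for retained participants, trimmed by capping at
a weight quantile (default 0.99; 1.0 disables). Weighted contrasts reuse
the cluster-mean core with cluster weights Σw; weighted logits treat w as
case weights in both the IRLS and the sandwich scores.

**Verified coding.** Vaccinations after the incentive window (April 2022)
count as "no"; the generator produces the already-coded binary, and the
estimators take it as given.

## 4. Randomization inference

The sharp-null p-value re-draws the assignment B times (default 2,000) with
outcomes fixed: quadruplet membership and the individual sample are held
fixed (the inference conditions on the realized selection), arms are
re-permuted within quadruplets and embedded-placebo positions re-drawn —
through the very `AssignmentPlan.rerandomize` path the designer uses, which
a seed-replay test asserts. Two-sided via |T|, with the +1 finite-sample
correction, so p ∈ (0, 1]. The source calls its procedure "bootstrapped
simulations"; whether outcomes were resampled or assignments re-drawn is
ambiguous there. This package implements assignment re-randomization and
says so: it is the design-based choice the embedded-placebo structure
supports. A 2,000-trial experiment during development confirmed exact size
(0.049 at nominal 0.05).

## 5. Power

Each replicate assigns arms by blocked permutation, draws village intercepts
at the σ_v matching the requested *observed-scale* ICC, simulates binomial
cluster totals, and tests cash (both cash arms pooled) against placebo with
the cluster-robust t-test. "Effect size" is an absolute risk difference
(0.06 = 6 points), the scale on which the trial reports all contrasts.
Analysis is by assigned village arm and the effect is applied village-wide;
embedded-placebo dilution is out of scope of the pre-registration claim
being reproduced. Defaults for the reproduction — baseline 0.36 (the
placebo reported-vaccination rate) and ICC 0.02 — are declared assumptions:
the registration's own values are not in the public record. The closed-form
cross-check deflates each arm's n by the design effect 1+(m−1)·ICC and
applies the unpooled two-proportion normal approximation; it runs
~0.01–0.02 optimistic against the t-test simulation in the mid-power range,
which the agreement tests budget for explicitly.

## 6. What a green test establishes

The generator reproduces marginal rates, observed-scale clustering,
attrition rates and the printed-count arithmetic of the source. It does not
model covariate correlation, spatial structure, household clustering,
time-varying vaccine availability, or informative (not-at-random)
missingness. Estimator-recovery tests therefore certify the *estimators*
under the stated DGP, not the substantive conclusions of the original
trial; the published covariate-adjusted odds ratios and their CIs depend on
the participant-level data and are not reproducible at desk scale.

## 7. Degenerate inputs and tie-breaks

- Fewer than 4 villages in a district, k greater than the available
  quadruplets, non-finite weights: explicit design errors.
- Constant outcomes make the ICC undefined and raise.
- Arms with fewer than 2 clusters make the between-cluster variance
  undefined and raise.
- SMD with zero pooled SD warns and reports NaN, flagged. The |SMD| = 0.1
  boundary counts as flagged.
- Villages with a single observation are dropped (with a warning) from
  fixed-effects attrition models.
- p̂ = 0 for a retained record is an error in IPW, not a silent infinite
  weight.
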
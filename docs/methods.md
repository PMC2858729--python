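# Methods

## The problem

Patient-reported outcomes (quality of life, pain, fatigue, ...) are measured
with questionnaires of binary items and analysed in one of two traditions:
classical test theory (CTT), which treats the observed sum score as the
measurement, or item response theory (IRT), which models the item responses
as manifestations of a latent trait. When a two-group study is planned with
the conventional normal-theory sample-size formula, the effect size it is fed
lives on one of two different scales — the latent-trait scale or the score
scale — and the two are not interchangeable: the bounded, discrete score
*attenuates* the effect. This package quantifies, by simulation, the power
actually delivered by each analysis strategy, and provides the sample-size
calculators and a pilot-based simulation-validation workflow to plan such
studies.

## Generative model

Responses follow the Rasch (one-parameter logistic) model. Patient *i* with
latent trait θᵢ answers binary item *j* of difficulty δⱼ positively with
probability

    P(X_ij = 1 | θ_i, δ_j) = exp(θ_i − δ_j) / (1 + exp(θ_i − δ_j)),

items being conditionally independent given θ (local independence). The
latent trait is normal within each group with common variance σ²:
θ ~ N(μ₁ + d·g, σ²), g ∈ {0, 1}, so with σ² = 1 the group effect d *is* the
latent-scale effect size ES = d/σ. Simulated banks place the J difficulties
at standard-normal quantiles δⱼ = Φ⁻¹(j/(J+1)): regularly spaced, symmetric,
summing to zero, so the score distribution is near-normal — deliberately
favourable ground for the CTT arm. The quantile rule j/(J+1) (rather than
(j−0.5)/J) was chosen because it keeps the bank's mean at exactly the pooled
latent mean for every J; simulation shows the two placements give power
indistinguishable at Monte-Carlo resolution, so nothing downstream hinges on
the choice. The pooled latent mean is 0 (μ₁ = −d/2, μ₂ = +d/2), centred on
the bank.

Imprecisely known item parameters are modelled by analysing with
δⱼ* = δⱼ + Uniform(−ε, +ε) noise, drawn independently per item and per
replicate dataset; ε = 0 means the published calibration is exact. Drawing
per replicate (rather than once per scenario) treats the calibration error
as part of the sampling variability being averaged over.

## Estimation

The free parameters are estimated by marginal maximum likelihood: the latent
trait is integrated out of each patient's response-pattern likelihood against
its group's normal density. Three analysis regimes mirror practical designs:

* **Situation 1** — μ₁ and all δⱼ fixed (instrument IRT-validated on the same
  population); free: d, σ².
* **Situation 2** — δⱼ fixed, μ₁ estimated (validated on a similar population
  whose latent mean may be shifted); free: μ₁, d, σ².
* **Situation 3** — everything estimated (classically validated instrument);
  free: μ₁, d, σ², δ₁..δ_J under Σδⱼ = 0.

Numerical choices:

* **Quadrature.** Fixed (non-adaptive) Gauss–Hermite with 61 nodes by
  default. The latent density is the integration kernel, so the rule is exact
  for polynomial integrands; with σ near 1 the log-likelihood moves by less
  than 1e−4 between 41 and 81 nodes (tested). Deterministic, so repeated fits
  are bit-identical.
* **Sufficient-statistic aggregation.** In the Rasch model the person-side
  sufficient statistic is the sum score: the pattern-specific factor
  exp(−Σⱼ xᵢⱼδⱼ) leaves the integral, which then depends on (group, score)
  only. Likelihood and gradient are accumulated over the ≤ 2(J+1) cells
  instead of N patients, making a J = 100 fit cost milliseconds.
* **Optimisation.** L-BFGS-B on transformed parameters (log σ) with analytic
  gradients; start values μ₁ = d = 0, σ = 1, and in Situation 3 δ from
  centred per-item logits of the (smoothed) proportions. Convergence:
  relative log-likelihood change below 1e−8, projected gradient below 1e−5,
  at most 500 iterations; hitting the cap sets `converged=False` rather than
  raising.
* **Identifiability.** The likelihood is invariant under adding a constant to
  μ₁ and all δⱼ (tested numerically); Situation 3 therefore imposes Σδⱼ = 0,
  matching the centred simulated banks, with μ₁ absorbing the location.
* **Degenerate items.** An item answered identically by every patient has no
  finite difficulty estimate; in Situation 3 it is excluded from estimation
  and reported on the results object. With N ≥ 100 and the default banks this
  is vanishingly rare.
* **Standard errors.** Inverse of the central-difference Hessian of the
  marginal log-likelihood at the optimum (step 1e−4 on the transformed
  coordinates); σ²'s SE by the delta method from log σ.

The group effect is tested by a two-sided Wald test d̂/SE(d̂) against a
standard normal reference — the large-sample MML convention; users comparing
against t-referenced software should expect slightly more rejections at small
N. An independent cross-check in the test suite fits the identical marginal
likelihood with lme4's adaptive-quadrature binomial GLMM (person random
intercept, items as fixed effects) and agrees with this implementation on d̂,
σ̂ and SE(d̂) to about 1e−4.

## CTT arm and the effect-size scale

The CTT arm scores each patient by the unweighted sum of responses (weights
are supported for instruments that prescribe them), compares groups with the
pooled-variance two-sample t-test, and reports the score-scale effect size
as (mean₂ − mean₁) divided by the **global** (combined-sample) standard
deviation. The global SD is the default because it is the scale a planner
observes without conditioning on group, and because the attenuation ratios it
produces (≈ 0.68 at J = 5, ≈ 0.94 at J = 100, averaged over effects) are the
ones the power results are calibrated against; the pooled within-group SD —
slightly larger under a true effect — is available via `sd="pooled"`.

## Power study

A scenario is (ES, N/group, J, ε, situation, replicates, α, seed). Each
replicate simulates a dataset and runs both arms; power is the proportion of
significant tests among usable replicates. Non-converged fits are excluded
from the denominator and counted — silently treating them as non-significant
would bias power down; in practice convergence failures do not occur at the
study's design sizes. Monte-Carlo 95% CIs use the normal approximation
p̂ ± 1.96√(p̂(1−p̂)/n). Randomness is split counter-style: replicate r of a
scenario seeded s uses `default_rng([s, r])`, so any replicate is
reproducible in isolation and scenarios are embarrassingly parallel.

Default replicates per scenario: 1,000 (CLI-overridable). The acceptance
script and test suite run 200–1,000 replicates per cell, sized so each
reported quantity's Monte-Carlo error is several times smaller than the
tolerance it is compared at.

## Sample-size calculators

`sample_size_normal` inverts the conventional formula
n = 2(z₁₋α/₂ + z₁₋β)²/ES²; `sample_size_ttest` searches for the smallest n
whose *exact* noncentral-t power reaches the target. The two differ by at
most a couple of patients (e.g. 104 vs 105 per group at ES 0.5, 95% power);
both are exposed because published tables mix the conventions.

`pilot_validation` emulates planning from a pilot study: each replicate draws
d, σ and every δⱼ independently and uniformly from their pilot 95% CIs
(uncertainty propagation by parameter draws; the uniform is a deliberately
simple, conservative spread), simulates the candidate study, and analyses
with a Situation-3 fit and the score t-test. Its key behaviour, exercised in
the tests: a sample size computed from the *score-scale* effect size the
instrument actually yields delivers the target power in both arms, whereas
the size computed from the latent effect size falls measurably short —
attenuation is the planning trap. `make_synthetic_pilot` supplies a test
fixture (synthetic, not real pilot data): 8 centred items scaled by the
latent SD with NHP-like summary values.

## What the generator does and does not emulate

Simulated data are complete (no missing responses), unidimensional, strictly
Rasch (equal discrimination, no guessing), with symmetric well-targeted item
banks and exactly normal latent traits. Passing tests therefore speak to
power and attenuation under near-ideal psychometric conditions; they say
nothing about robustness to skewed scores, off-target or polytomous items,
differential item functioning, or informative missingness. Polytomous models
(Partial Credit, Rating Scale), longitudinal designs and missing-data
handling are out of scope.

## Known limitations

* The Wald test's normal reference is mildly anti-conservative at small N;
  type-I error at N = 100, J = 10 measures ≈ 0.047–0.055 at α = 0.05.
* Situation-3 fits estimate J + 2 free parameters; at very small N with long
  questionnaires the observed-information SEs can be noisy.
* No closed-form IRT sample-size formula incorporating J is offered — the
  simulation engine *is* the planning tool for that question.
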
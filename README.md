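# raschpower

Power and sample-size analysis for two-group studies of patient-reported
outcomes (PROs), comparing the two standard analysis strategies:

* **IRT** — a Rasch model with a group effect on the latent trait, fitted by
  marginal maximum likelihood (MML), the effect tested by a Wald test;
* **CTT** — the observed sum score, compared between groups by a two-sample
  t-test.

It is aimed at biostatisticians planning studies whose endpoint is a
questionnaire of binary items (quality of life, pain, fatigue, ...): the
conventional sample-size formula n = 2(z₁₋α/₂ + z₁₋β)²/ES² needs an effect
size, and for a questionnaire that effect size lives on two different scales.
On the latent-trait scale θ (with θ ~ N(μ₁ + d·g, σ²) across groups
g ∈ {0,1} and item responses P(X=1|θ,δⱼ) = exp(θ−δⱼ)/(1+exp(θ−δⱼ))), the
effect size is ES_IRT = d/σ. On the score scale it is the standardized group
difference of sum scores, ES_CTT — systematically *attenuated* relative to
ES_IRT because the score is a bounded, discrete surrogate for θ. The package
quantifies by simulation how much power each strategy actually delivers for a
given (ES_IRT, N, number of items J, item-calibration precision ε, analysis
regime), and validates candidate sample sizes by simulation from pilot-study
estimates.

## Worked example

```python
import numpy as np
import raschpower as rp

# a 10-item questionnaire, medium latent effect, 100 patients/group
bank = rp.make_item_difficulties(10)
population = rp.latent_spec_from_effect_size(0.5)
rng = np.random.default_rng(1)
traits, groups = rp.simulate_latent_traits(population, 100, rng)
data = rp.simulate_responses(traits, groups, bank, rng)

fit = rp.RaschModel(data, spec=rp.FitSpecification(
    situation=2, fixed_difficulties=bank.difficulties)).fit()
print(fit.summary())
print(fit.wald_test(alpha=0.05))

scores = rp.compute_scores(data)
print("ES_CTT:", round(rp.ctt_effect_size(scores), 3))
```

prints

```
Rasch model, marginal maximum likelihood
======================================================
Situation:            2
Patients:             200  (group sizes 100/100)
Items used:           10
Quadrature nodes:     61
Log-likelihood:       -1208.6288
Converged:            True (6 iterations)
------------------------------------------------------
parameter       estimate     std err
mu1              -0.3621      0.1173
d (group)         0.6064      0.1661
sigma2            0.8444      0.1538
======================================================
TestResult(statistic=3.6504..., p_value=0.0002617..., alpha=0.05,
           significant=True, method='wald')
ES_CTT: 0.505
```

The Wald test rejects (d̂ = 0.61, SE 0.17). In this particular sample the
score-scale effect size (0.505) happens to sit near the latent 0.5; averaged
over replications it is attenuated (to about 93% of ES_IRT at J = 10).

Power for a whole scenario, and the planning calculators:

```python
result = rp.run_scenario(rp.ScenarioConfig(
    es_irt=0.5, n_per_group=100, n_items=5, situation=2,
    n_replicates=1000, seed=42))
print(round(result.power_irt, 3), round(result.power_ctt, 3),
      round(result.expected_power_normal, 3))
# 0.717 0.713 0.942   <- both arms deliver ~0.71, far below the naive 0.942

rp.sample_size_normal(0.271, alpha=0.05, power=0.90)   # 287 per group
rp.sample_size_ttest(0.5, alpha=0.05, power=0.95)      # 105 per group
```

With only J = 5 items, both analysis strategies deliver about 0.70 power
where the normal-theory formula fed with the latent effect size promises
0.942 — the central planning trap this package exposes.

The same engine is scriptable from the shell:

```bash
pro-power scenario --es 0.5 --n 100 --items 5 --situation 2 --reps 1000 \
          --seed 42 --out results.csv
pro-power grid --config src/raschpower/examples/situation2_grid.yaml --out grid.csv
pro-power samplesize --es 0.271 --power 0.90
pro-power validate --pilot pilot.yaml --n 287 --reps 1000 --seed 7
pro-power analyze --data responses.csv
```

Every result table gets a JSON manifest (command, config, version, seed) that
reproduces it bit-for-bit.

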
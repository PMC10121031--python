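# camcooccur

Two-species occupancy modelling and diel-activity-overlap analysis for
camera-trap surveys, built for the kind of question small-carnivore
ecologists ask of sparse photo data: do two sympatric species use the same
sites, and if they do, do they avoid each other in time instead?

The package takes a raw photo-record table (station, species, timestamp),
camera deployment intervals and a station covariate table, and carries the
analysis end to end:

* **Detection histories** — collapse photo bursts into independent records
  (a record is kept only if more than 60 minutes after the last kept record
  of that species at that station), then stack a multi-year study into
  station × 120-day survey rows, each split into 10 occasions of 12 days,
  with a per-occasion effort matrix and missing cells where cameras were off.
* **Spatial co-occurrence** — a two-species occupancy model in which the
  latent presence pair Z = (z₁, z₂) follows a multivariate Bernoulli
  distribution over {11, 10, 01, 00} parameterised by natural (log-odds)
  parameters

  f₁ = log(ψ₁₀/ψ₀₀) = x′α,  f₂ = log(ψ₀₁/ψ₀₀) = x′β,
  f₁₂ = log(ψ₁₁ψ₀₀ / ψ₀₁ψ₁₀) = x′γ

  with imperfect detection (logit-linear in effort or site covariates)
  marginalised per site. f₁₂ is the co-occurrence log odds-ratio; fixing it
  at 0 gives the independence null. Models are fitted by maximum likelihood,
  screened for collinear covariates (Spearman |ρ| ≥ 0.7), and ranked by AIC
  with Akaike weights; Wald 95% intervals flag important covariates.
  Marginal (ψ₁₁+ψ₁₀) and conditional (ψ₁₁/(ψ₁₁+ψ₀₁), …) occupancy are
  predicted over covariate grids.
* **Temporal overlap** — capture times mapped to the clock circle, von Mises
  kernel densities with the plug-in bandwidth rule, the coefficient of
  overlap Δ̂ (integral of the pointwise minimum of the two densities; the
  small-sample Δ̂₁ estimator below 75 records per species, Δ̂₄ above),
  smoothed-bootstrap confidence intervals, activity levels with a Wald
  comparison, and a kernel randomization test of equal activity patterns.
* **Synthetic studies** — a seeded generator (`camcooccur.synth`) that
  produces record/deployment/covariate tables with the full statistical
  structure above and returns the latent truth, so every stage is testable
  without any field data.

## Worked example

```python
from camcooccur import SimulationConfig, simulate_study
from camcooccur.activity import CircularSample, bootstrap_ci, randomization_test
from camcooccur.detections import filter_independent_records

study = simulate_study(SimulationConfig(seed=5))          # a 24-station study
records = filter_independent_records(study.records)

tiger_cat = CircularSample.from_records(records, "tiger_cat")
jaguarundi = CircularSample.from_records(records, "jaguarundi")

ov = bootstrap_ci(tiger_cat, jaguarundi, n_boot=2000, seed=5)
print(ov.estimator, round(ov.delta_hat, 2), [round(c, 2) for c in ov.ci])
# Dhat1 0.52 [0.35, 0.59]
rand = randomization_test(tiger_cat, jaguarundi, n_iter=2000, seed=5)
print(round(rand.null_summary, 2), rand.p_value)
# 0.91 0.0
```

The two simulated felids (one nocturnal, one diurnal) share only about half
of their diel activity (Δ̂₁ = 0.52, 95% CI 0.35–0.59), far below the null
expectation for a shared pattern (0.91), and the randomization test rejects
equal activity patterns (P < 0.001). The `examples/` directory holds one
short narrative script per capability — detection histories, the
co-occurrence model, activity overlap, and the full pipeline — each printing
the numbers it computes and what they mean.

A thin command-line interface mirrors the stages:

```bash
camcooccur simulate --seed 3 --out study/
camcooccur build-histories --records study/records.csv \
    --deployments study/deployments.csv --covariates study/covariates.csv \
    --start 2018-08-01 --out histories/
camcooccur activity-overlap --records study/records.csv \
    --pairs tiger_cat:jaguarundi --nboot 10000 --seed 42
```

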
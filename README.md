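# nestperm

Hierarchical randomization tests for nested experimental designs.

Most biomedical data is nested — images within wells, wells within animals,
trials within subjects — yet it is routinely analyzed either by treating
correlated observations as independent samples (pseudoreplication, which
inflates false-positive rates) or by collapsing each cluster to a single
mean (which discards the within-cluster information).  `nestperm` is for
experimentalists and biostatisticians who want calibrated p-values and
effect-size confidence intervals on such designs without distributional
assumptions, especially at the 3–5 clusters per group typical of bench
experiments, where both asymptotic tests and mixed models misbehave.

## The method

The experimental design is read off the column order of a long-format
table: label columns run from the outermost level to the innermost, the
response is the last column, and the user names the treatment column.
Given a design such as `Mouse > Treatment > Well > Image`, the test

1. aggregates to one mean per treated entity (here: per well) and computes
   the observed statistic;
2. builds an empirical null by hierarchically bootstrapping each entity's
   nested observations and, per bootstrap replicate, permuting the
   treatment labels — only within blocks (here: within each mouse), since
   labels are exchangeable only at the level where treatment was
   randomized;
3. reports the fraction of resampled statistics as or more extreme than
   the observed one: the two-tailed p-value.

Two approximately pivotal statistics are available: the Welch-form
`t = (B̄−Ā)/√(s²_B/n_B + s²_A/n_A)` for two groups, and for multi-group /
regression nulls the studentized covariance `T = Q/√(S²(Q))`, where
`Q = n·μ₁₁/(n−1)` is the sample covariance of treatment codes and
responses and `S²(Q)` a bias-corrected moment estimate of its variance.
On balanced two-group data the two give identical p-values.  Confidence
intervals come from test inversion: the set of effect sizes `b` the
shifted test `H0: β = b` does not reject, with bounds located by a seeded
bisection.  See `docs/methods.md` for the full account.

## Worked example

Simulate a four-level experiment — 3 mice, 2 treatments per mouse, 3 wells
per treatment, 3 measurements per well, a true effect of β = 2 — and test
it (the same calls work on any CSV/TSV laid out as described above):

```python
from nestperm.synthetic import SimulationModel, generate_dataset

model = SimulationModel(n_blocks=3, clusters_per_group=3, obs_per_cluster=3,
                        beta=2.0, icc=0.5)
generate_dataset(model, seed=42).data.to_csv("example.csv", index=False)
```

```bash
nestperm test example.csv --treatment-level 2 --permutations all \
    --bootstraps 100 --seed 7
```

```json
{
  "statistic": "t",
  "observed": 3.828887690249157,
  "p_two_tailed": 0.00059,
  "beta_hat": 1.7861907925876224,
  "se_beta": 0.46650383534007245,
  "n_bootstraps": 100,
  "n_permutations_per_bootstrap": 8000,
  "n_null": 800000,
  "total_distinct_permutations": 8000,
  "achievable_alpha": 0.00025
}
```

Treatment labels were permuted within each mouse only (20 arrangements per
mouse, 20³ = 8000 in total, all enumerated), wells were rebuilt by
resampling their measurements, and 100 bootstraps × 8000 permutations gave
an 800,000-value null; 0.059% of it was as extreme as the observed t of
3.83, and the estimated effect is β̂ ≈ 1.79 (true value 2).  The same
design inverts to a confidence interval:

```bash
nestperm ci example.csv --treatment-level 2 --permutations all \
    --bootstraps 100 --seed 7 --level 0.95
```

```json
{ "lower": 1.031766621373599, "upper": 2.5260367189472683,
  "beta_hat": 1.7861907925876224, "level": 0.95 }
```

The 95% interval (1.03, 2.53) contains the true effect.  The same
functionality is available in-process via `nestperm.hypothesis_test` and
`nestperm.confidence_interval`, and `nestperm simulate` runs whole
calibration studies from a YAML config.

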
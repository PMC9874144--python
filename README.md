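# mindpls

Behavioral partial least squares (PLS) analysis linking **trait-mindfulness
facets** to **longitudinal cognitive change** and **regional amyloid/tau PET
burden** in older adults at risk for Alzheimer's disease.

The package is for researchers who have (a) Five Facet Mindfulness
Questionnaire (FFMQ-39) item responses, (b) repeated cognitive index scores
(RBANS-style, standardized to mean 100 / SD 15), (c) wide regional SUVR
tables on the Desikan–Killiany atlas, and (d) a covariate table — and who
want the full multivariate pipeline: questionnaire scoring with imputation
and exclusion rules, mixed-model slope extraction, cross-block SVD with
permutation and bootstrap inference, and latent-score covariate adjustment.
A synthetic-cohort generator with a planted latent effect makes every stage
testable without access-restricted study data.

## The method

For a column-standardized behaviour block `X` (n × 5 facet z-scores) and
outcome block `Y` (n × q slopes or SUVRs), behavioral PLS decomposes the
cross-block correlation matrix

```
R = XᵀY/(n−1) = U S Vᵀ
```

Each latent variable (LV) *i* is a triple (singular value *sᵢ*, behaviour
saliences *uᵢ*, outcome saliences *vᵢ*); LV *i* explains
`100·sᵢ²/Σⱼsⱼ²` percent of the cross-block variance. Inference:

* **Permutation test** — rows of `Y` permuted, null singular values compared
  rank-for-rank, add-one p-values `(1+#{null ≥ obs})/(1+n_perm)`.
* **Bootstrap stability** — subjects resampled with replacement; each
  resample's decomposition is Procrustes-aligned to the original before the
  salience SDs are taken as bootstrap SEs. A facet is stable when
  `u ± SE` excludes zero; an outcome column when its bootstrap ratio
  `|v/SE(v)|` exceeds 1.96.
* **Latent scores** — `Lx = XU`, `Ly = YV`; their per-LV Pearson correlation
  summarizes the multivariate association, and the LV1 scores feed an OLS
  model adjusting for age, sex, education, APOE-ε4 and the
  questionnaire-to-baseline delay (standardized β reported).

Per-subject cognitive change scores come from a linear mixed-effects model
per index (`score ~ 1 + time`, correlated random intercept and slope, REML),
returning BLUP slopes; a per-subject OLS estimator is also available.

## Worked example

```python
from mindpls import (CohortConfig, generate_cohort, score_ffmq, standardize_facets,
                     fit_trajectories, align_slopes_to_facets, BehavioralPLS)

cohort = generate_cohort(CohortConfig(n_subjects=261, seed=7))
facets = standardize_facets(score_ffmq(cohort.item_responses))
slopes = fit_trajectories(cohort.cognition_long, method="lmm")
y, x = align_slopes_to_facets(slopes, facets)
res = BehavioralPLS.from_dataframes(x, y).fit(n_perm=1000, n_boot=1000, seed=11)
print(res.lv_table().round(4))
```

```
    singular_value  pct_crossblock  perm_p  latent_corr
lv
1           0.8119         96.4999  0.0010       0.4927
2           0.1264          2.3394  0.9461       0.1459
3           0.0749          0.8213  0.9700       0.0858
4           0.0472          0.3267  0.8761       0.0556
5           0.0093          0.0128  0.9301       0.0108
```

One dominant latent variable (96.5% of cross-block variance, permutation
p ≈ .001): the planted mindfulness–cognition association. Its facet profile:

```
print(res.behavior_table(0).round(3))
                       salience  boot_se  significant
variable
observing                 0.076    0.112        False
describing                0.531    0.094         True
acting_with_awareness     0.349    0.110         True
nonjudgment               0.662    0.082         True
nonreactivity             0.389    0.105         True
```

Nonjudgment and describing carry the largest weights, mirroring the planted
salience; `observing`'s interval covers zero, so it is not a stable
contributor. The LV1 latent-score correlation (0.49) stays significant after
covariate adjustment (`adjusted_association`: β = 0.484, t = 8.99, n = 261).

The same pipeline runs from the shell:

```
mindpls simulate --seed 3 --out cohort/
mindpls run-all --seed 2 --out results/
```

## Layout

| module | contents |
| --- | --- |
| `mindpls.ffmq` | FFMQ-39 scoring, imputation, exclusion, z-scoring |
| `mindpls.trajectories` | mixed-model / OLS slope extraction, block alignment |
| `mindpls.pls` | `BehavioralPLS` model + results, decomposition, permutation, bootstrap |
| `mindpls.adjust` | covariate-adjusted latent-score models, facet–psych correlations, augmented PLS |
| `mindpls.regions` | amyloid/tau region sets and SUVR table validation |
| `mindpls.simulate` | synthetic cohorts with a planted latent effect |
| `mindpls.pipeline` | `run_all` orchestration, subgroup filters, report bundle |
| `mindpls.cli` | `mindpls` command-line interface |
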
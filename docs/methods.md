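# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical choices and the known limitations of `mindpls`.

## Behavioral PLS correlation

Given a behaviour block `X` (n subjects × p = 5 z-scored mindfulness facets)
and an outcome block `Y` (n × q; q = 6 cognitive change scores, 38 amyloid
SUVRs, or 14 tau SUVRs), the cross-block correlation matrix
`R = XᵀY/(n−1)` is decomposed by SVD into `k = min(p, q)` latent variables.
Both blocks are column-standardized (sample SD, ddof = 1) so that `R` is a
correlation matrix; the `crossblock_decompose` contract *checks*
standardization (|mean| ≤ 1e−6, |SD−1| ≤ 1e−3) rather than silently redoing
it, so unit mismatches surface as errors. A raw-covariance analysis can be
run by standardizing differently upstream; the package default is the
correlation scale because the analysis summaries (latent-score Pearson
correlations, standardized β) are correlation-scale quantities.

Sign convention: SVD signs are arbitrary, so each LV is flipped jointly
(`uᵢ, vᵢ`) to make the largest-magnitude behaviour salience positive. This
gives deterministic output; the first LV's latent-score correlation is
automatically nonnegative because `corr(Xu₁, Yv₁) ∝ u₁ᵀRv₁ = s₁ ≥ 0`.

### Permutation inference

Rows of `Y` are permuted with `X` fixed — the standard behavioural-PLS
scheme: it breaks cross-block association while preserving each block's
internal correlation structure. Null singular values are compared
rank-for-rank to the observed ones (no Procrustes correction of null
decompositions; this choice is deliberate and documented here because other
implementations differ). P-values use the add-one rule
`(1+#{null ≥ obs})/(1+n_perm)`, which is never exactly zero and is slightly
conservative. Defaults: `n_perm = 1000`, α = 0.05. Note that under a
complete null the rank-matched p-values of *every* LV are approximately
uniform, so family-wise error over all LVs and analyses is larger than the
per-LV 5%; the pipeline's significance reporting is per-LV.

### Bootstrap stability

Subjects are resampled with replacement jointly across blocks
(`n_boot = 1000` default); each resample is re-standardized and decomposed,
then aligned to the original decomposition with an orthogonal Procrustes
rotation computed on the behaviour saliences and applied to both salience
sets (this absorbs sign flips and axis rotations that would otherwise
inflate the SEs). Bootstrap SEs are the across-resample SDs of the aligned
saliences. Stability criteria:

* behaviour facet: `u ± se_multiplier·SE` excludes zero. The default
  `se_multiplier = 1.0` encodes a literal "SE does not overlap zero"
  criterion; set 1.96 for a CI-style rule.
* outcome column: bootstrap ratio `|v/SE(v)| > 1.96`, applied two-sided on
  the signed ratio.

Resamples in which any column is constant (possible at small n) are redrawn
and counted; more than 100 consecutive degenerate draws aborts.

### Latent scores and covariate adjustment

Weighted scores `Lx = XU`, `Ly = YV` are computed from the standardized
blocks — the same matrices entering `R` — for internal geometric
consistency (the facet block is z-scored by construction; a raw-data
projection can be obtained by multiplying saliences into unstandardized
data directly). The LV1 scores enter an OLS model
`z(Ly₁) ~ z(Lx₁) + covariates` with age, sex, education years, APOE-ε4 and
questionnaire-to-baseline delay as defaults; continuous covariates are
z-scored, binary ones left as 0/1, so the reported coefficient is a
standardized β (equal to the Pearson correlation of the two scores when no
covariates are included). Only LV1 is carried into adjustment by default
because it dominates the cross-block variance in all planted and realistic
configurations; the `adjust` functions accept any LV's scores. Complete
cases only, with the dropped count recorded.

## Trajectory model

Per cognitive index, `score ~ 1 + time` with correlated random intercept and
random slope per subject, fitted by REML (statsmodels `MixedLM`). The
per-subject change score is the conditional (BLUP) slope — fixed slope plus
predicted random slope — because the PLS needs subject-level variation and
BLUPs are the minimum-MSE subject-level estimates. On convergence failure
the model is refit with independent random effects; failure of both raises,
naming the index. Single-visit subjects are retained under the mixed model
(their slopes shrink toward the fixed effect, informed by the estimated
intercept–slope covariance). The OLS estimator (`method="ols"`) fits each
subject independently and requires ≥2 distinct time points; single-visit
subjects are dropped with a logged count by default. BLUP slopes never have
larger variance than OLS slopes on the same data, and the two coincide as
residual variance vanishes — both properties are tested. Time is years from
each subject's own baseline; no practice-effect terms or within-model
covariates are included.

## Synthetic cohorts

The generator emulates an aging observational cohort (defaults n = 261;
PET subsample fraction 124/261) with marginals matching the study's
descriptive table: facet means/SDs (e.g. nonreactivity 23.11 ± 4.75),
per-index baseline scores near 100 ± 10–15, amyloid SUVR 1.34 ± 0.34, tau
SUVR 1.07 ± 0.14, age 67.3 ± 5.2, 71% female, 38.7% APOE-ε4, 4.6% incident
MCI, questionnaire administered ≈1429 ± 621 days after baseline.

Cross-block structure: one standard-normal latent factor `f` per subject.
For a block with unit-norm planted salience `a` (length m) and effect size
`r ∈ [0, 1)`, each standardized column is
`z_j = c_j f + √(1−c_j²) ε_j` with `c_j = √r · a_j · √m`, validated
`|c_j| ≤ 1`. This keeps every marginal SD exact while making the
between-block population correlation matrix rank-one and proportional to
the outer product of the planted saliences, so the planted salience is
exactly the population singular vector and `r = 0` gives full independence.
Under this scaling the LV1 latent-score correlation grows with both `r` and
block widths (≈0.5 at the default `r = 0.25` for 5 × 6 blocks), so `r`
should be read as a per-column variance share, not as the latent-score
correlation itself. Separate effect sizes per outcome block
(`cognition_effect_r`, `abeta_effect_r`, `tau_effect_r`) default to
`latent_effect_r`. Default planted saliences emphasize
nonjudgment/describing/nonreactivity on the behaviour side and are uniform
negative over PET regions (higher mindfulness ↔ lower burden).

Item responses are reconstructed from the target subscale totals: the total
is rounded to the nearest attainable integer, split evenly across the
subscale's items with the remainder on the first items, and reverse-keyed
items stored as `6 − value`; the scorer inverts this exactly, and the
quantization adds at most ±0.5 points of uniform noise to a total. The real
cohort's item-level response distribution is unknown; this scheme is a
construction device, not a claim about item behaviour, so item-level
psychometrics (inter-item correlations, reliability) of generated data are
not realistic even though subscale-level marginals are.

Visit schedule: baseline always observed; year 1 retained with probability
0.985, each later year with probability 0.87 (geometric dropout, cap 7
years), giving ≈98.5% of subjects with ≥2 visits and a median follow-up of
5 years (range 0–7). Visit scores are baseline + slope·t + N(0, 5²)
residuals; the 5-point residual SD is a realistic repeat-testing noise level
for standardized cognitive indices. Covariates are independent of `f` by
default; `age_confounding` and `psych_loading` knobs tie age or the nine
psychological variables to the factor for adjustment/augmentation tests.
SUVRs are clipped below at 0.01 (an ≈4σ event for amyloid, negligible for
the marginals) to keep them positive.

What passing tests show — and do not show: recovery and calibration results
demonstrate correctness of the estimators under this generative model
(shared single factor, linear trajectories, Gaussian noise, independent
items given the total). Real questionnaire, cognitive and PET data have
skewed SUVR distributions, floor/ceiling effects, informative dropout and
multi-factor structure that the generator deliberately omits.

## Region sets

The tau outcome block is fixed by its anatomical definition: 7 bilateral
early-Braak regions (entorhinal; amygdala, fusiform, parahippocampal,
lingual; inferior and middle temporal), 14 columns, hippocampus excluded
for choroid-plexus off-target binding. The 19-region amyloid set covers the
lateral/medial prefrontal, parietal, lateral-temporal and cingulate
families of a global-amyloid composite; because composite membership varies
between pipelines, it ships as editable YAML and the validator reorders and
checks any user table against whichever set is loaded. Column naming:
`ctx-<hemi>-<label>` for cortical, `<hemi>-<label>` for subcortical.

## Problem sizes and determinism

Monte-Carlo test sizes were chosen to give stable verdicts at desk scale:
permutation calibration uses 500 null cohorts of n = 200 with 200
permutations each (the observed LV1 rejection rate must lie in
[0.03, 0.07]); salience recovery uses 100 cohorts of n = 250 at r = 0.25
(≥90 of 100 must exceed |cosine| 0.9 against truth); both run the honest
path from raw tables through scoring and OLS slope extraction. All
randomness flows through `numpy.random.default_rng` seeds carried in
configs; the full pipeline is a pure function of (inputs, config, seed),
and a rerun with identical settings is byte-identical, including the JSON
report. Analysis-level seeds are spawned deterministically from the
top-level seed via `SeedSequence`.

## Limitations

* The mixed-model specification (REML, correlated intercept/slope, no
  covariates) is the package's declared choice of standard trajectory
  model; other random-effect structures are not exposed.
* No mean-centered task PLS, multi-group PLS or split-half reliability
  variants; no multiple-testing correction across the complementary
  facet–psych correlation table.
* No image-level processing: SUVRs enter at region level, reference-region
  handling is upstream.
* The questionnaire exclusion rule (>10% missing) is applied over the whole
  39-item form; a per-subscale variant can be emulated by raising
  `exclusion_threshold` and pre-filtering, but is not built in.
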
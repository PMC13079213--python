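# Methods

## Scope and model

`gxescreen` estimates how a dichotomised polygenic risk score (G) and a
dichotomised childhood-adversity exposure (E) combine on binary
psychopathology phenotypes. All inference is built on covariate-adjusted
binary logistic regression fitted by maximum likelihood on complete cases
for each model's columns; interaction statistics are functions of the
fitted coefficient vector and its variance–covariance matrix.

With coefficients β₁ (G), β₂ (E), β₃ (G×E), the joint odds ratios relative
to the doubly unexposed group are OR₁₀ = e^β₁, OR₀₁ = e^β₂,
OR₁₁ = e^(β₁+β₂+β₃). The additive interaction is
RERI = OR₁₁ − OR₁₀ − OR₀₁ + 1, whose variance is propagated with a
first-order delta method using gradient
h = (OR₁₁−OR₁₀, OR₁₁−OR₀₁, OR₁₁) over the 3×3 covariance block of
(β₁, β₂, β₃) — the gradient is zero for all other coefficients, so using
the block is exact, not an approximation. The multiplicative interaction is
β₃ itself. Both receive Wald tests; p-values and confidence intervals use
the normal reference distribution with a 1.96 multiplier. RERI additionally
decomposes the joint excess risk: (OR₁₀−1) + (OR₀₁−1) + RERI = OR₁₁ − 1,
the quantity behind the exported decomposition table.

Classification conventions: an additive interaction whose 95% CI spans
zero is reported as "none"; otherwise the RERI sign is compared with the
sign of OR₁₁ − 1 (synergistic when concordant, antagonistic when
discordant) — the comparison is made on the excess-risk scale because odds
ratios themselves are always positive. A multiplicative interaction is
classified by the sign of β₃ alone (positive: adversity effects amplified
at high genetic risk; negative: attenuated, a ceiling-type pattern).

## Exposure derivation

Adversity comes from five ordinal items (levels 0 "Never true" … 4 "Very
often true"). The three abuse items are endorsed at levels ≥ 2; the two
reverse-keyed neglect items (felt loved; taken to the doctor when needed)
are endorsed at levels ≤ 1. `any_ace` is 1 when at least one observed item
is endorsed; `ace_count` sums endorsed items over observed items (0–5).
Participants with all five items missing are excluded with an exclusion
record; participants with partial missingness are classified from observed
items only, so `any_ace = 0` asserts only that no *observed* item was
endorsed. "Prefer not to answer"-style codes should be recoded to missing
upstream.

The polygenic score aggregates an n×10 matrix of per-threshold scores:
columns are centred and scaled (sample SD, ddof=1), the first principal
component of the resulting correlation matrix is taken, its sign is
aligned so the component correlates positively with the row-wise mean of
the standardised columns (ties broken toward a positive loading sum), and
the component is re-standardised to mean 0 / SD 1 over the analysis
sample. The alignment never references an outcome. It pins the
orientation deterministically; the score is *equivariant* under global
negation of the inputs (score(−X) = −score(X)), which is the correct
behaviour since negating all columns reverses what "high" means. The
standardisation is done once over the full analysis sample, not per
model-specific complete-case subset. Dichotomisation uses the
linear-interpolation 75th percentile with a strict ">" rule, so ties at
the threshold fall into the low-risk group and a constant score vector has
an empty high group; the rule is deterministic and seed-free.

Symptom phenotypes are binary items (rule `direct`), ordinal items cut at
a registered threshold (`ordinal_threshold`), or continuous cognition
scores dichotomised at a configurable impairment quantile
(`quantile_impairment`, default lowest quartile, scores ≤ the quantile
coded impaired). Domain endorsement is 1 if any member symptom is 1, 0 if
all observed members are 0, and missing only when every member is missing
(the retention-maximising convention). A single-symptom domain is one
distinct phenotype counted at both levels, which is how 55 symptoms and 7
domains yield 61 distinct phenotypes.

## Screening cascade

Stage 1 fits one logistic model per phenotype × exposure (adversity plus
one PRS per disorder = 3 exposures) with all covariates adjusted; the
univariate Bonferroni level is α/(n_phenotypes × 3), recomputed from the
realized catalog so reduced synthetic catalogs stay consistent. Stage 2
selects, per PRS, the phenotypes significant for both that PRS and
adversity, and fits joint main-effect models. Stage 3 adds the product
term and computes both interaction statistics; the per-PRS interaction
tier uses α divided by the realized selection count for that PRS, with a
nominal tier at 0.05. Sensitivity analyses (all toggled off by default):
covariate×G and covariate×E product terms added to the interaction model
(Keller-style adjustment); adversity-count dose–response models per domain
(linear count by default, per-level categorical optionally); per-type
models for the five adversity flags; and a generic row filter for
ancestry-style subset re-analysis. Every attempted model appears exactly
once in a result table or in the exclusion log.

## Synthetic cohort generator

The generator emulates the participant-level table the models consume,
with known ground truth:

* **Threshold scores** per disorder: an equicorrelated multivariate normal
  (default correlation 0.8 between thresholds; alternatively a target PC1
  variance fraction t, converted to ρ = (k·t−1)/(k−1)), rescaled
  geometrically over 10⁰…10⁻³ to mimic the scale spread across p-value
  thresholds. Correlation 1.0 is supported as the degenerate rank-1 case.
* **Adversity items**: a latent Gaussian copula (default item correlation
  0.35) thresholded at per-item endorsement probabilities (defaults 0.06,
  0.10, 0.05, 0.15, 0.04), then mapped to ordinal codes within the
  endorsed/non-endorsed ranges. The defaults give an any-adversity rate
  near 0.25. Optional missingness is injected completely at random per
  item (default 0), always leaving at least one observed item per row to
  respect the inclusion rule.
* **Covariates**: sex ~ Bernoulli(0.437), birth year ~ round(N(1953, 8²)),
  four ordinal socioeconomic covariates with fixed category probabilities,
  a Gamma-distributed deprivation index, and 10 standard-normal genetic
  principal components.
* **Outcomes**: binary symptoms are Bernoulli with
  logit = logit(baseline prevalence) + β₁G + β₂E + β₃GE + covariate terms,
  where G and E are the *same* dichotomised exposures the pipeline later
  reconstructs (the PRS split is computed by running the package's own
  PRS-PCA on the generated scores), so planted and estimated coefficients
  live on the same scale. Covariate effects apply to internally
  standardised covariate values so that effect sizes are in per-SD units
  and the intercept keeps its prevalence interpretation. Continuous
  cognition scores are standard normal shifted downward by the same linear
  predictor (impairment = low score). Default baseline prevalence is 0.15;
  per-item prevalences in real questionnaires vary and are not calibrated
  to any published table — scenario prevalences are explicit inputs.
* **Planted interactions**: multiplicative-scale values set β₃ directly;
  additive-scale values give a target RERI, converted exactly via
  β₃ = log(RERI + e^β₁ + e^β₂ − 1) − β₁ − β₂, with an explicit
  infeasibility error when the implied joint OR is non-positive.

One `numpy` generator seeded from the scenario seed drives all draws, so
identical (scenario, seed) pairs reproduce bit-identical tables, and the
whole cascade is byte-deterministic given a config and seed.

What the generator does **not** emulate: linkage disequilibrium or any
genotype-level structure (threshold scores are drawn, not computed from
variants), gene–environment correlation (G and E are independent by
construction unless planted through shared covariates), selection into the
questionnaire subsample, informative missingness, and recall error in the
retrospective items. Passing tests therefore demonstrate the correctness
of the estimators and cascade logic under the assumed data-generating
process, not robustness to those real-data complications.

## Numerical choices

* Logistic fits use Newton scoring (statsmodels `Logit`), maxiter 100,
  parameter tolerance 1e-10; on a logit likelihood this is the same fixed
  point as iteratively reweighted least squares.
* Quasi-complete separation is flagged on a raised separation error, a
  non-finite Hessian, or any non-intercept |β| > 15 (the intercept is
  exempt because uncentred covariates such as birth year legitimately
  shift it far from zero). Flagged fits carry no estimates; downstream
  stages log and skip them.
* Ordinal covariates (employment, income, smoking, education) enter as
  unordered categorical indicators by default, configurable to linear
  scores. Complete-case analysis is per model (listwise deletion on that
  model's columns), so n varies across models.
* Wald inference throughout (consistent with reporting OR + CI + p);
  RERI p-values come from the Wald statistic on the delta-method SE, with
  a parametric bootstrap over the asymptotic coefficient distribution
  available as an independent check.
* Help-seeking-style single-symptom domains join each per-PRS interaction
  family independently, so the same phenotype may legitimately appear in
  both PRS families.

## Validation sizes

The test suite validates operating characteristics at sizes chosen to make
binomial noise small relative to the bands being checked: delta-method vs
bootstrap SE on one cohort of n = 20,000 with 2,000 bootstrap draws; CI
coverage and test size over 600 replicate cohorts of n = 5,000 per
condition (planted RERI 0 and 0.25; null product term); parameter recovery
at n = 200,000 within 3 estimated SEs; and exact recovery of a planted
six-phenotype screening structure at n = 60,000. The acceptance script
reruns the same computations at 300 replicates and n = 100,000 for the
point estimates.

## Limitations

RERI is reported on the odds-ratio scale, which approximates the
risk-ratio-scale RERI only for uncommon outcomes; no attributable
proportion or synergy index is computed. The pipeline starts from
precomputed per-threshold scores — genotype QC, clumping and per-variant
scoring are out of scope. Bonferroni is the only multiplicity correction
offered. Estimates for rare phenotypes at small n can be flagged for
separation and are then reported only in the exclusion log.
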
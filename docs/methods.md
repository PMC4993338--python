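# Statistical methods

This document states the exact models, estimators and algorithms implemented
in `twingrowth`, in the order of the analysis pipeline.

## 1. Cohort generating model

Individuals come in twin pairs indexed j (pair) and i ∈ {1, 2} (twin within
pair). Both twins share sex and zygosity; baseline age is drawn per pair from
a normal distribution (mean 68.86, SD 9.67) truncated below at 50 years.
Measurement occasions k = 1…5 occur at fixed gaps of 4.4, 2.6, 2.2 and 2.2
years after baseline. Attrition is monotone: attendance at occasion k+1
requires attendance at k and happens with the retention probability implied by
the study's occasion totals (636, 438, 302, 164, 58), i.e. ratios of
successive totals.

The raw T/S-ratio of twin i in pair j at age a is

```
y = β₀ + β₁·B₁(a) + β₂·B₂(a) + βsex·male + βgrs·(GRS − GRS̄)
    + zᵀ·u_j + zᵀ·v_ij + plate + ε
```

where `B₁(a) = min(a − c, 0)`, `B₂(a) = max(a − c, 0)` with centering age
c = 69.3; `z = (1, B₁, B₂)`; `u_j ~ N(0, Σ_B)` is shared by both twins
(between-pair, familial) and `v_ij ~ N(0, Σ_W)` is individual (within-pair);
`plate` is an additive per-plate effect (20 plates, SD 0.03, assigned
round-robin within occasion); `ε ~ N(0, σ²)`. Default fixed effects are the
study's published two-slope estimates: β₀ = 0.7287, β₁ = −0.0012,
β₂ = −0.0021, βsex = −0.0409 (male), βgrs = −0.011 per centered risk allele.
Σ_B, Σ_W and σ were calibrated so that the pooled T/S mean and SD match the
published 0.70 and 0.17.

Genotypes are Binomial(2, f) dosages per SNP (f = 0.5 by default, 7 SNPs).
Duplicate qPCR wells are `ts_raw + N(0, (cv·ts·√(π/2))²)` each; the √(π/2)
factor makes the *expected duplicate-pair CV* equal the nominal cv (the
expectation of a half-normal |d|/√2·mean corrects E[SD of two replicates]
= σ·√(2/π)).

A single-occasion variant (`cross_sectional_config`) sets both slopes to the
published cross-sectional age coefficient −0.0022 and the sex effect to
−0.0499 (female-coded +0.0499 in the analysis).

## 2. qPCR preprocessing

- **Batch adjustment**: `ts_adjusted = ts_raw − mean(plate) + grand mean`.
  Every plate mean maps exactly onto the grand mean; the transformation is
  idempotent and preserves the overall mean.
- **Duplicate CV**: mean over samples of `100·SD(dup₁, dup₂)/mean(dup₁, dup₂)`
  (ddof 1).
- **Outlier exclusion**: single-pass |z| > k rule with k = 4 (sample SD,
  ddof 1), either on the pooled sample (`overall`, used cross-sectionally) or
  within 10-year age bands 50–59, 60–69, 70–79, 80+ (`by_age_band`, used
  longitudinally). Bands with fewer than two observations exclude nothing.

## 3. Genetic risk score

Un-weighted sum of risk-allele dosages over the 7 SNPs, range 0–14. Missing
dosages make the score missing under the `strict` policy or are imputed with
the per-SNP mean dosage under `mean`. For model use the score is centered at
the sample mean. VCF input maps GT fields through a risk-allele table that
records risk and other allele per rsID; the dosage is the count of risk
alleles whether the risk allele is REF or ALT, multi-allelic records are
rejected, and `./.` becomes missing.

## 4. Cross-sectional regression

OLS of first-occasion adjusted T/S on an intercept, age and sex (female = 1),
optionally the centered GRS. The variance estimator is the CR1 cluster
sandwich with clusters g = twin pairs:

```
V = c · (XᵀX)⁻¹ [ Σ_g Xgᵀ eg egᵀ Xg ] (XᵀX)⁻¹,   c = G/(G−1) · (N−1)/(N−p)
```

with t(G−1) reference distribution for tests and confidence intervals. This
matches `statsmodels` `cov_type="cluster"` exactly (verified in the tests).

## 5. Latent growth curve models

### Model

For pair j with observation vector y_j (both twins' draws stacked),

```
y_j = X_j β + Z_Bj u_j + Z_Wj v_j + ε_j
V_j = Z_Bj Σ_B Z_Bjᵀ + blockdiag(Z_Wj,i Σ_W Z_Wj,iᵀ) + σ² I
```

Growth terms are a subset of (intercept, B₁, B₂) giving the model ladder:
intercept-only (5 parameters), one slope (10), two slopes (17); adding the
GRS covariate (18) and one interaction (19). Parameter count = fixed effects
+ d(d+1)/2 per random-effect level + 1 residual, d = number of growth terms.
Covariate sex is male = 1; GRS enters centered at the mean over unique
individuals.

### Estimation

Full maximum likelihood (not REML) on the marginal multivariate-normal
likelihood, summed over independent pairs. For speed, pairs are batched by
missingness pattern (m₁, m₂ draws per twin) so Cholesky factorisations and
solves are vectorised per pattern.

- Σ_B, Σ_W are parameterised by log-Cholesky factors (log diagonal,
  unconstrained off-diagonal), σ by log σ — guaranteeing positive
  semi-definiteness.
- Fixed effects are profiled out by GLS at each covariance iterate:
  β(θ) = (Σ XᵀV⁻¹X)⁻¹ Σ XᵀV⁻¹y, leaving a deviance in θ only.
- The analytic gradient uses the envelope theorem:
  d(−2LL) = Σ_j tr[(V_j⁻¹ − r_j r_jᵀ) dV_j] with r_j = V_j⁻¹(y_j − X_j β);
  β's dependence on θ contributes nothing at the GLS optimum.
- Optimisation: bounded L-BFGS-B, restarted from its own solution until the
  deviance stops improving (restarts reset the Hessian memory, escaping
  stalls in the flat log-Cholesky valley near zero variances), plus one
  seeded random restart on failure. The fitted deviance matches R/lme4's ML
  deviance to ~1e-6 on shared datasets.
- Wald standard errors for fixed effects come from (Σ XᵀV⁻¹X)⁻¹ at the ML
  solution.

### Inference

Nested models are compared by Δ(−2LL) on a χ² with df = parameter-count
difference; AIC = −2LL + 2k; BIC = −2LL + k·log(number of pairs). The
likelihood-ratio helper validates nesting structurally (growth terms,
covariates and interactions must be supersets).

## 6. Change metrics

- **Pairwise deltas**: for each individual, all C(m, 2) ordered draw pairs;
  delta = later − earlier, gap in years. The study's distribution of 1–5
  measurements over 636 individuals implies 1766 deltas.
- **Elongation fraction**: percentage of deltas strictly > 0, optionally
  stratified by the gap rounded to whole years. With the calibrated
  trajectory and ~7% duplicate CV this lands in the study's printed 44–47%.
- **Loess**: degree-1 locally weighted regression with tricube weights over
  the span-nearest `ceil(span·n)` points, no robustness iterations; agrees
  with the classic lowess reference implementation to ~1e-3 and machine
  precision on exact lines.

## 7. Pipeline reproducibility

One master seed is expanded via `numpy.random.SeedSequence.spawn` into
independent per-stage substreams (simulate, preprocess, grs, cross-sectional,
lgc, change metrics), so the whole bundle is byte-identical across reruns and
any stage can be re-run in isolation. Stage failures raise a `StageError`
naming the stage; already-written outputs are preserved.

## Known small-sample properties

Plate-mean batch adjustment removes the between-plate share of every signal,
attenuating regression slopes on adjusted values by a factor of about
(1 − 1/m), where m is the samples-per-plate count (~32 at study scale, i.e.
~3% attenuation of the cross-sectional age coefficient). This is a property
of the published adjustment itself, not of this implementation; the
recovery tests account for it explicitly.
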
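# twingrowth

Longitudinal twin-cohort telomere length analysis: a synthetic cohort
generator plus the full estimation toolchain used in twin studies of
leukocyte telomere length (LTL) measured as a qPCR T/S-ratio.

The package re-implements, end to end, the analysis design of the SATSA
(Swedish Adoption/Twin Study of Aging) longitudinal telomere study:

- **Cohort simulator** — twin pairs (MZ/DZ), five measurement occasions with
  monotone attrition, piecewise-linear mean trajectory, between-pair
  (familial) and within-pair (individual) random effects, additive qPCR plate
  effects, duplicate wells with a calibrated coefficient of variation, and
  7-SNP genotypes.
- **qPCR preprocessing** — plate batch adjustment (plate means mapped onto
  the grand mean), duplicate-well CV, 4-SD outlier exclusion (overall or
  within 10-year age bands).
- **Genetic risk score** — un-weighted count of risk alleles across 7 SNPs
  (range 0–14), from a dosage table or a VCF via a configurable risk-allele
  map.
- **Cross-sectional regression** — first-occasion LTL on age and sex with
  twin-pair-clustered (CR1) sandwich standard errors and t(G−1) inference.
- **Latent growth curve models** — two-slope (spline knot at age 69.3) linear
  mixed models with random intercept/slopes at both the twin-pair and
  individual level, fitted by full maximum likelihood with the marginal
  multivariate-normal likelihood, log-Cholesky covariance parameterisation,
  analytic gradients and profiled fixed effects. Model ladders are compared
  by likelihood-ratio tests, AIC and BIC.
- **Change metrics** — within-individual pairwise deltas, the apparent
  "elongation" fraction, and a tricube local-linear (loess) age trend.
- **Pipeline + CLI** — a single-seed reproducible run writing every result
  table, and a thin `twingrowth` command-line interface.

The mixed-model likelihood, optimizer, sandwich estimator and loess smoother
are implemented in this package; `statsmodels` and R's `lme4` are used only
as cross-check oracles in the test suite.

## Worked example

Simulate a cohort at the study-calibrated defaults, preprocess it, and fit
the two-slope growth model:

```python
import twingrowth as tg
from twingrowth import lgc

config = tg.SimConfig(n_pairs=150, seed=3)
individuals, measurements, _ = tg.simulate_cohort(config)
measurements = tg.adjust_batch(measurements)
kept, _ = tg.exclude_outliers(measurements, mode="by_age_band")
data = kept.merge(individuals[["individual_id", "pair_id", "sex"]],
                  on="individual_id")

fit = lgc.fit_ml(lgc.two_slope_spec(), data, seed=0)
print(f"-2LL {fit.minus2ll:.1f}, {fit.parameter_count} parameters")
print(fit.fixed_summary().round(4))
```

Output:

```
-2LL -1386.6, 17 parameters
           estimate      se  ci_lower  ci_upper  p_value
term
intercept    0.7065  0.0169    0.6733    0.7397   0.0000
slope1      -0.0011  0.0013   -0.0036    0.0015   0.4169
slope2      -0.0022  0.0009   -0.0039   -0.0005   0.0111
sex         -0.0142  0.0229   -0.0590    0.0307   0.5355
```

The intercept is the expected T/S-ratio for women at the centering age 69.3;
`slope1`/`slope2` are the annual change before/after the knot; `sex` is the
male–female difference. At full study scale (318 pairs) the estimates
recover the generating values 0.7287, −0.0012, −0.0021 and −0.0409.

## Command line

```bash
twingrowth run --seed 42 --outdir study_run     # full pipeline, default profile
twingrowth simulate --seed 1 --n-pairs 100 --outdir cohort
twingrowth preprocess cohort/measurements.csv --mode by_age_band
twingrowth grs cohort/genotypes.csv
twingrowth cross-sectional cohort/individuals.csv cohort/measurements.csv
twingrowth lgc cohort/individuals.csv cohort/measurements.csv --model twoslope
twingrowth deltas cohort/measurements.csv
```

`twingrowth run` writes individuals/measurements/genotypes tables, a
preprocessing report, the cross-sectional fit, the three-model growth-curve
ladder with likelihood-ratio tests, the five-model GRS-adjusted ladder, fixed
and random effect estimates, predicted trajectories, pairwise deltas, the
elongation summary and a loess trend — all reproducible from the one seed.

## Repository layout

- `src/twingrowth/` — the library (`simulate`, `preprocess`, `grs`,
  `cross_sectional`, `lgc`, `change_metrics`, `pipeline`, `cli`, `satsa`
  published-constant module, shipped YAML profiles).
- `examples/` — seven narrated scripts, one per capability.
- `docs/methods.md` — statistical methods in detail.
- `tests/` — pytest suite with oracle cross-checks (brute-force joint
  multivariate normal, statsmodels, lme4) and an acceptance suite
  (`tests/test_acceptance.py`).
- `scripts/acceptance.py` — recomputes the stochastic acceptance targets:
  `python scripts/acceptance.py --seed 1 --out results/acceptance.json`.

## Testing

```bash
python -m pytest -q
```

The suite includes property-based tests (hypothesis), exact worked-example
arithmetic, parameter-recovery and CI-coverage experiments, and an R/lme4
deviance cross-check (requires `Rscript` with lme4 and jsonlite; every
numeric result also has a pure-Python oracle).
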
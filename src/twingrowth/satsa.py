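"""Published summary statistics from the SATSA leukocyte telomere length study.

SATSA (the Swedish Adoption/Twin Study of Aging) measured leukocyte telomere
length (LTL) by qPCR, as a T/S-ratio, in 636 individuals from same-sex twin
pairs at up to five in-person-testing occasions spanning roughly 20 years.
The constants here are the study's printed summary tables and model estimates.
They serve two purposes in this package:

* calibration defaults for the synthetic cohort generator, so that simulated
  cohorts reproduce the study's structure (sample sizes, attrition, T/S
  moments, fixed effects); and
* inputs for worked-example reconstructions (parameter-count ladders,
  deviance-difference arithmetic, count totals).

Values from the study's supplementary material (individual variance
components, risk-allele identities/frequencies) were not published in the
available text; where the generator needs them it uses provisional,
documented defaults instead (see the SimConfig docstring).
"""

from __future__ import annotations

# --- Cross-sectional characteristics (baseline, first available measure) ---

N_INDIVIDUALS = 636
N_MZ_COMPLETE_PAIRS = 84
N_DZ_COMPLETE_PAIRS = 152
TS_MEAN = 0.70
TS_SD = 0.17
AGE_MEAN = 68.86
AGE_SD = 9.67
N_WOMEN = 372
PROP_WOMEN = 0.58
GRS_MEAN = 8.42
GRS_SD = 1.43
N_GENOTYPED = 585

# Cross-sectional regression (first-occasion LTL on age + sex, twin-pair
# clustered sandwich SEs; sex coded female = 1 in that analysis).
CROSS_SECTIONAL_AGE_B = -0.0022       # T/S-ratio per year
CROSS_SECTIONAL_FEMALE_B = 0.0499     # T/S-ratio

# --- Longitudinal characteristics by measurement occasion (men, women) ---

OCCASION_N_MEN = (264, 181, 128, 66, 22)
OCCASION_N_WOMEN = (372, 257, 174, 98, 36)
OCCASION_N_TOTAL = tuple(
    m + w for m, w in zip(OCCASION_N_MEN, OCCASION_N_WOMEN)
)  # (636, 438, 302, 164, 58)

# Mean age at draw per occasion (men, women).
OCCASION_AGE_MEAN_MEN = (67.44, 71.84, 74.36, 76.52, 78.42)
OCCASION_AGE_MEAN_WOMEN = (69.86, 73.75, 76.55, 78.73, 80.91)

# Number of individuals with exactly 1..5 LTL measurements.
MEASUREMENT_COUNT_DISTRIBUTION = (198, 136, 138, 106, 58)

# --- Latent growth curve model ladder (N = 1598 samples) ---
# Per model: (-2LL, parameter count). Deviance differences between nested
# models are recomputed from these, never stored.
LGC_LADDER = {
    "intercept_only": (-1865.9, 5),
    "one_slope": (-1910.5, 10),
    "two_slope": (-1930.4, 17),
}

# Adjusted two-slope models on the genotyped subsample (N = 1504 samples).
LGC_ADJUSTED_LADDER = {
    "two_slope": (-1834.2, 17),
    "two_slope+slope2_x_sex": (-1834.4, 18),
    "two_slope+grs": (-1843.1, 18),
    "two_slope+grs+slope2_x_grs": (-1843.9, 19),
    "two_slope+grs+sex_x_grs": (-1843.2, 19),
}

# --- Two-slope model fixed effects (sex coded male = 1) ---

CENTERING_AGE = 69.3          # median age at the third testing occasion
LGC_INTERCEPT = 0.7287        # T/S at 69.3 y, female reference
LGC_SLOPE1 = -0.0012          # T/S per year before 69.3 y (not significant)
LGC_SLOPE2 = -0.0021          # T/S per year after 69.3 y
LGC_SEX_EFFECT = -0.0409      # T/S, men vs women
LGC_GRS_EFFECT = -0.011       # T/S per additional risk allele (centered GRS)

# --- Assay precision and elongation ---

QPCR_DUPLICATE_CV = 0.0698    # coefficient of variation of qPCR duplicates
ELONGATION_OVERALL_PCT = 46.0
ELONGATION_RANGE_PCT = (44.0, 47.0)

# Outlier policy: samples beyond 4 SDs of the mean, overall or within
# decade age bands.
OUTLIER_K_SD = 4.0
AGE_BANDS = ((50.0, 60.0), (60.0, 70.0), (70.0, 80.0), (80.0, None))


def retention_from_occasion_totals(totals=OCCASION_N_TOTAL) -> list[float]:
    """Per-occasion retention probabilities implied by occasion totals.

    Under monotone attrition the probability of attending occasion k+1 given
    attendance at occasion k is the ratio of successive totals.
    """
    return [totals[i + 1] / totals[i] for i in range(len(totals) - 1)]
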
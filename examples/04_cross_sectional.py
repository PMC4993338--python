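"""Cross-sectional analysis: first-occasion LTL on age and sex with
twin-pair-clustered sandwich standard errors.

Twins are not independent observations, so ordinary OLS standard errors are
too small; the cluster-robust (CR1) sandwich estimator clusters on twin pair.
The study's published coefficients are -0.0022 T/S per year of age and +0.0499
for women.
"""

import twingrowth as tg
from twingrowth.simulate import cross_sectional_config

config = cross_sectional_config(seed=11, n_pairs=318)
individuals, measurements, _ = tg.simulate_cohort(config)
measurements = tg.adjust_batch(measurements)
firsts, _ = tg.exclude_outliers(tg.first_measurements(measurements), mode="overall")

fit = tg.cross_sectional_analysis(individuals, firsts)
print(fit.summary().round(4).to_string())
print(f"\n{fit.n_clusters} twin-pair clusters, {fit.n_obs} individuals")

# add the genetic risk score as a covariate
fit_grs = tg.cross_sectional_analysis(individuals, firsts, include_grs=True)
print("\nwith the centered GRS:")
print(fit_grs.summary().round(4).to_string())
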
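"""qPCR preprocessing: plate batch adjustment, duplicate CV, outlier removal.

Raw T/S-ratios carry an additive plate effect.  `adjust_batch` maps every
plate mean onto the grand mean; `compute_cv` summarises duplicate-well
precision (the study reports 6.98%); `exclude_outliers` applies the 4-SD rule
either overall (cross-sectional) or within 10-year age bands (longitudinal).
"""

import twingrowth as tg

config = tg.SimConfig(n_pairs=150, seed=7)
_, measurements, _ = tg.simulate_cohort(config)
measurements = tg.simulate_duplicates(measurements, config.duplicate_cv, seed=1)

adjusted = tg.adjust_batch(measurements)
print("plate means after adjustment all equal the grand mean:")
print(adjusted.groupby("plate_id")["ts_adjusted"].mean().round(6).head(5).to_string())

cv = tg.compute_cv(adjusted)
print(f"\nmean duplicate CV: {cv:.2f}% (assay nominal 6.98%)")

kept, excluded = tg.exclude_outliers(adjusted, mode="by_age_band", k_sd=4)
print(f"\n4-SD rule within age bands: kept {len(kept)}, excluded {len(excluded)}")

firsts = tg.first_measurements(adjusted)
print(f"first-occasion subset for cross-sectional analysis: {len(firsts)} samples")
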
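"""Generate a synthetic longitudinal twin cohort and inspect its structure.

The generator produces three linked tables: one row per individual (twin-pair
membership, zygosity, sex, baseline age, risk-allele count), one row per blood
draw (age, qPCR plate, raw T/S-ratio, optional duplicate wells), and one row
per individual of SNP dosages.  Defaults reproduce the design of the SATSA
telomere study: 318 pairs, five occasions with monotone attrition, ages
centred near 69 years.
"""

import twingrowth as tg

config = tg.SimConfig(n_pairs=100, seed=2024)
individuals, measurements, genotypes = tg.simulate_cohort(config)
measurements = tg.simulate_duplicates(measurements, config.duplicate_cv, seed=1)

print(f"{len(individuals)} individuals in {individuals['pair_id'].nunique()} pairs")
print(individuals.head(4).to_string(index=False))
print()
print(f"{len(measurements)} measurements; per-occasion counts:")
print(measurements["occasion"].value_counts().sort_index().to_string())
print()
print("measurements per individual:")
print(measurements.groupby("individual_id").size().value_counts().sort_index()
      .rename_axis("n_draws").to_string())
print()
print(genotypes.head(3).to_string(index=False))
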
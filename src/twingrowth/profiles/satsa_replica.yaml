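# Study-replica pipeline profile: simulates a cohort with the structure of
# the SATSA telomere study and runs the full analysis ladder.
#
# The run seed is mandatory on the command line (twingrowth run --seed N);
# stage substreams are derived from it. Random-effect covariances are
# provisional defaults (the study's variance components were not published)
# and fully configurable here.
seed: 1
k_sd: 4.0
longitudinal_outlier_mode: by_age_band
centering_age: 69.3
grs_ladder: true
outdir: twingrowth_run
simulate:
  n_pairs: 318
  prop_mz: 0.3559
  prop_female_pairs: 0.58
  baseline_age_mean: 68.86
  baseline_age_sd: 9.67
  min_age: 50.0
  occasion_gaps: [4.4, 2.6, 2.2, 2.2]
  # per-occasion retention implied by occasion totals 636/438/302/164/58
  retention: [0.688679, 0.689498, 0.543046, 0.353659]
  fixed_effects:
    intercept: 0.7287
    slope1: -0.0012
    slope2: -0.0021
    sex_effect: -0.0409   # male = 1 coding
    grs_effect: -0.011
  centering_age: 69.3
  between_pair_cov:
    - [0.0115, 0.0, 0.0]
    - [0.0, 1.521e-05, 0.0]      # slope-1 SD 0.0039
    - [0.0, 0.0, 4.84e-06]       # slope-2 SD 0.0022
  within_pair_cov:
    - [0.0115, 0.0, 0.0]
    - [0.0, 2.5e-05, 0.0]        # slope-1 SD 0.0050
    - [0.0, 0.0, 1.024e-05]      # slope-2 SD 0.0032
  residual_sd: 0.049
  plate_count: 20
  plate_effect_sd: 0.03
  duplicate_cv: 0.0698
  allele_freqs: [0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5]
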
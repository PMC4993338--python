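"""Generator invariants: determinism, twin structure, attrition, calibration."""

import numpy as np
import pandas as pd
import pytest

import twingrowth as tg
from twingrowth import satsa
from twingrowth.simulate import SimConfig, simulate_cohort, simulate_duplicates


def _noise_free(**kw):
    base = dict(
        between_pair_cov=np.zeros((3, 3)),
        within_pair_cov=np.zeros((3, 3)),
        residual_sd=0.0,
        plate_effect_sd=0.0,
    )
    base.update(kw)
    return SimConfig(**base)


def test_seed_determinism_byte_identical():
    cfg = SimConfig(n_pairs=25, seed=7)
    tables_a = simulate_cohort(cfg)
    tables_b = simulate_cohort(SimConfig(n_pairs=25, seed=7))
    for a, b in zip(tables_a, tables_b):
        assert a.to_csv(index=False) == b.to_csv(index=False)
    # different seed differs
    c = simulate_cohort(SimConfig(n_pairs=25, seed=8))[1]
    assert not c["ts_raw"].equals(tables_a[1]["ts_raw"])


def test_twin_pair_structure(small_cohort):
    _cfg, individuals, measurements, _ = small_cohort
    sizes = individuals.groupby("pair_id").size()
    assert (sizes == 2).all()
    for col in ("zygosity", "sex"):
        assert (individuals.groupby("pair_id")[col].nunique() == 1).all()
    assert set(individuals["zygosity"]) <= {"MZ", "DZ"}
    # ages strictly increasing within individual; raw T/S positive
    for _ind, g in measurements.groupby("individual_id"):
        assert g.sort_values("occasion")["age_at_draw"].is_monotonic_increasing
    assert (measurements["ts_raw"] > 0).all()
    assert individuals["baseline_age"].min() >= 50.0


def test_monotone_attrition(small_cohort):
    _cfg, _ind, measurements, _ = small_cohort
    for _ind_id, g in measurements.groupby("individual_id"):
        occ = sorted(g["occasion"])
        assert occ == list(range(1, len(occ) + 1)), "dropout must be monotone"


def test_full_retention_gives_all_occasions():
    cfg = SimConfig(n_pairs=20, retention=[1.0] * 4, seed=3)
    _, measurements, _ = simulate_cohort(cfg)
    assert (measurements.groupby("individual_id").size() == 5).all()


def test_noise_free_trajectories_exactly_piecewise():
    cfg = _noise_free(n_pairs=15, seed=5)
    individuals, measurements, _ = simulate_cohort(cfg)
    fx = cfg.fixed_effects
    df = measurements.merge(individuals, on="individual_id")
    grs_c = df["grs"] - individuals["grs"].mean()
    d = df["age_at_draw"] - cfg.centering_age
    expected = (
        fx.intercept
        + fx.slope1 * np.minimum(d, 0)
        + fx.slope2 * np.maximum(d, 0)
        + fx.sex_effect * (df["sex"] == "male")
        + fx.grs_effect * grs_c
    )
    np.testing.assert_allclose(df["ts_raw"], expected, atol=1e-12)


def test_pair_sharing_of_between_pair_effects():
    # kill within-pair and residual noise (and the GRS term, which differs
    # between twins): both twins' trajectories must coincide exactly
    cfg = SimConfig(
        n_pairs=12,
        within_pair_cov=np.zeros((3, 3)),
        residual_sd=0.0,
        plate_effect_sd=0.0,
        fixed_effects=tg.FixedEffects(grs_effect=0.0),
        retention=[1.0] * 4,
        seed=9,
    )
    _, measurements, _ = simulate_cohort(cfg)
    measurements["pair_id"] = measurements["individual_id"].str.slice(0, 5)
    wide = measurements.pivot_table(
        index=["pair_id", "occasion"], columns="individual_id", values="ts_raw"
    )
    for _key, row in wide.iterrows():
        vals = row.dropna().to_numpy()
        assert np.allclose(vals, vals[0], atol=1e-12)


def test_per_occasion_counts_match_retention():
    cfg = SimConfig(n_pairs=318, seed=11)
    _, measurements, _ = simulate_cohort(cfg)
    counts = measurements.groupby("occasion").size().to_numpy()
    expected = np.array(satsa.OCCASION_N_TOTAL, dtype=float)
    # binomial tolerance: each count within ~3.5 SD of its expectation
    for k in range(1, 5):
        p = np.prod(cfg.retention[:k])
        sd = np.sqrt(636 * p * (1 - p))
        assert abs(counts[k] - expected[k]) < 3.5 * sd + 1


def test_pooled_ts_moments_match_study():
    means, sds = [], []
    for seed in (0, 1, 2, 3):
        _, m, _ = simulate_cohort(SimConfig(seed=seed))
        adj = tg.adjust_batch(m)
        means.append(adj["ts_adjusted"].mean())
        sds.append(adj["ts_adjusted"].std(ddof=1))
    assert abs(np.mean(means) - satsa.TS_MEAN) < 0.012
    assert abs(np.mean(sds) - satsa.TS_SD) < 0.015


def test_random_effect_covariance_recovered_empirically():
    # single occasion at the knot, no noise: observed deviations are
    # a0_j + b0_ij, so twin cross-covariance estimates the between-pair
    # intercept variance and the residual the within-pair one
    n = 20000
    cfg = SimConfig(
        n_pairs=n,
        baseline_age_mean=69.3,
        baseline_age_sd=0.0,
        occasion_gaps=[],
        retention=[],
        residual_sd=0.0,
        plate_effect_sd=0.0,
        fixed_effects=tg.FixedEffects(sex_effect=0.0, grs_effect=0.0),
        seed=17,
    )
    _, m, _ = simulate_cohort(cfg)
    dev = (m["ts_raw"] - cfg.fixed_effects.intercept).to_numpy().reshape(n, 2)
    vb_true = cfg.between_pair_cov[0, 0]
    vw_true = cfg.within_pair_cov[0, 0]
    vb_hat = np.mean(dev[:, 0] * dev[:, 1])
    vtot_hat = dev.var()
    tol = 4.0 / np.sqrt(n)  # ~4 SE of these moment estimates, scale ~variance
    assert abs(vb_hat - vb_true) < tol * (vb_true + vw_true)
    assert abs(vtot_hat - (vb_true + vw_true)) < tol * (vb_true + vw_true)


@pytest.mark.parametrize(
    "field,value",
    [
        ("between_pair_cov", np.array([[1, 2, 0], [2, 1, 0], [0, 0, 1]])),  # not PSD
        ("retention", [0.5]),  # shorter than occasion gaps
        ("retention", [0.5, 0.5, 0.5, 1.5]),  # not a probability
        ("residual_sd", -0.1),
        ("allele_freqs", [0.5] * 6),
    ],
)
def test_invalid_config_rejected(field, value):
    with pytest.raises(ValueError):
        SimConfig(**{field: value})


def test_duplicates_zero_cv_equal_and_nominal_cv_recovered(small_cohort):
    _cfg, _ind, measurements, _ = small_cohort
    exact = simulate_duplicates(measurements, 0.0, seed=1)
    assert (exact["duplicate_1"] == exact["ts_raw"]).all()
    assert (exact["duplicate_2"] == exact["ts_raw"]).all()

    # many samples: mean pair CV approaches the nominal 6.98%
    big = pd.concat([measurements] * 40, ignore_index=True)
    noisy = simulate_duplicates(big, 0.0698, seed=2)
    cv = tg.compute_cv(noisy)
    assert abs(cv - 6.98) < 0.15


def test_duplicate_noise_law_matches_monte_carlo_oracle():
    # single sample, ts_raw = 1: the pair CV must be distributed as in a
    # direct Monte-Carlo of the stated noise law (Gaussian replicates with
    # SD = cv * ts * sqrt(pi/2))
    cv = 0.0698
    one = pd.DataFrame(
        {"individual_id": ["x"], "occasion": [1], "age_at_draw": [70.0],
         "plate_id": ["P1"], "ts_raw": [1.0]}
    )
    draws = [
        tg.compute_cv(simulate_duplicates(one, cv, seed=s)) for s in range(4000)
    ]
    rng = np.random.default_rng(123)
    sd = cv * np.sqrt(np.pi / 2)
    reps = 1.0 + rng.normal(0.0, sd, size=(4000, 2))
    oracle = 100 * reps.std(axis=1, ddof=1) / reps.mean(axis=1)
    assert abs(np.mean(draws) - oracle.mean()) < 4 * oracle.std() / np.sqrt(4000)
    assert abs(np.mean(draws) - 6.98) < 0.3
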
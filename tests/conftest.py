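import numpy as np
import pandas as pd
import pytest

import twingrowth as tg


@pytest.fixture(scope="session")
def small_cohort():
    """One fixed 60-pair cohort: raw tables straight from the generator."""
    cfg = tg.SimConfig(n_pairs=60, seed=42)
    individuals, measurements, genotypes = tg.simulate_cohort(cfg)
    return cfg, individuals, measurements, genotypes


@pytest.fixture(scope="session")
def analysis_data(small_cohort):
    """Preprocessed long-format data ready for model fitting."""
    _cfg, individuals, measurements, _geno = small_cohort
    adj = tg.adjust_batch(measurements)
    kept, _ = tg.exclude_outliers(adj, mode="by_age_band")
    return kept.merge(
        individuals[["individual_id", "pair_id", "sex", "grs"]], on="individual_id"
    )


def brute_force_neg2_loglik(params, spec, data):
    """Independent -2 log-likelihood: per pair, assemble the full joint
    covariance of all its observations and evaluate the MVN density."""
    from scipy.stats import multivariate_normal

    from twingrowth import lgc

    total = 0.0
    for _pid, g in data.groupby("pair_id"):
        g = g.sort_values(["individual_id", "age_at_draw"])
        b1, b2 = lgc.age_basis(g["age_at_draw"].to_numpy(), spec.centering_age)
        basis = {"intercept": np.ones(len(g)), "slope1": b1, "slope2": b2}
        Z = np.column_stack([basis[t] for t in ("intercept", "slope1", "slope2")
                             if t in spec.growth_terms])
        cols = {t: basis[t] for t in ("intercept", "slope1", "slope2")
                if t in spec.growth_terms}
        if "sex" in spec.covariates:
            cols["sex"] = (g["sex"] == "male").astype(float).to_numpy()
        if "grs" in spec.covariates:
            # caller passes a pre-centered grs column so both routes agree
            cols["grs"] = g["grs"].to_numpy(dtype=float)
        for inter in spec.interactions:
            a, b = inter.split(":")
            cols[inter] = cols[a] * cols[b] if a in cols else basis[a] * cols[b]
        X = np.column_stack([cols[n] for n in spec.fixed_names])
        beta = np.array([params.fixed[n] for n in spec.fixed_names])
        twin = pd.factorize(g["individual_id"])[0]
        same = twin[:, None] == twin[None, :]
        V = (
            Z @ params.between_pair_cov @ Z.T
            + (Z @ params.within_pair_cov @ Z.T) * same
            + params.residual_var * np.eye(len(g))
        )
        total += -2.0 * multivariate_normal.logpdf(
            g["ts_adjusted"].to_numpy(), X @ beta, V
        )
    return total
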
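"""Synthetic same-sex twin cohorts with longitudinal qPCR telomere measures.

The generating model mirrors the two-slope latent growth curve used in the
analysis modules: each individual's expected T/S-ratio trajectory is a
piecewise-linear function of age with a knot at the centering age,

    mu_ij(t) = intercept + slope1*B1(t) + slope2*B2(t)
               + sex_effect*male_i + grs_effect*(GRS_i - mean GRS)
               + a_j . (1, B1, B2) + b_ij . (1, B1, B2)

where B1(t) = min(t - c, 0), B2(t) = max(t - c, 0), a_j is a pair-level
(familial) random effect shared by both twins and b_ij an individual-level
(non-familial) one, both trivariate Gaussian.  Observed raw T/S adds an
additive plate batch effect and a Gaussian residual.  Attrition across the
measurement occasions is monotone: once an individual misses an occasion they
never return, matching the declining per-occasion counts of the cohort the
generator emulates.

Defaults reproduce the SATSA telomere study's structure: 318 same-sex pairs
(636 individuals), baseline age ~ N(68.9, 9.67^2) truncated at 50, up to five
occasions at gaps 4.4/2.6/2.2/2.2 years, retention implied by occasion totals
636/438/302/164/58, fixed effects from the published two-slope model, pooled
adjusted T/S mean ~0.70 and SD ~0.17, and qPCR duplicate CV ~7%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import satsa

GROWTH_TERMS = ("intercept", "slope1", "slope2")

#: rsIDs of the seven LTL-associated SNPs entering the genetic risk score.
GRS_SNPS = (
    "rs2736100",
    "rs2281929",
    "rs11125529",
    "rs10936599",
    "rs7675998",
    "rs9420907",
    "rs8105767",
)


@dataclass
class FixedEffects:
    """Population-average trajectory parameters (sex coded male = 1)."""

    intercept: float = satsa.LGC_INTERCEPT
    slope1: float = satsa.LGC_SLOPE1
    slope2: float = satsa.LGC_SLOPE2
    sex_effect: float = satsa.LGC_SEX_EFFECT
    grs_effect: float = satsa.LGC_GRS_EFFECT


def _default_between_pair_cov() -> np.ndarray:
    # Provisional: intercept variance split equally between familial and
    # non-familial levels; slope-1 variation larger than slope-2 and larger
    # within pairs than between; calibrated so pooled T/S SD ~ 0.17.
    return np.diag([0.0115, 0.0039**2, 0.0022**2])


def _default_within_pair_cov() -> np.ndarray:
    return np.diag([0.0115, 0.0050**2, 0.0032**2])


@dataclass
class SimConfig:
    """Full parameterisation of the synthetic twin cohort.

    Covariance matrices are ordered (intercept, slope1, slope2).  All T/S
    quantities are on the raw T/S-ratio scale; ages in years.
    """

    n_pairs: int = 318
    prop_mz: float = satsa.N_MZ_COMPLETE_PAIRS / (
        satsa.N_MZ_COMPLETE_PAIRS + satsa.N_DZ_COMPLETE_PAIRS
    )
    prop_female_pairs: float = satsa.PROP_WOMEN
    baseline_age_mean: float = satsa.AGE_MEAN
    baseline_age_sd: float = satsa.AGE_SD
    min_age: float = 50.0
    occasion_gaps: list[float] = field(default_factory=lambda: [4.4, 2.6, 2.2, 2.2])
    retention: list[float] = field(default_factory=satsa.retention_from_occasion_totals)
    fixed_effects: FixedEffects = field(default_factory=FixedEffects)
    centering_age: float = satsa.CENTERING_AGE
    between_pair_cov: np.ndarray = field(default_factory=_default_between_pair_cov)
    within_pair_cov: np.ndarray = field(default_factory=_default_within_pair_cov)
    residual_sd: float = 0.049  # ~7% CV at the 0.70 T/S mean
    plate_count: int = 20
    plate_effect_sd: float = 0.03
    duplicate_cv: float = satsa.QPCR_DUPLICATE_CV
    allele_freqs: list[float] = field(default_factory=lambda: [0.5] * 7)
    seed: int = 0

    def __post_init__(self) -> None:
        self.between_pair_cov = np.asarray(self.between_pair_cov, dtype=float)
        self.within_pair_cov = np.asarray(self.within_pair_cov, dtype=float)
        if isinstance(self.fixed_effects, dict):
            self.fixed_effects = FixedEffects(**self.fixed_effects)
        self.validate()

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        for name in ("prop_mz", "prop_female_pairs"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("baseline_age_sd", "residual_sd", "plate_effect_sd", "duplicate_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(g <= 0 for g in self.occasion_gaps):
            raise ValueError("occasion_gaps must be positive")
        if len(self.retention) != len(self.occasion_gaps):
            raise ValueError(
                f"retention must have one entry per occasion gap "
                f"({len(self.occasion_gaps)}), got {len(self.retention)}"
            )
        if any(not 0.0 <= r <= 1.0 for r in self.retention):
            raise ValueError("retention probabilities must lie in [0, 1]")
        for name in ("between_pair_cov", "within_pair_cov"):
            m = getattr(self, name)
            if m.shape != (3, 3):
                raise ValueError(f"{name} must be 3x3 (intercept, slope1, slope2)")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(m).min() < -1e-10:
                raise ValueError(f"{name} must be positive semi-definite")
        if len(self.allele_freqs) != len(GRS_SNPS):
            raise ValueError(f"allele_freqs must have {len(GRS_SNPS)} entries")
        if any(not 0.0 < f < 1.0 for f in self.allele_freqs):
            raise ValueError("allele frequencies must lie in (0, 1)")
        if self.plate_count < 1:
            raise ValueError("plate_count must be >= 1")

    def replace(self, **changes) -> "SimConfig":
        """Copy of the config with fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)


def cross_sectional_config(seed: int = 0, n_pairs: int = 318) -> SimConfig:
    """Single-occasion generator matching the cross-sectional analysis.

    A single linear age slope equal to the published cross-sectional age
    coefficient (-0.0022 T/S per year) and the published sex difference
    (women 0.0499 higher, i.e. -0.0499 on the male indicator).
    """
    fx = FixedEffects(
        slope1=satsa.CROSS_SECTIONAL_AGE_B,
        slope2=satsa.CROSS_SECTIONAL_AGE_B,
        sex_effect=-satsa.CROSS_SECTIONAL_FEMALE_B,
    )
    return SimConfig(
        n_pairs=n_pairs, occasion_gaps=[], retention=[], fixed_effects=fx, seed=seed
    )


def _piecewise_basis(ages: np.ndarray, centering_age: float) -> np.ndarray:
    d = np.asarray(ages, dtype=float) - centering_age
    return np.column_stack([np.ones_like(d), np.minimum(d, 0.0), np.maximum(d, 0.0)])


def _truncated_normal(rng, mean, sd, lower, size):
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(mean, sd, size=todo.size)
        ok = draw >= lower
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _mvn_psd(rng, cov, size):
    """Zero-mean multivariate normal draws from a PSD (possibly singular)
    covariance, via an eigenvalue square-root factor."""
    w, v = np.linalg.eigh(cov)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    return rng.standard_normal((size, cov.shape[0])) @ factor.T


def simulate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one cohort.

    Returns
    -------
    individuals : DataFrame
        individual_id, pair_id, zygosity, sex, baseline_age, grs.
    measurements : DataFrame
        individual_id, occasion (1-based), age_at_draw, plate_id, ts_raw,
        ts_adjusted (empty; filled by preprocessing), duplicate_1/2 (empty;
        filled by :func:`simulate_duplicates`).
    genotypes : DataFrame
        individual_id plus one risk-allele dosage column per GRS SNP.

    The same config (including seed) always yields identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_pairs = config.n_pairs
    n_ind = 2 * n_pairs

    pair_ids = np.repeat([f"F{j:04d}" for j in range(1, n_pairs + 1)], 2)
    member = np.tile([1, 2], n_pairs)
    individual_ids = np.array([f"{p}.{m}" for p, m in zip(pair_ids, member)])

    zygosity = np.repeat(
        np.where(rng.random(n_pairs) < config.prop_mz, "MZ", "DZ"), 2
    )
    sex = np.repeat(
        np.where(rng.random(n_pairs) < config.prop_female_pairs, "female", "male"), 2
    )
    male = (sex == "male").astype(float)
    baseline_age = np.repeat(
        _truncated_normal(
            rng, config.baseline_age_mean, config.baseline_age_sd,
            config.min_age, n_pairs,
        ),
        2,
    )

    # genotypes: risk-allele dosages, Binomial(2, freq) per SNP
    dosages = np.column_stack(
        [rng.binomial(2, f, size=n_ind) for f in config.allele_freqs]
    )
    grs = dosages.sum(axis=1).astype(float)
    grs_centered = grs - grs.mean()

    # random effects over (intercept, slope1, slope2)
    a_pair = _mvn_psd(rng, config.between_pair_cov, n_pairs)
    a = np.repeat(a_pair, 2, axis=0)
    b = _mvn_psd(rng, config.within_pair_cov, n_ind)

    # monotone attrition: attendance at occasion k+1 requires attendance at k
    n_occ = len(config.occasion_gaps) + 1
    attends = np.ones((n_ind, n_occ), dtype=bool)
    for k, r in enumerate(config.retention):
        attends[:, k + 1] = attends[:, k] & (rng.random(n_ind) < r)

    plate_effects = rng.normal(0.0, config.plate_effect_sd, size=config.plate_count)
    fx = config.fixed_effects
    beta = np.array([fx.intercept, fx.slope1, fx.slope2])

    rows = []
    occ_ages = baseline_age[:, None] + np.concatenate(
        [[0.0], np.cumsum(config.occasion_gaps)]
    )[None, :]
    for k in range(n_occ):
        idx = np.flatnonzero(attends[:, k])
        ages = occ_ages[idx, k]
        basis = _piecewise_basis(ages, config.centering_age)
        mu = (
            basis @ beta
            + fx.sex_effect * male[idx]
            + fx.grs_effect * grs_centered[idx]
            + np.einsum("ij,ij->i", basis, a[idx])
            + np.einsum("ij,ij->i", basis, b[idx])
        )
        plate_idx = np.arange(idx.size) % config.plate_count
        resid = rng.normal(0.0, config.residual_sd, size=idx.size)
        ts_raw = mu + plate_effects[plate_idx] + resid
        rows.append(
            pd.DataFrame(
                {
                    "individual_id": individual_ids[idx],
                    "occasion": k + 1,
                    "age_at_draw": ages,
                    "plate_id": [f"P{p + 1:02d}" for p in plate_idx],
                    "ts_raw": ts_raw,
                }
            )
        )

    measurements = pd.concat(rows, ignore_index=True)
    measurements = measurements.sort_values(
        ["individual_id", "occasion"], kind="mergesort"
    ).reset_index(drop=True)
    measurements["ts_adjusted"] = np.nan
    measurements["duplicate_1"] = np.nan
    measurements["duplicate_2"] = np.nan

    individuals = pd.DataFrame(
        {
            "individual_id": individual_ids,
            "pair_id": pair_ids,
            "zygosity": zygosity,
            "sex": sex,
            "baseline_age": baseline_age,
            "grs": grs,
        }
    )
    genotypes = pd.DataFrame(
        dict({"individual_id": individual_ids},
             **{snp: dosages[:, i] for i, snp in enumerate(GRS_SNPS)})
    )
    return individuals, measurements, genotypes


# Half-normal correction: for a two-replicate pair with additive Gaussian
# noise of SD sigma, E[pair SD] = sigma*sqrt(2/pi), so the per-replicate SD
# must be scaled up by sqrt(pi/2) for the expected pair CV to equal the
# nominal duplicate_cv.
_DUPLICATE_SD_SCALE = float(np.sqrt(np.pi / 2.0))


def simulate_duplicates(
    measurements: pd.DataFrame, duplicate_cv: float, seed: int = 0
) -> pd.DataFrame:
    """Fill duplicate_1/duplicate_2 with noisy qPCR replicates of ts_raw.

    Each replicate is ts_raw plus Gaussian noise with SD
    ``duplicate_cv * ts_raw * sqrt(pi/2)``, so that the expected
    coefficient of variation of a duplicate pair equals ``duplicate_cv``.
    """
    if duplicate_cv < 0:
        raise ValueError("duplicate_cv must be non-negative")
    rng = np.random.default_rng(seed)
    out = measurements.copy()
    ts = out["ts_raw"].to_numpy(dtype=float)
    sd = duplicate_cv * np.abs(ts) * _DUPLICATE_SD_SCALE
    out["duplicate_1"] = ts + rng.normal(0.0, 1.0, ts.size) * sd
    out["duplicate_2"] = ts + rng.normal(0.0, 1.0, ts.size) * sd
    return out


def write_cohort_csv(
    individuals: pd.DataFrame,
    measurements: pd.DataFrame,
    genotypes: pd.DataFrame,
    outdir,
) -> dict[str, str]:
    """Write the three cohort tables as CSV; returns written paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("individuals", individuals),
        ("measurements", measurements),
        ("genotypes", genotypes),
    ):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    return paths
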
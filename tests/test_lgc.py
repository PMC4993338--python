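"""Growth-curve model: basis, parameter counting, likelihood oracle, fitting."""

import json
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import twingrowth as tg
from twingrowth import lgc
from twingrowth.lgc import (
    LGCParams,
    LGCSpec,
    age_basis,
    count_parameters,
    fit_ml,
    intercept_only_spec,
    likelihood_ratio_test,
    lrt_from_deviances,
    neg2_loglik,
    one_slope_spec,
    predict_trajectory,
    two_slope_spec,
)
from conftest import brute_force_neg2_loglik


class TestAgeBasis:
    @pytest.mark.parametrize(
        "age,expected", [(69.3, (0, 0)), (59.3, (-10, 0)), (79.3, (0, 10))]
    )
    def test_knot_and_limbs(self, age, expected):
        b1, b2 = age_basis(age, 69.3)
        assert (b1, b2) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None)
    @given(
        age=st.floats(min_value=0, max_value=120),
        c=st.floats(min_value=40, max_value=100),
    )
    def test_limbs_sum_to_centered_age(self, age, c):
        b1, b2 = age_basis(age, c)
        assert b1 + b2 == pytest.approx(age - c)
        assert b1 <= 0 <= b2


class TestCountParameters:
    @pytest.mark.parametrize(
        "spec,expected",
        [
            (intercept_only_spec(), 5),
            (one_slope_spec(), 10),
            (two_slope_spec(), 17),
            (two_slope_spec(covariates=("sex", "grs")), 18),
            (two_slope_spec(interactions=("slope2:sex",)), 18),
            (two_slope_spec(covariates=("sex", "grs"),
                            interactions=("slope2:grs",)), 19),
            (two_slope_spec(covariates=("sex", "grs"),
                            interactions=("sex:grs",)), 19),
        ],
    )
    def test_model_ladder(self, spec, expected):
        assert count_parameters(spec) == expected


class TestNeg2Loglik:
    def _data(self, n_pairs, seed, **kw):
        cfg = tg.SimConfig(n_pairs=n_pairs, seed=seed, **kw)
        ind, meas, _ = tg.simulate_cohort(cfg)
        meas = meas.assign(ts_adjusted=meas["ts_raw"])
        data = meas.merge(
            ind[["individual_id", "pair_id", "sex", "grs"]], on="individual_id"
        )
        data["grs"] = data["grs"] - ind["grs"].mean()  # pre-centered
        return data

    def test_scalar_normal_closed_form(self):
        # one pair, one measurement, intercept-only: the density is a plain
        # univariate normal with variance V_b + V_w + sigma^2
        data = pd.DataFrame(
            {
                "pair_id": ["p"],
                "individual_id": ["p.1"],
                "age_at_draw": [70.0],
                "ts_adjusted": [0.65],
                "sex": ["female"],
            }
        )
        spec = intercept_only_spec()
        params = LGCParams(
            fixed={"intercept": 0.7, "sex": -0.04},
            between_pair_cov=[[0.01]],
            within_pair_cov=[[0.02]],
            residual_var=0.03,
        )
        vtot = 0.01 + 0.02 + 0.03
        expected = np.log(2 * np.pi * vtot) + (0.65 - 0.7) ** 2 / vtot
        assert neg2_loglik(params, spec, data) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("n_pairs,seed", [(3, 0), (7, 1), (10, 2)])
    def test_matches_full_joint_mvn_oracle(self, n_pairs, seed):
        data = self._data(n_pairs, seed)
        spec = two_slope_spec(covariates=("sex", "grs"),
                              interactions=("slope2:sex",))
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3)) * 0.02
        B = rng.normal(size=(3, 3)) * 0.02
        params = LGCParams(
            fixed={"intercept": 0.72, "slope1": -0.001, "slope2": -0.002,
                   "sex": -0.04, "grs": -0.01, "slope2:sex": 0.001},
            between_pair_cov=A @ A.T + 1e-4 * np.eye(3),
            within_pair_cov=B @ B.T + 1e-4 * np.eye(3),
            residual_var=0.002,
        )
        ours = neg2_loglik(params, spec, data)
        brute = brute_force_neg2_loglik(params, spec, data)
        assert ours == pytest.approx(brute, rel=1e-8)

    def test_non_psd_returns_inf(self):
        data = self._data(3, 4)
        params = LGCParams(
            fixed={"intercept": 0.7, "slope1": 0.0, "slope2": 0.0, "sex": 0.0},
            between_pair_cov=np.diag([1.0, 1.0, -0.5]),
            within_pair_cov=np.eye(3) * 0.01,
            residual_var=0.002,
        )
        assert neg2_loglik(params, two_slope_spec(), data) == np.inf


class TestFitML:
    def test_degenerate_noise_recovers_fixed_effects_exactly(self):
        cfg = tg.SimConfig(
            n_pairs=50,
            between_pair_cov=np.zeros((3, 3)),
            within_pair_cov=np.zeros((3, 3)),
            residual_sd=1e-3,
            plate_effect_sd=0.0,
            fixed_effects=tg.FixedEffects(grs_effect=0.0),
            retention=[1.0] * 4,
            seed=13,
        )
        ind, meas, _ = tg.simulate_cohort(cfg)
        meas = meas.assign(ts_adjusted=meas["ts_raw"])
        data = meas.merge(ind[["individual_id", "pair_id", "sex"]], on="individual_id")
        fit = fit_ml(two_slope_spec(), data, seed=0)
        fx = cfg.fixed_effects
        # GLS at near-zero noise = OLS; estimates pin the generating values
        assert fit.params.fixed["intercept"] == pytest.approx(fx.intercept, abs=5e-4)
        assert fit.params.fixed["slope1"] == pytest.approx(fx.slope1, abs=1e-4)
        assert fit.params.fixed["slope2"] == pytest.approx(fx.slope2, abs=1e-4)
        assert fit.params.fixed["sex"] == pytest.approx(fx.sex_effect, abs=5e-4)

    def test_nesting_monotonicity_and_ladder(self, analysis_data):
        fits = [
            fit_ml(s, analysis_data, seed=0)
            for s in (intercept_only_spec(), one_slope_spec(), two_slope_spec())
        ]
        assert [f.parameter_count for f in fits] == [5, 10, 17]
        assert fits[1].minus2ll <= fits[0].minus2ll + 1e-3
        assert fits[2].minus2ll <= fits[1].minus2ll + 1e-3
        for f in fits:
            assert f.aic == pytest.approx(f.minus2ll + 2 * f.parameter_count)
            assert f.bic == pytest.approx(
                f.minus2ll + f.parameter_count * np.log(f.n_pairs)
            )
        t = likelihood_ratio_test(fits[0], fits[1])
        assert t.df == 5 and t.delta_minus2ll >= 0
        t = likelihood_ratio_test(fits[1], fits[2])
        assert t.df == 7 and 0 <= t.p_value <= 1

    def test_age_shift_invariance(self, analysis_data):
        shift = 7.0
        fit_a = fit_ml(two_slope_spec(), analysis_data, seed=0)
        shifted = analysis_data.assign(age_at_draw=analysis_data["age_at_draw"] + shift)
        fit_b = fit_ml(two_slope_spec(centering_age=69.3 + shift), shifted, seed=0)
        assert fit_b.minus2ll == pytest.approx(fit_a.minus2ll, abs=1e-5)
        for term in ("intercept", "slope1", "slope2", "sex"):
            assert fit_b.params.fixed[term] == pytest.approx(
                fit_a.params.fixed[term], abs=1e-6
            )

    def test_lme4_oracle_on_fixed_dataset(self, tmp_path):
        """Independent mixed-model cross-check via lme4 (ML, same model)."""
        cfg = tg.SimConfig(
            n_pairs=80,
            seed=11,
            between_pair_cov=np.diag([0.01, 4e-5, 2e-5]),
            within_pair_cov=np.diag([0.01, 4e-5, 2e-5]),
        )
        ind, meas, _ = tg.simulate_cohort(cfg)
        meas = tg.adjust_batch(meas)
        data = meas.merge(ind[["individual_id", "pair_id", "sex"]], on="individual_id")
        b1, b2 = age_basis(data["age_at_draw"].to_numpy(), 69.3)
        rdata = data.assign(b1=b1, b2=b2, male=(data["sex"] == "male").astype(int))
        csv = tmp_path / "data.csv"
        rdata.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(textwrap.dedent("""
            suppressMessages({library(lme4); library(jsonlite)})
            args <- commandArgs(trailingOnly = TRUE)
            d <- read.csv(args[1])
            f <- lmer(ts_adjusted ~ b1 + b2 + male + (1 + b1 + b2 | pair_id) +
                      (1 + b1 + b2 | individual_id), data = d, REML = FALSE,
                      control = lmerControl(optimizer = "bobyqa",
                                            optCtrl = list(maxfun = 100000),
                                            check.nobs.vs.nRE = "ignore"))
            vc <- VarCorr(f)
            mat <- function(m) as.matrix(as.data.frame(
                lapply(as.data.frame(as.matrix(m)), unlist)))
            out <- list(deviance = deviance(f), fixef = as.list(fixef(f)),
                        pair = mat(vc$pair_id), individual = mat(vc$individual_id),
                        sigma2 = sigma(f)^2)
            cat(toJSON(out, digits = 12, auto_unbox = TRUE))
        """))
        res = subprocess.run(
            ["Rscript", str(script), str(csv)], capture_output=True, text=True,
            timeout=600,
        )
        assert res.returncode == 0, res.stderr
        o = json.loads(res.stdout)
        params = LGCParams(
            fixed={"intercept": o["fixef"]["(Intercept)"], "slope1": o["fixef"]["b1"],
                   "slope2": o["fixef"]["b2"], "sex": o["fixef"]["male"]},
            between_pair_cov=np.array(o["pair"]),
            within_pair_cov=np.array(o["individual"]),
            residual_var=o["sigma2"],
        )
        # our likelihood evaluated at lme4's ML solution equals its deviance
        ours_at_lme4 = neg2_loglik(params, two_slope_spec(), data)
        assert ours_at_lme4 == pytest.approx(o["deviance"], abs=1e-6)
        # and the two independently minimised -2LLs agree
        fit = fit_ml(two_slope_spec(), data, seed=0)
        assert fit.minus2ll == pytest.approx(o["deviance"], abs=1e-4)

    def test_grs_model_parameter_count_and_effect_sign(self, analysis_data):
        data = analysis_data.copy()
        fit = fit_ml(two_slope_spec(covariates=("sex", "grs")), data, seed=0)
        assert fit.parameter_count == 18
        assert "grs" in fit.params.fixed

    def test_errors(self, analysis_data):
        one_pair = analysis_data[analysis_data["pair_id"] == analysis_data["pair_id"].iloc[0]]
        with pytest.raises(ValueError, match="pairs"):
            fit_ml(two_slope_spec(), one_pair)
        fit = fit_ml(two_slope_spec(), analysis_data, seed=0)
        reduced = fit_ml(one_slope_spec(), analysis_data, seed=0)
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(fit, reduced)


class TestLRTArithmetic:
    def test_identical_fits_give_zero(self):
        t = lrt_from_deviances(-100.0, -100.0, 0)
        assert t.delta_minus2ll == 0.0 and t.p_value == 1.0

    def test_chi2_reference(self):
        t = lrt_from_deviances(-1865.9, -1910.5, 5)
        assert t.delta_minus2ll == pytest.approx(44.6)
        assert t.p_value < 1e-7


@pytest.fixture(scope="module")
def fit(analysis_data):
    return fit_ml(two_slope_spec(), analysis_data, seed=0)


class TestPredictTrajectory:
    def test_intercept_at_knot_female(self, fit):
        pred = predict_trajectory(fit, [fit.spec.centering_age], sex="female")
        assert pred["predicted_ts"].iloc[0] == pytest.approx(
            fit.params.fixed["intercept"]
        )

    def test_parallel_sex_trajectories(self, fit):
        ages = np.linspace(55, 85, 7)
        men = predict_trajectory(fit, ages, sex="male")["predicted_ts"]
        women = predict_trajectory(fit, ages, sex="female")["predicted_ts"]
        diff = (men - women).to_numpy()
        np.testing.assert_allclose(diff, fit.params.fixed["sex"], rtol=1e-10)

    def test_piecewise_linear_shape(self, fit):
        c = fit.spec.centering_age
        p = predict_trajectory(fit, [c - 2, c - 1, c, c + 1, c + 2])["predicted_ts"]
        left = p.iloc[1] - p.iloc[0]
        right = p.iloc[4] - p.iloc[3]
        assert left == pytest.approx(fit.params.fixed["slope1"])
        assert right == pytest.approx(fit.params.fixed["slope2"])

    def test_grs_shifts_level_by_fitted_effect(self, analysis_data):
        fit = fit_ml(two_slope_spec(covariates=("sex", "grs")), analysis_data, seed=0)
        base = predict_trajectory(fit, [70.0], grs_centered=0.0)["predicted_ts"].iloc[0]
        plus = predict_trajectory(fit, [70.0], grs_centered=1.0)["predicted_ts"].iloc[0]
        assert plus - base == pytest.approx(fit.params.fixed["grs"], rel=1e-10)
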
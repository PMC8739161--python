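"""Two-stage population PK estimation and the weight covariate test."""

import numpy as np
import pytest
from scipy import stats

from phase1pk.core_pk import DoseEvent, PKParameters, conc_2cmt_infusion
from phase1pk.nca import ConcentrationProfile
from phase1pk.poppk_fit import (
    CovariateTestResult,
    FitError,
    PopPKModel,
    ResidualErrorModel,
    fit_individual,
    fit_population_two_stage,
    individual_clearance,
    individual_parameters,
    load_model,
    save_model,
    weight_covariate_test,
)

RICH_TIMES = np.array(
    [0.0, 0.5, 1, 2, 4, 8, 24, 72, 168, 336, 672, 1008, 1344, 1680, 2016], float
)


def model_profile(params, dose=500.0, subject="s1", weight=70.0, noise_cv=0.0, rng=None):
    c = np.asarray(
        conc_2cmt_infusion(params, [DoseEvent(0.0, dose, 0.5)], RICH_TIMES), float
    )
    if noise_cv > 0:
        c = c * np.exp(rng.normal(0.0, noise_cv, c.size))
    return ConcentrationProfile(
        subject_id=subject,
        dose=dose,
        times=tuple(RICH_TIMES),
        concentrations=tuple(c),
        blq=tuple([False] * RICH_TIMES.size),
        nominal_trough_time=336.0,
        body_weight=weight,
    )


class TestIndividualClearance:
    def test_reference_weight_identity(self):
        model = PopPKModel(theta=PKParameters(0.01, 3.0, 0.03, 1.5), theta_wt=0.75)
        assert individual_clearance(model, 70.0) == pytest.approx(0.01)

    def test_null_exponent_removes_weight_effect(self):
        model = PopPKModel(theta=PKParameters(0.01, 3.0, 0.03, 1.5), theta_wt=0.0)
        assert individual_clearance(model, 40.0) == individual_clearance(model, 140.0)

    def test_power_law_closed_form(self):
        model = PopPKModel(theta=PKParameters(0.01, 3.0, 0.03, 1.5), theta_wt=0.75)
        assert individual_clearance(model, 140.0) == pytest.approx(
            0.01 * 2**0.75, rel=1e-12
        )
        assert 2**0.75 == pytest.approx(1.6818, abs=1e-4)

    def test_eta_acts_multiplicatively(self):
        model = PopPKModel(theta=PKParameters(0.01, 3.0, 0.03, 1.5))
        assert individual_clearance(model, 70.0, eta=np.log(2.0)) == pytest.approx(0.02)


class TestIndividualFit:
    def test_noise_free_recovery_within_one_percent(self, typical_params):
        profile = model_profile(typical_params)
        fit = fit_individual(profile, PKParameters(0.005, 2.0, 0.02, 3.0), seed=0)
        assert fit.converged
        for name in ("cl", "v1", "q", "v2"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(typical_params, name), rel=0.01
            )

    def test_underdetermined_profile_rejected(self, typical_params):
        t = (0.0, 1.0, 24.0, 336.0)
        c = conc_2cmt_infusion(typical_params, [DoseEvent(0.0, 500.0, 0.5)], np.array(t))
        profile = ConcentrationProfile(
            subject_id="s",
            dose=500.0,
            times=t,
            concentrations=tuple(c),
            blq=(False,) * 4,
        )
        with pytest.raises(FitError):
            fit_individual(profile, typical_params, seed=0)

    def test_noisy_median_cl_error_small(self, typical_params, rng):
        errors = []
        for i in range(25):
            profile = model_profile(
                typical_params, subject=f"s{i}", noise_cv=0.20, rng=rng
            )
            fit = fit_individual(
                profile, typical_params, residual=ResidualErrorModel(0.20, 0.05), seed=i
            )
            errors.append(abs(fit.params.cl / typical_params.cl - 1.0))
        assert np.median(errors) < 0.15


class TestTwoStage:
    def make_population(self, n, theta_wt=0.5, seed=0, noise_cv=0.12):
        rng = np.random.default_rng(seed)
        model = PopPKModel(
            theta=PKParameters(0.008, 3.5, 0.03, 1.5),
            theta_wt=theta_wt,
            omega2={"cl": 0.09, "v1": 0.04, "q": 0.09, "v2": 0.09},
        )
        profiles, weights = [], rng.uniform(50.0, 120.0, n)
        for i in range(n):
            etas = {k: rng.normal(0, np.sqrt(model.omega2[k])) for k in model.omega2}
            params = individual_parameters(model, weights[i], etas)
            profiles.append(
                model_profile(
                    params,
                    dose=round(3.0 * weights[i], 1),
                    subject=f"s{i:03d}",
                    weight=weights[i],
                    noise_cv=noise_cv,
                    rng=rng,
                )
            )
        return model, profiles

    def test_degenerate_population_zero_variance(self, typical_params):
        # identical subjects at one shared weight: the covariate drops
        # out and the variances collapse to zero
        profiles = [
            model_profile(typical_params, subject=f"s{i}", weight=70.0)
            for i in range(8)
        ]
        init = PopPKModel(theta=PKParameters(0.005, 2.0, 0.02, 3.0))
        model, _ = fit_population_two_stage(profiles, init, default_tau=336.0)
        assert model.theta_wt == 0.0
        assert model.omega2["cl"] == pytest.approx(0.0, abs=1e-4)
        assert model.theta.cl == pytest.approx(typical_params.cl, rel=0.01)

    def test_degenerate_population_distinct_weights(self, typical_params):
        # identical noise-free kinetics with varying weights: omega^2 -> 0
        # and the typical values reproduce the shared truth
        profiles = [
            model_profile(typical_params, subject=f"s{i}", weight=50.0 + 5 * i)
            for i in range(8)
        ]
        init = PopPKModel(theta=PKParameters(0.005, 2.0, 0.02, 3.0))
        model, fits = fit_population_two_stage(profiles, init, default_tau=336.0)
        assert len(fits) == 8
        assert model.theta_wt == pytest.approx(0.0, abs=1e-3)
        for name in ("cl", "v1", "q", "v2"):
            assert model.omega2[name] == pytest.approx(0.0, abs=1e-4)
            assert getattr(model.theta, name) == pytest.approx(
                getattr(typical_params, name), rel=0.01
            )

    def test_order_invariance(self):
        _, profiles = self.make_population(8, seed=3)
        init = PopPKModel(theta=PKParameters(0.01, 3.0, 0.03, 2.0))
        fwd, _ = fit_population_two_stage(profiles, init, default_tau=336.0, seed=5)
        rev, _ = fit_population_two_stage(profiles[::-1], init, default_tau=336.0, seed=5)
        assert fwd.theta.cl == rev.theta.cl
        assert fwd.theta_wt == rev.theta_wt

    def test_too_few_subjects_rejected(self):
        _, profiles = self.make_population(4, seed=1)
        init = PopPKModel(theta=PKParameters(0.01, 3.0, 0.03, 2.0))
        with pytest.raises(FitError):
            fit_population_two_stage(profiles, init, default_tau=336.0)

    def test_recovers_weight_exponent(self):
        truth, profiles = self.make_population(60, theta_wt=0.5, seed=7)
        init = PopPKModel(theta=PKParameters(0.01, 3.0, 0.03, 2.0))
        model, _ = fit_population_two_stage(profiles, init, default_tau=336.0, seed=7)
        assert model.theta_wt == pytest.approx(0.5, abs=0.25)
        assert model.theta.cl == pytest.approx(truth.theta.cl, rel=0.10)


class TestWeightCovariateTest:
    def test_matches_manual_regression_oracle(self):
        rng = np.random.default_rng(2)
        w = rng.uniform(50, 120, 17)
        cl = 0.008 * (w / 70.0) ** 0.4 * np.exp(rng.normal(0, 0.3, 17))
        res = weight_covariate_test(cl, w)
        x, y = np.log(w), np.log(cl)
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        resid = y - (y.mean() + slope * (x - x.mean()))
        se = np.sqrt(np.sum(resid**2) / (len(w) - 2) / sxx)
        t = slope / se
        p = 2 * stats.t.sf(abs(t), df=len(w) - 2)
        assert res.slope == pytest.approx(slope, rel=1e-8)
        assert res.standard_error == pytest.approx(se, rel=1e-8)
        assert res.p_value == pytest.approx(p, rel=1e-8)

    def test_perfect_association(self):
        w = np.array([50.0, 60.0, 75.0, 90.0, 110.0])
        res = weight_covariate_test(0.0001 * w, w)
        assert res.slope == pytest.approx(1.0, abs=1e-10)
        assert res.p_value < 1e-12
        assert res.significant

    def test_constant_weights_rejected(self):
        with pytest.raises(FitError):
            weight_covariate_test([0.01, 0.02, 0.01, 0.02], [70.0] * 4)

    def test_result_type(self):
        res = weight_covariate_test([0.01, 0.02, 0.015, 0.012], [50, 70, 90, 110])
        assert isinstance(res, CovariateTestResult)
        assert 0.0 <= res.p_value <= 1.0


class TestSerialization:
    def test_yaml_round_trip(self, tmp_path):
        model = PopPKModel(
            theta=PKParameters(0.0083, 3.5, 0.03, 1.5),
            theta_wt=0.42,
            omega2={"cl": 0.09, "v1": 0.05, "q": 0.1, "v2": 0.08},
            residual=ResidualErrorModel(0.17, 0.04),
        )
        path = tmp_path / "model.yaml"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded == model
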
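"""Noncompartmental analysis against closed-form and quadrature oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

from phase1pk.core_pk import DoseEvent, PKParameters, conc_2cmt_infusion
from phase1pk.nca import (
    ConcentrationProfile,
    NCAError,
    accumulation_ratio,
    auc_lin_up_log_down,
    geo_stats,
    lambda_z_fit,
    nca_single_dose,
)


def make_profile(times, concs, dose=100.0, subject="s1", **kwargs):
    return ConcentrationProfile(
        subject_id=subject,
        dose=dose,
        times=tuple(times),
        concentrations=tuple(concs),
        blq=tuple(kwargs.pop("blq", [False] * len(times))),
        **kwargs,
    )


def exhaustive_lambda_z_oracle(times, concs, tie_tol=1e-4):
    """Independent reference: score every contiguous terminal subset."""
    t = np.asarray(times, float)
    c = np.asarray(concs, float)
    imax = int(np.argmax(c))
    idx = [i for i in range(len(t)) if i > imax and c[i] > 0]
    best = None
    for start in range(len(idx) - 2):
        sel = idx[start:]
        x, y = t[sel], np.log(c[sel])
        n = len(sel)
        A = np.vstack([x, np.ones(n)]).T
        coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        yhat = A @ coef
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        lz = -coef[0]
        if lz <= 0:
            continue
        if best is None or adj > best[0] + tie_tol or (
            abs(adj - best[0]) <= tie_tol and n > best[1]
        ):
            best = (adj, n, lz)
    return best


class TestLambdaZ:
    def test_exact_monoexponential(self):
        t = np.array([2.0, 24.0, 96.0, 240.0, 480.0, 720.0])
        c = 50.0 * np.exp(-0.002 * t)
        profile = make_profile([0.0, *t], [0.0, *c])
        fit = lambda_z_fit(profile)
        assert fit is not None
        assert fit.lambda_z == pytest.approx(0.002, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_subset_matches_exhaustive_oracle(self, seed, typical_params):
        rng = np.random.default_rng(seed)
        t = np.array([0.5, 1, 2, 4, 8, 24, 72, 168, 336, 504, 1008, 1680], float)
        c = conc_2cmt_infusion(typical_params, [DoseEvent(0.0, 500.0)], t)
        c = c * np.exp(rng.normal(0.0, 0.15, size=t.size))
        profile = make_profile(t, c, dose=500.0)
        fit = lambda_z_fit(profile)
        oracle = exhaustive_lambda_z_oracle(t, c)
        assert fit is not None and oracle is not None
        assert fit.points_used == oracle[1]
        assert fit.lambda_z == pytest.approx(oracle[2], rel=1e-8)

    def test_two_post_peak_points_not_estimable(self):
        profile = make_profile([0.0, 1.0, 24.0, 48.0], [0.0, 30.0, 20.0, 15.0])
        assert lambda_z_fit(profile) is None


class TestAUC:
    def test_rectangle_constant_concentration(self):
        assert auc_lin_up_log_down([0.0, 24.0], [10.0, 10.0]) == pytest.approx(240.0)

    def test_log_trapezoid_closed_form(self):
        got = auc_lin_up_log_down([0.0, 1.0], [10.0, 5.0])
        assert got == pytest.approx((10.0 - 5.0) / np.log(2.0), rel=1e-10)
        assert got == pytest.approx(7.2135, abs=5e-5)

    def test_matches_quadrature_on_model_curve(self, typical_params):
        doses = [DoseEvent(0.0, 500.0, 0.5)]
        t = np.array([0, 0.5, 1, 2, 4, 8, 24, 48, 72, 120, 168, 252, 336], float)
        c = conc_2cmt_infusion(typical_params, doses, t)
        trapz = auc_lin_up_log_down(t, c)
        ref = sum(
            quad(lambda x: conc_2cmt_infusion(typical_params, doses, x), a, b, limit=200)[0]
            for a, b in [(0.0, 0.5), (0.5, 336.0)]
        )
        assert trapz == pytest.approx(ref, rel=5e-3)

    def test_monotone_in_t_end(self, typical_params):
        doses = [DoseEvent(0.0, 500.0, 0.5)]
        t = np.array([0, 0.5, 1, 4, 24, 96, 336], float)
        c = conc_2cmt_infusion(typical_params, doses, t)
        aucs = [auc_lin_up_log_down(t, c, t_end=te) for te in [12.0, 96.0, 200.0, 336.0]]
        assert all(a < b for a, b in zip(aucs, aucs[1:]))

    def test_partial_interval_consistent_interpolation(self):
        # log interval: AUC to the midpoint must use exponential interpolation
        full = auc_lin_up_log_down([0.0, 2.0], [10.0, 2.5])
        half = auc_lin_up_log_down([0.0, 2.0], [10.0, 2.5], t_end=1.0)
        k = np.log(4.0) / 2.0
        expected_half = (10.0 - 10.0 * np.exp(-k)) / k
        assert half == pytest.approx(expected_half, rel=1e-10)
        assert half < full

    def test_unsorted_times_rejected(self):
        with pytest.raises(NCAError):
            auc_lin_up_log_down([0.0, 2.0, 1.0], [1.0, 2.0, 3.0])

    def test_single_point_rejected(self):
        with pytest.raises(NCAError):
            auc_lin_up_log_down([0.0], [1.0])


class TestSingleDoseNCA:
    def test_half_life_from_terminal_slope(self):
        t = np.array([1.0, 24.0, 168.0, 336.0, 672.0, 1008.0])
        c = 40.0 * np.exp(-0.002 * t)
        res = nca_single_dose(make_profile([0.0, *t], [0.0, *c]), tau=336.0)
        assert res.t_half_days == pytest.approx(np.log(2) / 0.002 / 24.0, rel=1e-8)
        assert res.t_half_days == pytest.approx(14.44, abs=0.005)

    def test_unit_self_consistency(self, typical_params):
        doses = [DoseEvent(0.0, 500.0, 0.5)]
        t = np.array([0, 0.5, 1, 2, 4, 8, 24, 72, 168, 336, 672, 1344, 2016], float)
        c = conc_2cmt_infusion(typical_params, doses, t)
        res = nca_single_dose(make_profile(t, c, dose=500.0), tau=336.0)
        assert res.cl_l_per_day * res.auc_0_inf / 24.0 == pytest.approx(500.0, rel=1e-8)

    def test_model_recovery_cl_and_vss(self, typical_params):
        doses = [DoseEvent(0.0, 500.0, 0.5)]
        t = np.array([0, 0.5, 1, 2, 4, 8, 24, 72, 168, 336, 672, 1008, 1344, 2016], float)
        c = conc_2cmt_infusion(typical_params, doses, t)
        res = nca_single_dose(make_profile(t, c, dose=500.0), tau=336.0)
        assert res.cl_l_per_day / 24.0 == pytest.approx(typical_params.cl, rel=0.02)
        assert res.vss_l == pytest.approx(typical_params.vss, rel=0.05)
        assert res.auc_0_inf >= res.auc_0_last

    def test_all_blq_post_dose_raises(self):
        with pytest.raises(NCAError):
            profile = make_profile(
                [0.0, 1.0, 24.0], [0.0, 0.05, 0.02], blq=[True, True, True]
            )
            nca_single_dose(profile, tau=336.0)

    def test_blq_policy(self):
        # embedded BLQ excluded, trailing BLQ truncates
        t = [0.0, 1.0, 24.0, 96.0, 168.0, 336.0]
        c = [0.0, 30.0, 20.0, 0.0, 5.0, 0.0]
        blq = [True, False, False, True, False, True]
        profile = make_profile(t, c, blq=blq)
        tq, cq = profile.quantifiable()
        np.testing.assert_array_equal(tq, [0.0, 1.0, 24.0, 168.0])
        np.testing.assert_array_equal(cq, [0.0, 30.0, 20.0, 5.0])

    def test_ctrough_at_nominal_time(self):
        t = [0.0, 1.0, 24.0, 168.0, 330.0]
        c = [0.0, 30.0, 20.0, 10.0, 6.0]
        profile = make_profile(t, c, nominal_trough_time=336.0)
        res = nca_single_dose(profile, tau=336.0)
        assert res.ctrough == pytest.approx(6.0)
        far = make_profile(t[:-1] + [200.0], c, nominal_trough_time=336.0)
        assert nca_single_dose(far, tau=336.0).ctrough is None


class TestAccumulation:
    def test_identical_cycles_100_percent(self):
        t = [0.0, 1.0, 24.0, 168.0, 336.0]
        c = [0.0, 30.0, 20.0, 10.0, 6.0]
        r1 = nca_single_dose(make_profile(t, c), tau=336.0)
        ratio = accumulation_ratio(r1, r1)
        assert ratio.auc_tau_pct == pytest.approx(100.0)
        assert ratio.cmax_pct == pytest.approx(100.0)

    def test_one_compartment_tau_equal_half_life_doubles_auc(self):
        # near one-compartment kinetics dosed every half-life accumulate
        # to 1 / (1 - 1/2) = 200% at steady state
        params = PKParameters(cl=0.01, v1=5.0, q=1e-7, v2=1.0)
        k = params.cl / params.v1
        tau = np.log(2.0) / k
        n_ss = 40
        doses_1 = [DoseEvent(0.0, 100.0, 0.5)]
        doses_ss = [DoseEvent(i * tau, 100.0, 0.5) for i in range(n_ss + 1)]
        offsets = np.array([0.0, 0.5, 1, 2, 8, 24, 60, 120, 200, 280, tau])
        c1 = conc_2cmt_infusion(params, doses_1, offsets)
        css = conc_2cmt_infusion(params, doses_ss, n_ss * tau + offsets)
        r1 = nca_single_dose(make_profile(offsets, c1), tau=tau)
        rss = nca_single_dose(
            make_profile(offsets, css, subject="s1"), tau=tau
        )
        ratio = accumulation_ratio(rss, r1)
        assert ratio.auc_tau_pct == pytest.approx(200.0, rel=0.02)

    def test_subject_mismatch_rejected(self):
        t = [0.0, 1.0, 24.0, 168.0, 336.0]
        c = [0.0, 30.0, 20.0, 10.0, 6.0]
        ra = nca_single_dose(make_profile(t, c, subject="a"), tau=336.0)
        rb = nca_single_dose(make_profile(t, c, subject="b"), tau=336.0)
        with pytest.raises(NCAError):
            accumulation_ratio(ra, rb)


class TestGeoStats:
    def test_no_dispersion(self):
        g = geo_stats([5.0, 5.0, 5.0])
        assert g.geometric_mean == pytest.approx(5.0)
        assert g.gcv_pct == pytest.approx(0.0, abs=1e-10)

    def test_n2_reports_min_max_only(self):
        g = geo_stats([1.0, 10.0])
        assert g.geometric_mean is None and g.gcv_pct is None
        assert (g.minimum, g.maximum) == (1.0, 10.0)

    def test_formula_oracle(self):
        vals = [1.0, 10.0, 100.0]
        g = geo_stats(vals)
        logs = np.log(vals)
        expected_gcv = 100.0 * np.sqrt(np.exp(np.var(logs, ddof=1)) - 1.0)
        assert g.geometric_mean == pytest.approx(10.0, rel=1e-12)
        assert g.gcv_pct == pytest.approx(expected_gcv, rel=1e-12)

    def test_non_positive_rejected(self):
        with pytest.raises(NCAError):
            geo_stats([1.0, 0.0, 2.0])
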
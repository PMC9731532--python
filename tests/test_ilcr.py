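"""Point ILCR, lognormal calibration, MC/LHS engines, risk classification."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from baprisk.errors import EmptyInputError, InfeasibleMomentsError, ParameterError
from baprisk.ilcr import (
    DEFAULT_ED_SPEC,
    ILCRParams,
    LognormalSpec,
    RiskClass,
    RiskThresholds,
    analytic_mean_ilcr,
    classify_risk,
    compute_ilcr_point,
    fit_lognormal_from_summary,
    latin_hypercube,
    lognormal_from_mean_cv,
    risk_proportions,
    run_lhs,
    run_monte_carlo,
)


class TestPointFormula:
    def test_zero_exposure_zero_risk(self):
        assert compute_ilcr_point(0.0) == 0.0

    def test_hand_arithmetic_at_defaults(self):
        # 7.10e-6 * 365 * 43 * 7.3 / 25550 = 3.184e-5
        assert compute_ilcr_point(7.10) == pytest.approx(3.184e-5, rel=5e-4)

    @given(st.floats(0.1, 100.0), st.floats(40.0, 90.0))
    def test_bw_cancellation_identity(self, edi, bw):
        """The per-kg form equals the literal mg/day form for any body weight."""
        params = ILCRParams()
        ed_mg_per_day = edi * 1e-6 * bw
        literal = ed_mg_per_day * params.ef * params.ed * params.csf / (bw * params.at)
        assert compute_ilcr_point(edi, params) == pytest.approx(literal, rel=1e-12)

    def test_random_ed_rejected(self):
        with pytest.raises(ParameterError):
            compute_ilcr_point(1.0, ILCRParams(ed=DEFAULT_ED_SPEC))


class TestLognormalCalibration:
    def test_degenerate_mean_equals_median(self):
        spec = fit_lognormal_from_summary(5.0, 5.0)
        assert spec.mu == pytest.approx(math.log(5.0))
        assert spec.sigma == 0.0

    def test_closed_form_values(self):
        spec = fit_lognormal_from_summary(7.10, 5.20)
        assert spec.mu == pytest.approx(1.6487, abs=1e-4)
        assert spec.sigma == pytest.approx(math.sqrt(2 * math.log(7.10 / 5.20)), rel=1e-12)
        assert spec.sigma == pytest.approx(0.7892, abs=1e-4)
        assert spec.median == pytest.approx(5.20)
        assert spec.mean == pytest.approx(7.10)

    def test_infeasible_moments_raise(self):
        with pytest.raises(InfeasibleMomentsError):
            fit_lognormal_from_summary(4.0, 5.0)
        with pytest.raises(InfeasibleMomentsError):
            fit_lognormal_from_summary(4.0, 0.0)

    def test_sampling_recovers_summaries_within_1pct(self, rng):
        spec = fit_lognormal_from_summary(7.10, 5.20)
        x = spec.sample(rng, 1_000_000)
        assert np.mean(x) == pytest.approx(7.10, rel=0.01)
        assert np.median(x) == pytest.approx(5.20, rel=0.01)

    def test_parameter_recovery_roundtrip_at_1e5(self):
        """Known (mu, sigma) -> MC ILCR samples -> refit recovers mu within
        0.02 and sigma within 0.05."""
        spec = LognormalSpec(mu=1.6487, sigma=0.7894)
        params = ILCRParams()  # fixed ED so ILCR = k * EDI
        k = compute_ilcr_point(1.0, params)
        dist = run_monte_carlo(spec, params, n_iter=100_000, seed=5)
        edi_back = dist.samples / k
        refit = fit_lognormal_from_summary(float(np.mean(edi_back)), float(np.median(edi_back)))
        assert refit.mu == pytest.approx(spec.mu, abs=0.02)
        assert refit.sigma == pytest.approx(spec.sigma, abs=0.05)

    def test_mean_cv_constructor(self):
        spec = lognormal_from_mean_cv(43.0, 0.1)
        assert spec.mean == pytest.approx(43.0, rel=1e-12)
        x = spec.ppf(np.array([0.5]))
        assert x.item() < 43.0  # median below mean for sigma > 0


class TestEngines:
    def test_point_mass_inputs_reduce_to_point_formula(self):
        params = ILCRParams(ed=LognormalSpec(mu=math.log(43.0), sigma=0.0))
        expected = compute_ilcr_point(7.10, params)
        for runner in (run_monte_carlo, run_lhs):
            dist = runner(7.10, params, n_iter=100, seed=3)
            assert np.allclose(dist.samples, expected, rtol=1e-12)

    def test_seeded_runs_are_bit_identical(self):
        spec = fit_lognormal_from_summary(7.10, 5.20)
        for runner in (run_monte_carlo, run_lhs):
            a = runner(spec, n_iter=500, seed=11)
            b = runner(spec, n_iter=500, seed=11)
            assert np.array_equal(a.samples, b.samples)

    def test_engines_use_distinct_streams(self):
        spec = fit_lognormal_from_summary(7.10, 5.20)
        mc = run_monte_carlo(spec, n_iter=500, seed=11)
        lhs = run_lhs(spec, n_iter=500, seed=11)
        assert not np.array_equal(mc.samples, lhs.samples)

    def test_mc_mean_matches_analytic_expectation(self):
        """Sample mean within 3 standard errors of
        E[EDI] * 1e-6 * EF * E[ED] * CSF / AT."""
        spec = fit_lognormal_from_summary(7.10, 5.20)
        params = ILCRParams(ed=DEFAULT_ED_SPEC)
        dist = run_monte_carlo(spec, params, n_iter=10_000, seed=2)
        expected = analytic_mean_ilcr(spec.mean, params)
        assert abs(dist.mean - expected) <= 3 * dist.standard_error()

    def test_linearity_in_edi_scale(self):
        spec = LognormalSpec(mu=1.0, sigma=0.5)
        scaled = LognormalSpec(mu=1.0 + math.log(3.0), sigma=0.5)
        a = run_monte_carlo(spec, n_iter=400, seed=7)
        b = run_monte_carlo(scaled, n_iter=400, seed=7)
        assert np.allclose(b.samples, 3.0 * a.samples, rtol=1e-10)

    def test_empirical_edi_sample_accepted(self):
        edi = np.array([1.0, 2.0, 5.0, 10.0])
        dist = run_monte_carlo(edi, n_iter=1000, seed=4)
        assert dist.samples.min() >= 0
        assert dist.samples.shape == (1000,)

    def test_independent_mode_requires_bw(self):
        with pytest.raises(ParameterError, match="bw"):
            run_monte_carlo(1.0, ILCRParams(), n_iter=10, seed=0, mode="independent")

    def test_independent_mode_fixed_bw_matches_edi_mode(self):
        params = ILCRParams(ed=43.0, bw=63.46)
        a = run_monte_carlo(7.1, params, n_iter=50, seed=1, mode="edi")
        b = run_monte_carlo(7.1, params, n_iter=50, seed=1, mode="independent")
        assert np.allclose(a.samples, b.samples)


class TestLatinHypercube:
    def test_marginal_stratification_exact(self, rng):
        n = 10
        u = latin_hypercube(rng, n, 3)
        for j in range(3):
            strata = np.floor(u[:, j] * n).astype(int)
            assert sorted(strata) == list(range(n))  # one draw per [k/n, (k+1)/n)

    def test_lhs_mean_within_mc_standard_error_band(self):
        spec = fit_lognormal_from_summary(7.10, 5.20)
        params = ILCRParams(ed=DEFAULT_ED_SPEC)
        mc = run_monte_carlo(spec, params, n_iter=10_000, seed=9)
        lhs = run_lhs(spec, params, n_iter=10_000, seed=9)
        assert abs(lhs.mean - mc.mean) <= 3 * mc.standard_error()

    def test_lhs_mean_estimator_variance_not_worse_than_mc(self):
        """Over 100 replicate seeds at matched n, the LHS mean varies no more
        than the MC mean (stratification can only help the mean)."""
        spec = fit_lognormal_from_summary(7.10, 5.20)
        params = ILCRParams(ed=DEFAULT_ED_SPEC)
        mc_means = [run_monte_carlo(spec, params, n_iter=256, seed=s).mean for s in range(100)]
        lhs_means = [run_lhs(spec, params, n_iter=256, seed=s).mean for s in range(100)]
        assert np.var(lhs_means) < np.var(mc_means)


class TestClassification:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (1e-7, RiskClass.ACCEPTABLE),
            (3.37e-5, RiskClass.MODERATE),
            (2e-4, RiskClass.SERIOUS),
            (1e-6, RiskClass.MODERATE),  # boundaries are strict on both sides
            (1e-4, RiskClass.MODERATE),
        ],
    )
    def test_thresholds(self, value, expected):
        assert classify_risk(value) is expected

    def test_out_of_order_thresholds_rejected(self):
        with pytest.raises(ParameterError):
            RiskThresholds(low=1e-4, high=1e-6)

    def test_proportions_toy(self):
        props = risk_proportions([1e-7, 1e-5, 1e-3])
        assert props.as_tuple() == pytest.approx((100 / 3, 100 / 3, 100 / 3))

    def test_all_moderate(self):
        props = risk_proportions([1e-5] * 4)
        assert props.as_tuple() == (0.0, 100.0, 0.0)

    def test_counting_oracle_over_1000_samples(self, rng):
        values = rng.lognormal(math.log(3e-5), 1.5, size=1000)
        props = risk_proportions(values)
        thresholds = RiskThresholds()
        n_low = sum(1 for v in values if classify_risk(v, thresholds) is RiskClass.ACCEPTABLE)
        n_mod = sum(1 for v in values if classify_risk(v, thresholds) is RiskClass.MODERATE)
        n_high = sum(1 for v in values if classify_risk(v, thresholds) is RiskClass.SERIOUS)
        assert props.as_tuple() == (n_low / 10.0, n_mod / 10.0, n_high / 10.0)

    @given(st.lists(st.floats(1e-9, 1e-2), min_size=1, max_size=50))
    def test_proportions_sum_to_100(self, values):
        assert sum(risk_proportions(values).as_tuple()) == pytest.approx(100.0)

    def test_empty_raises(self):
        with pytest.raises(EmptyInputError):
            risk_proportions([])
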
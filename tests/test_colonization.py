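"""Likelihood inference of colonization rate and founder-group size."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from patchdemes.colonization import (
    estimate_colonization_rate, joint_ridge, loglik_empty,
    multiple_colonization_fraction, p_single, profile_dauer_rate,
    rate_from_occupancy_fraction, ridge_quadratic_fit, zt_poisson_mean,
    zt_rate_from_mean,
)
from patchdemes.records import OccupancySummary

rates = st.floats(min_value=0.01, max_value=10.0,
                  allow_nan=False, allow_infinity=False)


class TestEmptyPatchLikelihood:
    def test_closed_form_is_the_maximizer(self, survey_summary):
        mle = -math.log(survey_summary.n_empty / survey_summary.n_patches)
        grid = np.arange(0.01, 2.0, 1e-4)
        lls = [loglik_empty(l, survey_summary) for l in grid]
        assert abs(grid[int(np.argmax(lls))] - mle) < 1e-4

    def test_optimizer_agrees_with_grid_oracle(self, survey_summary):
        est = estimate_colonization_rate(survey_summary)
        grid = np.arange(0.01, 2.0, 1e-4)
        lls = [loglik_empty(l, survey_summary) for l in grid]
        assert abs(est.mle - grid[int(np.argmax(lls))]) < 1e-4

    def test_nonpositive_rate_rejected(self, survey_summary):
        with pytest.raises(ValueError):
            loglik_empty(0.0, survey_summary)


class TestRateEstimate:
    def test_closed_form_identity(self, survey_summary):
        est = estimate_colonization_rate(survey_summary)
        assert math.isclose(math.exp(-est.mle),
                            survey_summary.n_empty / survey_summary.n_patches,
                            abs_tol=1e-6)

    def test_ci_bounds_sit_at_the_drop(self, survey_summary):
        est = estimate_colonization_rate(survey_summary)
        for bound in (est.ci_low, est.ci_high):
            assert abs(loglik_empty(bound, survey_summary)
                       - (est.loglik_max - est.drop_used)) < 1e-4

    def test_two_patch_closed_form(self):
        s = OccupancySummary("sp", n_patches=2, n_occupied=1, n_single=0)
        est = estimate_colonization_rate(s)
        assert math.isclose(est.mle, math.log(2), abs_tol=1e-6)

    def test_all_empty_is_boundary_flagged(self):
        s = OccupancySummary("sp", n_patches=50, n_occupied=0, n_single=0)
        est = estimate_colonization_rate(s)
        assert est.boundary == "all_empty"
        assert est.mle == 0.0 and est.ci_low == 0.0 < est.ci_high

    def test_none_empty_is_boundary_flagged(self):
        s = OccupancySummary("sp", n_patches=50, n_occupied=50, n_single=0)
        est = estimate_colonization_rate(s)
        assert est.boundary == "none_empty"
        assert math.isnan(est.mle) and est.ci_high == math.inf

    def test_fig_occupancy_rate(self):
        # 70% occupancy implies ~1.2 colonizations per fig.
        assert round(rate_from_occupancy_fraction(0.70), 1) == 1.2


class TestZeroTruncatedMean:
    @pytest.mark.parametrize("lam,expected", [
        (0.0, 1.0),
        (3.90, 3.9806),
        (20.0, 20.0),
    ])
    def test_known_values(self, lam, expected):
        assert math.isclose(zt_poisson_mean(lam), expected, abs_tol=5e-5)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            zt_poisson_mean(-0.1)

    @given(rates)
    def test_roundtrip_with_inverse(self, lam):
        assert math.isclose(zt_rate_from_mean(zt_poisson_mean(lam)), lam,
                            rel_tol=1e-6, abs_tol=1e-9)


class TestSingleWormModel:
    @given(rates, rates)
    def test_p_single_factorizes(self, lc, ld):
        """p equals the product of the two zero-truncated one-event terms."""
        one_event = lambda lam: lam * math.exp(-lam) / -math.expm1(-lam)
        assert math.isclose(p_single(lc, ld), one_event(lc) * one_event(ld),
                            rel_tol=1e-10)

    def test_profile_agrees_with_dense_grid(self, survey_summary):
        from patchdemes.colonization import _single_loglik
        pt = profile_dauer_rate(survey_summary, 0.29)
        grid = np.arange(0.5, 8.0, 1e-4)
        lls = [_single_loglik(l, 0.29, 101, 7) for l in grid]
        assert abs(pt.lambda_d_hat - grid[int(np.argmax(lls))]) < 1e-4

    def test_closed_form_ridge_equation(self, survey_summary):
        # The interior optimum solves lam/(e^lam - 1) = phat (e^lc - 1)/lc.
        lc = 0.7
        pt = profile_dauer_rate(survey_summary, lc)
        lhs = pt.lambda_d_hat / math.expm1(pt.lambda_d_hat)
        rhs = (7 / 101) * math.expm1(lc) / lc
        assert math.isclose(lhs, rhs, rel_tol=1e-6)

    def test_unattainable_fraction_flags_no_solution(self):
        # 90 of 100 occupied patches single-worm: impossible at lambda_c = 2.
        s = OccupancySummary("sp", n_patches=100, n_occupied=100, n_single=90)
        pt = profile_dauer_rate(s, 2.0)
        assert pt.boundary == "no_solution"
        assert pt.expected_founders == 1.0


class TestJointRidge:
    def test_ridge_is_monotone_decreasing(self, survey_summary):
        pts, _ = joint_ridge(survey_summary, np.arange(0.05, 2.01, 0.05))
        founders = [p.expected_founders for p in pts]
        assert all(a > b for a, b in zip(founders, founders[1:]))

    def test_region_mask_contains_maximum(self, survey_summary):
        pts, mask = joint_ridge(survey_summary, np.arange(0.1, 2.01, 0.1))
        best = int(np.argmax([p.loglik for p in pts]))
        assert mask[best]

    def test_empty_grid_rejected(self, survey_summary):
        with pytest.raises(ValueError):
            joint_ridge(survey_summary, [])

    def test_quadratic_fit_recovers_an_exact_quadratic(self):
        from patchdemes.records import RidgePoint
        xs = np.linspace(0.1, 2.0, 25)
        pts = [RidgePoint(lambda_c=x, lambda_d_hat=1.0,
                          expected_founders=4.0 - 0.6 * x - 0.05 * x * x,
                          loglik=0.0, boundary="synthetic") for x in xs]
        coef = ridge_quadratic_fit(pts)
        assert np.allclose(coef, [4.0, -0.6, -0.05], atol=1e-8)


class TestMultipleColonization:
    def test_closed_form_at_one(self):
        expected = 1 - math.exp(-1) / (1 - math.exp(-1))
        assert math.isclose(multiple_colonization_fraction(1.0), expected,
                            rel_tol=1e-12)

    def test_vanishes_for_rare_colonizations(self):
        assert multiple_colonization_fraction(1e-8) < 1e-7

    @given(rates)
    def test_bounded_in_unit_interval(self, lam):
        assert 0 <= multiple_colonization_fraction(lam) < 1


class TestParameterRecovery:
    def test_profile_ci_covers_truth_near_nominal_rate(self):
        """95% profile CIs should cover the true rate ~95% of the time."""
        true_lam = 0.29
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            occ = rng.binomial(400, -math.expm1(-true_lam))
            s = OccupancySummary("sp", 400, int(occ), 0)
            est = estimate_colonization_rate(s)
            hits += est.ci_low <= true_lam <= est.ci_high
        assert 0.92 <= hits / n_rep <= 0.98
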
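"""Core model quantities: trajectory, hazard, closed-form integrated hazard
and per-subject likelihood contributions, checked against independent
quadrature and direct-formula oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

from jointlsm.core import (B_SWITCH_TOL, JointParams, LongitudinalRecord,
                           SubjectEffects, SurvivalRecord,
                           cumulative_hazard, hazard,
                           longitudinal_loglik_contribution,
                           piecewise_cumulative_hazard,
                           survival_loglik_contribution, trajectory)

SIGMA2 = np.array([[43.5, 3.2], [3.2, 1.7]])


def params_with(**kw):
    base = dict(beta11=38.5, beta12=1.73, sigma=2.8, Sigma=SIGMA2,
                log_lambda=np.log(0.008), alpha3=0.2, center=47.15)
    base.update(kw)
    return JointParams(**base)


ZERO = SubjectEffects(0.0, 0.0)


class TestTrajectory:
    @pytest.mark.parametrize("t,expected", [(0.0, 38.5), (10.0, 55.8)])
    def test_population_line(self, t, expected):
        assert trajectory(params_with(), ZERO, t) == pytest.approx(expected)

    def test_quadratic_population_value(self):
        p = params_with(beta11=38.5, beta12=0.8, beta13=0.3,
                        Sigma=np.array([[43.5, 3.2, -0.3],
                                        [3.2, 1.7, -0.2],
                                        [-0.3, -0.2, 0.08]]))
        assert trajectory(p, SubjectEffects(0, 0, 0), 8.0) == \
            pytest.approx(64.1)

    def test_random_effects_shift_line(self):
        eff = SubjectEffects(2.0, -0.5)
        assert trajectory(params_with(), eff, 4.0) == \
            pytest.approx(38.5 + 2 + (1.73 - 0.5) * 4)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            trajectory(params_with(), ZERO, -1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            trajectory(params_with(), ZERO, np.nan)
        with pytest.raises(ValueError):
            SubjectEffects(np.inf, 0.0)


class TestHazard:
    def test_baseline_when_no_association(self):
        p = params_with(alpha3=0.0)
        assert hazard(p, ZERO, 3.0) == pytest.approx(np.exp(-4.8283), rel=1e-3)
        assert hazard(p, ZERO, 3.0) == pytest.approx(0.008)

    def test_baseline_at_process_mean(self):
        # population trajectory crosses c = 47.15 at t = 5
        assert hazard(params_with(), ZERO, 5.0) == pytest.approx(0.008)

    def test_proportional_hazards_identity(self):
        p = params_with()
        h1 = hazard(p, SubjectEffects(0.0, 0.0), 5.0)
        h2 = hazard(p, SubjectEffects(5.0, 0.0), 5.0)  # +5 mm
        assert h2 / h1 == pytest.approx(np.exp(0.2 * 5))


class TestCumulativeHazard:
    def test_constant_hazard_limit(self):
        p = params_with(alpha3=0.0)
        assert cumulative_hazard(p, ZERO, 10.0) == pytest.approx(0.08)

    def test_zero_at_origin_and_monotone(self, nonzero_effects):
        p = params_with()
        t = np.linspace(0, 12, 200)
        H = cumulative_hazard(p, nonzero_effects, t)
        assert H[0] == 0.0
        assert np.all(np.diff(H) > 0)

    def test_matches_quadrature_oracle(self, nonzero_effects):
        p = params_with()
        H = cumulative_hazard(p, nonzero_effects, 6.0)
        Hq, err = quad(lambda s: hazard(p, nonzero_effects, s), 0, 6.0,
                       epsrel=1e-12)
        assert H == pytest.approx(Hq, rel=1e-8)

    def test_quadrature_oracle_over_random_draws(self, rng):
        # closed form vs adaptive quadrature on 100 admissible draws
        for _ in range(100):
            p = params_with(alpha1=rng.normal(0, 0.1),
                            alpha2=rng.normal(0, 0.1),
                            alpha3=rng.normal(0.1, 0.1))
            eff = SubjectEffects(rng.normal(0, 6), rng.normal(0, 1.3))
            t = rng.uniform(0.1, 12)
            H = cumulative_hazard(p, eff, t)
            Hq, _ = quad(lambda s: hazard(p, eff, s), 0, t, epsrel=1e-12,
                         limit=200)
            assert H == pytest.approx(Hq, rel=1e-8)

    def test_b_zero_limit_is_constant_hazard(self):
        p = params_with()
        eff = SubjectEffects(1.0, -p.beta12)  # b = alpha3*(beta12+u2) = 0
        a = 0.2 * (p.beta11 + 1.0 - p.center)
        expected = 0.008 * np.exp(a) * 7.0
        assert cumulative_hazard(p, eff, 7.0) == pytest.approx(expected)

    def test_series_and_ratio_branches_agree_at_switch(self):
        p = params_with()
        for sign in (+1, -1):
            b_target = sign * B_SWITCH_TOL
            u2 = b_target / p.alpha3 - p.beta12
            eff = SubjectEffects(0.5, u2)
            H = cumulative_hazard(p, eff, 10.0)
            # ratio branch computed directly at the same b
            a = 0.2 * (p.beta11 + 0.5 - p.center)
            ratio = 0.008 * np.exp(a) * np.expm1(b_target * 10) / b_target
            assert H == pytest.approx(ratio, rel=1e-10)

    def test_centering_reparameterization_invariance(self, nonzero_effects):
        # (c -> c + d, log lambda -> log lambda + alpha3*d) leaves h, H alone
        p1 = params_with()
        d = 3.7
        p2 = params_with(center=p1.center + d,
                         log_lambda=p1.log_lambda + p1.alpha3 * d)
        for t in (0.5, 4.0, 9.5):
            assert hazard(p1, nonzero_effects, t) == \
                pytest.approx(hazard(p2, nonzero_effects, t), rel=1e-12)
            assert cumulative_hazard(p1, nonzero_effects, t) == \
                pytest.approx(cumulative_hazard(p2, nonzero_effects, t),
                              rel=1e-12)

    def test_quadratic_trajectory_rejected(self):
        p = params_with(beta13=0.1, Sigma=np.array(
            [[43.5, 3.2, -0.3], [3.2, 1.7, -0.2], [-0.3, -0.2, 0.08]]))
        with pytest.raises(ValueError):
            cumulative_hazard(p, SubjectEffects(0, 0, 0), 5.0)


class TestPiecewiseCumulativeHazard:
    def test_single_band_equals_closed_form(self, nonzero_effects):
        p = params_with()
        H1 = piecewise_cumulative_hazard(p, [], [p.log_lambda],
                                         nonzero_effects, 7.0)
        assert H1 == pytest.approx(
            cumulative_hazard(p, nonzero_effects, 7.0), rel=1e-12)

    def test_equal_rates_partition_invariance(self, nonzero_effects):
        p = params_with()
        H1 = piecewise_cumulative_hazard(p, [], [p.log_lambda],
                                         nonzero_effects, 9.0)
        H2 = piecewise_cumulative_hazard(p, [2.0, 5.0],
                                         [p.log_lambda] * 3,
                                         nonzero_effects, 9.0)
        assert H2 == pytest.approx(H1, rel=1e-12)

    def test_matches_quadrature_oracle(self, nonzero_effects):
        p = params_with()
        cuts = [2.0, 5.0]
        loglams = [np.log(0.005), np.log(0.01), np.log(0.02)]

        def h(s):
            band = np.searchsorted(cuts, s, side="right")
            shifted = params_with(log_lambda=loglams[band])
            return hazard(shifted, nonzero_effects, s)

        for t in (1.5, 4.0, 8.5):
            Hq = sum(quad(h, lo, min(hi, t), epsrel=1e-12)[0]
                     for lo, hi in [(0, 2), (2, 5), (5, np.inf)]
                     if t > lo)
            H = piecewise_cumulative_hazard(p, cuts, loglams,
                                            nonzero_effects, t)
            assert H == pytest.approx(Hq, rel=1e-8)

    def test_bad_bands_rejected(self, nonzero_effects):
        p = params_with()
        with pytest.raises(ValueError):
            piecewise_cumulative_hazard(p, [5.0, 2.0], [1, 1, 1],
                                        nonzero_effects, 3.0)
        with pytest.raises(ValueError):
            piecewise_cumulative_hazard(p, [2.0], [1.0], nonzero_effects,
                                        3.0)


class TestLoglikContributions:
    def test_censored_constant_hazard(self):
        p = params_with(alpha3=0.0)
        rec = SurvivalRecord("a", 10.0, 0)
        assert survival_loglik_contribution(p, ZERO, rec) == \
            pytest.approx(-0.08)

    def test_event_constant_hazard(self):
        p = params_with(alpha3=0.0)
        rec = SurvivalRecord("a", 10.0, 1)
        assert survival_loglik_contribution(p, ZERO, rec) == \
            pytest.approx(np.log(0.008) - 0.08)

    def test_event_density_equals_quadrature_survivor_oracle(
            self, nonzero_effects):
        p = params_with()
        T = 6.5
        rec = SurvivalRecord("a", T, 1)
        Hq, _ = quad(lambda s: hazard(p, nonzero_effects, s), 0, T,
                     epsrel=1e-12)
        expected = np.log(hazard(p, nonzero_effects, T)) - Hq
        assert survival_loglik_contribution(p, nonzero_effects, rec) == \
            pytest.approx(expected, rel=1e-8)

    def test_single_point_on_trajectory(self):
        p = params_with(sigma=1.0)
        recs = [LongitudinalRecord("a", 2.0, trajectory(p, ZERO, 2.0))]
        assert longitudinal_loglik_contribution(p, ZERO, recs) == \
            pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_two_points_unit_deviations(self):
        p = params_with(sigma=1.0)
        recs = [
            LongitudinalRecord("a", 0.0, trajectory(p, ZERO, 0.0) + 1),
            LongitudinalRecord("a", 2.0, trajectory(p, ZERO, 2.0) - 1),
        ]
        assert longitudinal_loglik_contribution(p, ZERO, recs) == \
            pytest.approx(-np.log(2 * np.pi) - 1.0)

    def test_matches_normal_density_oracle(self, rng, nonzero_effects):
        from scipy.stats import norm
        p = params_with()
        recs = [LongitudinalRecord("a", t, rng.normal(45, 8))
                for t in (0.0, 2.0, 4.0)]
        expected = sum(
            norm.logpdf(r.response,
                        trajectory(p, nonzero_effects, r.time), p.sigma)
            for r in recs)
        got = longitudinal_loglik_contribution(p, nonzero_effects, recs)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            longitudinal_loglik_contribution(params_with(), ZERO, [])


class TestParamValidation:
    def test_default_center_is_process_mean(self):
        p = JointParams(beta11=38.5, beta12=1.73, sigma=2.8, Sigma=SIGMA2,
                        log_lambda=np.log(0.008))
        assert p.center == pytest.approx(47.15)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            params_with(sigma=-1.0)

    def test_non_pd_Sigma_rejected(self):
        with pytest.raises(ValueError):
            params_with(Sigma=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            params_with(Sigma=np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_roundtrip_dict(self):
        p = params_with(alpha1=0.05)
        q = JointParams.from_dict(p.to_dict())
        assert q.to_dict() == pytest.approx(p.to_dict())
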
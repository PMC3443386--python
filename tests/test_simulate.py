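"""Synthetic data generator: distributional checks against closed-form
moments, inverse-transform correctness (KS against the model survivor
function), censoring-rule invariants and scenario definitions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from jointlsm.core import JointParams, SubjectEffects, cumulative_hazard
from jointlsm.simulate import (ScenarioSpec, apply_censoring,
                               draw_subject_effects, make_scenario,
                               simulate, simulate_event_times,
                               simulate_measurements)


class TestScenarios:
    def test_table1_definition(self):
        spec = make_scenario("table1")
        p = spec.params
        assert p.alpha3 == pytest.approx(0.2)
        assert p.log_lambda == pytest.approx(np.log(0.008))
        assert spec.threshold is None
        assert p.center == pytest.approx(47.15)
        np.testing.assert_allclose(spec.exam_times, [0, 2, 4, 6, 8])

    def test_table2_has_threshold_and_same_longitudinal_truth(self):
        s1, s2 = make_scenario("table1"), make_scenario("table2")
        assert s2.threshold == 55.0
        assert s2.params.alpha3 == pytest.approx(0.22)
        for attr in ("beta11", "beta12", "sigma"):
            assert getattr(s2.params, attr) == getattr(s1.params, attr)
        np.testing.assert_allclose(s2.params.Sigma, s1.params.Sigma)

    def test_table3_gross_quadratic_truth(self):
        spec = make_scenario("table3_gross")
        p = spec.params
        assert (p.beta11, p.beta12, p.beta13) == (38.5, 0.8, 0.3)
        assert p.Sigma.shape == (3, 3)
        np.testing.assert_allclose(
            p.Sigma, [[43.5, 3.2, -0.3], [3.2, 1.7, -0.2],
                      [-0.3, -0.2, 0.08]])

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            make_scenario("table9")


class TestEffects:
    def test_sample_moments_match_Sigma(self):
        spec = make_scenario("table1", n_subjects=100_000)
        U = draw_subject_effects(spec, np.random.default_rng(7))
        # 3-MC-SE bands for variances and the implied correlation
        v1, v2 = U[:, 0].var(), U[:, 1].var()
        assert abs(v1 - 43.5) < 3 * 43.5 * np.sqrt(2 / 1e5)
        assert abs(v2 - 1.7) < 3 * 1.7 * np.sqrt(2 / 1e5)
        rho = np.corrcoef(U.T)[0, 1]
        assert rho == pytest.approx(3.2 / np.sqrt(43.5 * 1.7), abs=0.01)

    def test_zero_Sigma_rejected(self):
        with pytest.raises(ValueError):
            JointParams(beta11=38.5, beta12=1.73, sigma=2.8,
                        Sigma=np.zeros((2, 2)), log_lambda=np.log(0.008))


class TestMeasurements:
    def test_noise_free_limit_is_trajectory(self):
        spec = make_scenario("table1", n_subjects=50)
        spec.params.sigma = 1e-12
        rng = np.random.default_rng(0)
        U = draw_subject_effects(spec, rng)
        y = simulate_measurements(spec, U, rng)
        mu = (spec.params.beta11 + U[:, 0:1]
              + (spec.params.beta12 + U[:, 1:2]) * spec.exam_times)
        np.testing.assert_allclose(y, mu, atol=1e-6)

    def test_baseline_mean_and_variance(self):
        spec = make_scenario("table1", n_subjects=100_000)
        rng = np.random.default_rng(11)
        U = draw_subject_effects(spec, rng)
        y0 = simulate_measurements(spec, U, rng)[:, 0]
        mc_se = np.sqrt(51.34 / 1e5)
        assert abs(y0.mean() - 38.5) < 3 * mc_se
        # var = Sigma11 + sigma^2 = 43.5 + 7.84
        assert y0.var() == pytest.approx(51.34, rel=0.02)


class TestEventTimes:
    def test_exponential_limit_when_no_association(self):
        spec = make_scenario("table1", n_subjects=100_000)
        spec.params.alpha3 = 0.0
        rng = np.random.default_rng(3)
        U = draw_subject_effects(spec, rng)
        T = simulate_event_times(spec.params, U, rng)
        assert np.isfinite(T).all()
        assert abs(T.mean() - 125.0) < 3 * 125.0 / np.sqrt(1e5)

    def test_ks_against_survivor_function(self, table1_params):
        # fixed effects vector: T should follow 1 - exp(-H(t))
        eff = SubjectEffects(2.0, 0.5)
        U = np.tile([2.0, 0.5], (10_000, 1))
        rng = np.random.default_rng(99)
        T = simulate_event_times(table1_params, U, rng)
        T = T[np.isfinite(T)]

        def cdf(t):
            return 1 - np.exp(-cumulative_hazard(table1_params, eff, t))

        res = sps.kstest(T, cdf)
        assert res.pvalue > 0.01

    def test_negative_drift_yields_infinite_times(self, table1_params):
        # u2 well below -beta12 makes H bounded; large E draws never fail
        U = np.tile([0.0, -5.0], (2000, 1))
        rng = np.random.default_rng(5)
        T = simulate_event_times(table1_params, U, rng)
        assert np.isinf(T).any()

    def test_quadratic_inversion_matches_closed_form_when_linear(self):
        # a vanishing quadratic effect forces the grid-inversion path while
        # leaving the trajectory effectively linear: the numerically
        # inverted times must match the closed-form inverse
        p3 = make_scenario("table3_gross").params
        p = JointParams(beta11=38.5, beta12=1.73, beta13=0.0, sigma=2.8,
                        Sigma=p3.Sigma.copy(), log_lambda=p3.log_lambda,
                        alpha3=0.2, center=47.15)
        U = np.tile([1.0, 0.2, 1e-12], (200, 1))
        p_lin = JointParams(beta11=38.5, beta12=1.73, sigma=2.8,
                            Sigma=p3.Sigma[:2, :2].copy(),
                            log_lambda=p3.log_lambda, alpha3=0.2,
                            center=47.15)
        T_quad = simulate_event_times(p, U, np.random.default_rng(8))
        T_lin = simulate_event_times(p_lin, U[:, :2],
                                     np.random.default_rng(8))
        both = np.isfinite(T_quad) & np.isfinite(T_lin) & (T_lin < 10)
        assert both.sum() > 30
        np.testing.assert_allclose(T_quad[both], T_lin[both], atol=2e-4)


class TestCensoring:
    def test_same_seed_bit_identical(self):
        a = simulate(make_scenario("table2", n_subjects=200, seed=42))
        b = simulate(make_scenario("table2", n_subjects=200, seed=42))
        pd.testing.assert_frame_equal(a.data.longitudinal,
                                      b.data.longitudinal)
        pd.testing.assert_frame_equal(a.data.survival, b.data.survival)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_event_iff_failure_strictly_first(self):
        spec = make_scenario("table1", n_subjects=4)
        y = np.full((4, 5), 40.0)
        U = np.zeros((4, 2))
        true_T = np.array([3.0, np.inf, 9.99, 11.0])
        C1 = np.array([10.0, 10.0, 10.0, 10.0])
        ds = apply_censoring(spec, true_T, y, U, C1)
        sur = ds.data.survival
        np.testing.assert_allclose(sur["time"], [3.0, 10.0, 9.99, 10.0])
        np.testing.assert_array_equal(sur["event"], [1, 0, 1, 0])
        # subject 1: measurements at t=0,2 only
        times = ds.data.longitudinal.query("id == 1")["time"].to_numpy()
        np.testing.assert_allclose(times, [0.0, 2.0])

    def test_threshold_censors_at_first_crossing(self):
        spec = make_scenario("table2", n_subjects=1)
        y = np.array([[40.0, 46.0, 56.0, 60.0, 62.0]])
        U = np.zeros((1, 2))
        ds = apply_censoring(spec, np.array([7.0]), y, U, np.array([9.0]))
        sur = ds.data.survival
        assert sur.loc[0, "time"] == 4.0  # first exam with y >= 55
        assert sur.loc[0, "event"] == 0
        # the triggering measurement itself is retained
        lon = ds.data.longitudinal
        assert lon["time"].max() == 4.0
        assert lon["y"].iloc[-1] == 56.0

    def test_invariants_on_simulated_scenarios(self):
        for name in ("table1", "table2", "table3_gross"):
            ds = simulate(make_scenario(name, n_subjects=400, seed=1234))
            sur = ds.data.survival
            lon = ds.data.longitudinal
            spec = ds.spec
            assert (sur["time"] <= spec.admin_horizon + 1e-12).all()
            last = lon.groupby("id")["time"].max()
            assert (last.to_numpy()
                    <= sur.set_index("id").loc[last.index, "time"]
                    .to_numpy() + 1e-12).all()
            merged = lon.merge(sur, on="id", suffixes=("", "_s"))
            if spec.threshold is not None:
                # baseline crossings censor ~1 day after entry, so the t=0
                # measurement is the one admissible pre-censoring crossing
                before = merged[(merged["time"] < merged["time_s"] - 1e-9)
                                & (merged["time"] > 0)]
                assert (before["y"] < spec.threshold).all()
            # event implies the latent failure time was the strict minimum
            tr = ds.truth.set_index("id")
            ev = sur[sur["event"] == 1].set_index("id")
            np.testing.assert_allclose(
                ev["time"], tr.loc[ev.index, "true_time"])

    def test_every_subject_retains_baseline_measurement(self):
        ds = simulate(make_scenario("table1", n_subjects=2000, seed=77))
        counts = ds.data.longitudinal.groupby("id").size()
        assert len(counts) == 2000
        assert (counts >= 1).all()


class TestEventRates:
    def test_rates_under_generating_process(self):
        # under the continuous current-value hazard link the linear scenario
        # produces ~2.2 events per 100 person-years and the threshold
        # scenario ~0.9; both are stable properties of this generator
        ev1 = py1 = ev2 = py2 = 0.0
        for r in range(30):
            d1 = simulate(make_scenario("table1", n_subjects=1000,
                                        seed=500 + r))
            d2 = simulate(make_scenario("table2", n_subjects=1000,
                                        seed=900 + r))
            ev1 += d1.data.n_events; py1 += d1.data.person_years
            ev2 += d2.data.n_events; py2 += d2.data.person_years
        assert 100 * ev1 / py1 == pytest.approx(2.2, abs=0.25)
        assert 100 * ev2 / py2 == pytest.approx(0.9, abs=0.2)

    def test_scenario_spec_validation(self):
        spec = make_scenario("table1")
        with pytest.raises(ValueError):
            ScenarioSpec(params=spec.params, n_subjects=0)
        with pytest.raises(ValueError):
            ScenarioSpec(params=spec.params, exam_times=[0, 2, 11])
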
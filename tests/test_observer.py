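"""Generative observer: adaptation dynamics, proprioception, policies, sessions."""

import numpy as np
import pandas as pd
import pytest

from clampconf import (
    ConfigurationError,
    ObserverParams,
    SessionDesign,
    fourier_component,
    generate_confidence,
    generate_report,
    lti_response,
    make_clamp_sequence,
    phase_to_lag,
    sense_hand,
    simulate_adaptation,
    simulate_cohort,
    simulate_pretest,
    simulate_session,
)


def steady_state_reach(params: ObserverParams, design: SessionDesign, warm_cycles: int = 100):
    """Noise-free reach over one session after the transient has decayed.

    The warmup spans whole cycles, so the analysis window keeps the phase
    origin of trial 1.
    """
    warm = SessionDesign(
        n_trials=design.n_trials + warm_cycles * design.trials_per_cycle,
        trials_per_cycle=design.trials_per_cycle,
        clamp_amplitude=design.clamp_amplitude,
    )
    x, _ = simulate_adaptation(params, make_clamp_sequence(warm), np.random.default_rng(0))
    return x[-design.n_trials:]


class TestAdaptationDynamics:
    def test_zero_learning_rate_means_no_adaptation(self, clamp, rng):
        params = ObserverParams(learning_rate=0.0, sigma_m=4.0)
        x, reach = simulate_adaptation(params, clamp, rng)
        assert np.all(x == 0.0)
        assert np.std(reach) == pytest.approx(4.0, rel=0.15)  # pure motor noise

    def test_recursion_matches_hand_rolled_loop(self, clamp, rng):
        params = ObserverParams(retention=0.9, learning_rate=0.2, sigma_m=1.0)
        x, _ = simulate_adaptation(params, clamp, rng)
        expected = np.zeros(clamp.size)
        for t in range(1, clamp.size):
            expected[t] = 0.9 * expected[t - 1] - 0.2 * clamp[t - 1]
        np.testing.assert_allclose(x, expected, atol=1e-12)

    @pytest.mark.parametrize("retention,learning_rate", [(0.95, 0.1), (0.5, 0.5468), (0.0, 0.3)])
    def test_steady_state_matches_closed_form(self, design, retention, learning_rate):
        params = ObserverParams(retention=retention, learning_rate=learning_rate, sigma_m=1e-12)
        reach = steady_state_reach(params, design)
        amp, phase = fourier_component(reach, design.cycles_per_session)
        lag = phase_to_lag(phase, design.cycles_per_session, "clamp_sine", design)
        gain, lag_oracle = lti_response(retention, learning_rate, design.trials_per_cycle)
        assert amp == pytest.approx(gain * design.clamp_amplitude, abs=1e-8)
        assert lag == pytest.approx(lag_oracle, abs=1e-8)
        assert 10.0 < lag < 20.0  # anti-phase plus a learning delay


class TestLtiResponse:
    def test_vanishing_memory_limit_is_one_step_delayed_antiphase(self):
        _, lag = lti_response(1e-9, 1e-9, 20)
        assert lag == pytest.approx(11.0, abs=1e-6)

    def test_gain_monotone_in_learning_rate(self):
        gains = [lti_response(0.8, b, 20)[0] for b in (0.05, 0.1, 0.2, 0.4)]
        assert np.all(np.diff(gains) > 0)

    def test_lag_exceeds_half_cycle_for_all_retentions(self):
        for a in np.linspace(0.0, 0.999, 25):
            _, lag = lti_response(a, 0.1, 20)
            assert 10.0 < lag < 20.0

    def test_unstable_learner_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            lti_response(1.0, 0.1, 20)


class TestProprioception:
    def test_noise_has_requested_spread_and_no_bias(self, rng):
        reach = np.zeros(100_000)
        sensed = sense_hand(reach, 7.16, rng)
        assert np.std(sensed - reach) == pytest.approx(7.16, rel=0.02)
        assert np.mean(sensed - reach) == pytest.approx(0.0, abs=0.1)

    def test_nonpositive_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            sense_hand(np.zeros(5), 0.0, rng)


class TestReportPolicies:
    @pytest.fixture
    def noiseless(self):
        def make(policy, **kw):
            return ObserverParams(report_policy=policy, report_noise_sd=0.0, **kw)

        return make

    def test_motor_plan_reports_the_aim(self, noiseless):
        report = generate_report(np.array([5.0, -3.0]), np.array([10.0, -10.0]), noiseless("motor_plan"))
        np.testing.assert_array_equal(report, [0.0, 0.0])

    def test_feedback_pulled_tracks_the_clamp(self, noiseless):
        clamp = np.array([10.0, -4.0])
        report = generate_report(np.array([1.0, 2.0]), clamp, noiseless("feedback_pulled"))
        np.testing.assert_array_equal(report, clamp)

    def test_proprioceptive_report_is_map_shrunk(self, noiseless):
        p = noiseless("proprioceptive_antiphase", sigma_m=4.0, sigma_p=4.0)
        report = generate_report(np.array([10.0]), np.array([0.0]), p)
        assert report[0] == pytest.approx(5.0)  # equal reliabilities halve s

    def test_tiny_proprioceptive_noise_reports_the_hand(self, noiseless):
        p = noiseless("proprioceptive_antiphase", sigma_m=4.0, sigma_p=1e-6)
        reach = np.array([7.3, -2.1])
        assert generate_report(reach, np.zeros(2), p) == pytest.approx(reach, abs=1e-9)

    def test_full_weight_on_feedback_is_the_clamp(self, noiseless):
        p = noiseless("weighted_combination", report_weight=1.0)
        clamp = np.array([-6.0, 8.0])
        np.testing.assert_array_equal(generate_report(np.array([1.0, 1.0]), clamp, p), clamp)

    def test_missing_policy_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_report(np.zeros(2), np.zeros(2), ObserverParams())


class TestConfidencePolicies:
    def test_prior_only_is_constant_baseline(self, design):
        p = ObserverParams(confidence_policy="prior_only", conf_baseline=8.0, conf_noise_sd=0.0)
        arc = generate_confidence(np.array([10.0, -10.0]), np.array([3.0, 1.0]), p, design)
        np.testing.assert_array_equal(arc, [8.0, 8.0])

    def test_aligned_signals_leave_mismatch_policy_at_baseline(self, design):
        p = ObserverParams(confidence_policy="mismatch_driven", conf_baseline=5.0, conf_noise_sd=0.0)
        clamp = np.array([4.0, -7.0])
        arc = generate_confidence(clamp, clamp, p, design)
        np.testing.assert_array_equal(arc, [5.0, 5.0])

    def test_feedback_policy_doubles_the_clamp_frequency(self, design, clamp):
        p = ObserverParams(confidence_policy="feedback_driven", conf_gain=0.5, conf_noise_sd=0.0)
        arc = np.asarray(generate_confidence(clamp, np.zeros_like(clamp), p, design))
        spectrum = np.abs(np.fft.rfft(arc - arc.mean()))
        assert np.argmax(spectrum) == 2 * design.cycles_per_session

    def test_arcs_clipped_into_valid_range(self, design):
        p = ObserverParams(confidence_policy="prior_only", conf_baseline=0.0, conf_noise_sd=50.0)
        arc = np.asarray(
            generate_confidence(np.zeros(500), np.zeros(500), p, design, np.random.default_rng(0))
        )
        assert np.all(arc >= 0.1) and np.all(arc <= design.wager_max_arc)


class TestSessions:
    def test_default_session_shape_and_schema(self, design):
        s = simulate_session(ObserverParams(seed=3), design)
        assert len(s) == 240
        np.testing.assert_array_equal(s["trial"], np.arange(1, 241))
        assert s["clamp_dir"].iloc[0] == 0.0
        assert "report_dir" not in s.columns
        assert np.all(s["confidence_arc"] > 0)
        assert np.all((s["points"] >= 0) & (s["points"] <= 10))
        assert np.all(s.loc[s["points"] > 0, "captured"])

    def test_same_seed_is_bit_identical(self, ma_design):
        p = ObserverParams(report_policy="weighted_combination", seed=11)
        a = simulate_session(p, ma_design)
        b = simulate_session(p, ma_design)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_observer_sits_at_target_and_baseline(self, design):
        p = ObserverParams(
            sigma_m=1e-9,
            sigma_p=1e-9,
            learning_rate=0.0,
            confidence_policy="prior_only",
            conf_baseline=6.0,
            conf_noise_sd=0.0,
            seed=0,
        )
        s = simulate_session(p, design)
        assert np.allclose(s["reach_dir"], 0.0, atol=1e-6)
        assert np.allclose(s["confidence_arc"], 6.0)

    def test_task_policy_mismatch_rejected(self, design, ma_design):
        with pytest.raises(ConfigurationError):
            simulate_session(ObserverParams(report_policy="motor_plan"), design)
        with pytest.raises(ConfigurationError):
            simulate_session(ObserverParams(), ma_design)

    def test_initial_arc_respects_task_range(self, ma_design):
        p = ObserverParams(report_policy="motor_plan", seed=2)
        s = simulate_session(p, ma_design)
        assert s["initial_arc"].min() >= 1.0 and s["initial_arc"].max() <= 20.0


class TestCohort:
    def test_cohort_size_and_reproducibility(self, design):
        a, ta = simulate_cohort(20, ObserverParams(), design, seed=5)
        b, tb = simulate_cohort(20, ObserverParams(), design, seed=5)
        assert len(a) == 20 and len(ta) == 20
        pd.testing.assert_frame_equal(ta, tb)
        pd.testing.assert_frame_equal(a[7], b[7])

    def test_point_mass_sampler_gives_identical_params_distinct_noise(self, design):
        sessions, truth = simulate_cohort(3, ObserverParams(sigma_m=2.0), design, seed=1)
        assert truth["sigma_m"].nunique() == 1
        assert not np.array_equal(sessions[0]["reach_dir"], sessions[1]["reach_dir"])

    def test_pretest_follows_forward_model(self):
        rng = np.random.default_rng(9)
        pre = simulate_pretest(3.99, 7.16, 5000, rng)
        k = 3.99**2 / (3.99**2 + 7.16**2)
        assert np.std(pre["reach_dir"]) == pytest.approx(3.99, rel=0.05)
        # reports regress on endpoints with slope k under the ideal model
        slope = np.polyfit(pre["reach_dir"], pre["report_dir"], 1)[0]
        assert slope == pytest.approx(k, abs=0.03)
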
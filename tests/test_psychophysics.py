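"""Psychophysical estimators: feedforward windowing, adaptation rate,
staircase JND, controller noise, internal-model uncertainty."""

import math

import numpy as np
import pytest

from myopsych import SubjectModel, simulate_adaptation_series
from myopsych.core import Z_084
from myopsych.psychophysics import (
    StaircaseState,
    compute_internal_model_uncertainty,
    estimate_adaptation_rate,
    estimate_controller_noise,
    feedforward_segment,
    run_jnd_experiment,
    staircase_threshold,
    staircase_to_csv,
    staircase_update,
)
from myopsych.strategies import StrategyConfig
from myopsych.task import BlockSpec, Target, TrialLog, run_block, run_steady_hold


def make_log(t, raw, target=None):
    t = np.asarray(t, dtype=float)
    raw = np.asarray(raw, dtype=float)
    n = len(t)
    from myopsych.strategies import AudioFrame

    return TrialLog(target=target or Target(center=(25.0, 0.0)),
                    t=t, pos=np.zeros((n, 2)), raw=raw, gated=raw.copy(),
                    audio=[AudioFrame()] * n, movement_onset_time=0.0,
                    outcome="acquired")


class TestFeedforwardWindow:
    def test_constant_activation_passthrough(self):
        t = np.arange(0, 0.40, 0.016)
        raw = np.tile([0.4, 0.1], (len(t), 1))
        assert feedforward_segment(make_log(t, raw)) == pytest.approx((0.4, 0.1))

    def test_window_excludes_onset_transient(self):
        t = np.arange(0, 0.40, 0.016)
        raw = np.zeros((len(t), 2))
        raw[t >= 0.100, 0] = 0.6
        assert feedforward_segment(make_log(t, raw))[0] == pytest.approx(0.6)

    def test_boundary_closure(self):
        # 99 ms excluded; 100 ms and 230 ms included
        t = np.array([0.0, 0.099, 0.100, 0.150, 0.230, 0.231])
        raw = np.stack([np.array([9.0, 9.0, 1.0, 2.0, 3.0, 9.0]),
                        np.zeros(6)], axis=1)
        assert feedforward_segment(make_log(t, raw))[0] == pytest.approx(2.0)

    def test_short_trial_rejected(self):
        t = np.arange(0, 0.20, 0.016)
        with pytest.raises(ValueError):
            feedforward_segment(make_log(t, np.zeros((len(t), 2))))


class TestAdaptationRate:
    def test_perfect_compensation_from_logs(self):
        s = SubjectModel(adaptation_gain=1.0, sigma_sens=0.0, sigma_cntl=0.0,
                         motor_noise=0.0, rng_seed=0)
        logs = run_block(s, StrategyConfig("RAW"), BlockSpec.adaptation(), seed=0)
        est = estimate_adaptation_rate(logs)
        assert est.rate == pytest.approx(1.0, abs=0.01)

    def test_zero_gain_near_zero_rate(self):
        s = SubjectModel(adaptation_gain=0.0, rng_seed=1)
        series = simulate_adaptation_series(s, 80, seed=1)
        assert abs(estimate_adaptation_rate(series).rate) < 0.05

    def test_gain_sweep_recovery(self):
        # estimator consistency across the physiological gain range
        for gain in (0.2, 0.46, 0.8, 1.2):
            s = SubjectModel(adaptation_gain=gain)
            rates = [estimate_adaptation_rate(
                simulate_adaptation_series(s, 80, seed=seed)).rate
                for seed in range(20)]
            assert abs(np.mean(rates) - gain) < 0.05, gain

    def test_zero_error_variance_flagged(self):
        u = np.zeros(40)
        est = estimate_adaptation_rate((u, u))
        assert est.flagged and math.isnan(est.rate)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            estimate_adaptation_rate((np.arange(5.0), np.arange(5.0)))


class TestStaircase:
    def test_update_moves_level_by_weighted_steps(self):
        st = StaircaseState(current_level=50.0, step_down=1.0)
        assert st.step_up == pytest.approx(5.25)
        staircase_update(st, correct=True)
        assert st.current_level == pytest.approx(49.0)
        staircase_update(st, correct=False)
        assert st.current_level == pytest.approx(49.0 + 5.25)

    def test_alternating_responses_accumulate_reversals(self):
        st = StaircaseState(current_level=50.0, step_down=1.0)
        for i in range(10):
            staircase_update(st, correct=(i % 2 == 0))
        assert st.n_reversals == 9  # every flip after the first response

    def test_all_correct_monotone_floored_no_reversals(self):
        st = StaircaseState(current_level=3.0, step_down=1.0)
        for _ in range(10):
            staircase_update(st, correct=True)
        assert st.current_level == 0.0
        assert st.n_reversals == 0

    def test_terminates_at_23_reversals_and_rejects_updates(self):
        st = StaircaseState(current_level=50.0, step_down=1.0)
        i = 0
        while not st.terminated:
            staircase_update(st, correct=(i % 2 == 0))
            i += 1
        assert st.n_reversals == 23
        with pytest.raises(RuntimeError):
            staircase_update(st, correct=True)

    def test_threshold_is_23rd_reversal_level(self):
        st = StaircaseState(current_level=50.0, step_down=1.0)
        i = 0
        while not st.terminated:
            staircase_update(st, correct=(i % 2 == 0))
            i += 1
        assert staircase_threshold(st) == st.reversal_levels[22]

    def test_premature_threshold_rejected(self):
        with pytest.raises(RuntimeError):
            staircase_threshold(StaircaseState())

    def test_invalid_step_ratio_rejected(self):
        with pytest.raises(ValueError):
            StaircaseState(step_down=1.0, step_up=2.0)


class TestJNDExperiment:
    def test_converges_near_84_percent_level(self):
        s = SubjectModel(psychometric_slope=30.0)
        expected = 30.0 * math.sqrt(2.0) * Z_084
        jnds = [run_jnd_experiment(s, seed=seed).jnd for seed in range(50)]
        assert np.mean(jnds) == pytest.approx(expected, rel=0.10)

    def test_threshold_scales_with_observer_slope(self):
        jnd_1 = [run_jnd_experiment(SubjectModel(psychometric_slope=20.0),
                                    seed=s).jnd for s in range(50)]
        jnd_2 = [run_jnd_experiment(SubjectModel(psychometric_slope=40.0),
                                    seed=s).jnd for s in range(50)]
        ratio = np.mean(jnd_2) / np.mean(jnd_1)
        assert ratio == pytest.approx(2.0, rel=0.15)
        # stochastic dominance of the threshold distribution
        assert np.mean(jnd_2) > np.mean(jnd_1)

    def test_equilibrium_accuracy_at_tracked_levels(self):
        # long-run fraction correct after burn-in converges to 0.84
        from myopsych.subject import p_correct_2ifc

        for slope in (20.0, 40.0):
            s = SubjectModel(psychometric_slope=slope)
            fracs = []
            for seed in range(40):
                res = run_jnd_experiment(s, seed=seed)
                st = res.state
                if st.n_reversals < 4:
                    continue
                # trials after the 4th reversal are the converged regime
                idx = [i for i, f in enumerate(st.reversal_flags) if f][3]
                fracs.append(np.mean(
                    [p_correct_2ifc(lv, slope) for lv in st.levels[idx:]]))
            assert np.mean(fracs) == pytest.approx(0.84, abs=0.03)

    def test_max_trial_guard_flags_run(self, subject):
        res = run_jnd_experiment(subject, max_trials=20)
        assert res.flagged and "max_trials" in res.flag_reason

    def test_history_csv(self, tmp_path, subject):
        res = run_jnd_experiment(subject, seed=0)
        staircase_to_csv(res.state, tmp_path / "stair.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "stair.csv")
        assert df["reversal"].sum() == 23
        assert len(df) == res.state.trial_count


class TestControllerNoise:
    def test_noiseless_subject_zero(self):
        s = SubjectModel(sigma_cntl=0.0)
        hold = run_steady_hold(s, StrategyConfig("RAW"), 2.0, seed=0)
        assert estimate_controller_noise([hold[:, 0]]) == 0.0

    def test_recovers_known_sd(self):
        s = SubjectModel(sigma_cntl=0.1, rng_seed=0)
        hold = run_steady_hold(s, StrategyConfig("RAW"), 5.0, seed=3)
        assert estimate_controller_noise([hold[:, 0]]) == pytest.approx(0.1, abs=0.02)

    def test_invariant_to_held_level(self):
        s = SubjectModel(sigma_cntl=0.05, rng_seed=0)
        ests = []
        for intent in (0.2, 0.8):
            hold = run_steady_hold(s, StrategyConfig("RAW"), 5.0, seed=4,
                                   intent=(intent, 0.0))
            ests.append(estimate_controller_noise([hold[:, 0]]))
        assert ests[0] == pytest.approx(ests[1], abs=0.02)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            estimate_controller_noise([np.zeros(10)])


class TestInternalModelUncertainty:
    def test_zero_rate_gives_zero_uncertainty(self):
        est = compute_internal_model_uncertainty(0.0, jnd=40.0, sigma_cntl_hat=0.1)
        assert est.p_param == 0.0

    def test_monotone_in_rate_and_jnd(self):
        base = compute_internal_model_uncertainty(0.5, 40.0, 0.1).p_param
        assert compute_internal_model_uncertainty(0.6, 40.0, 0.1).p_param > base
        assert compute_internal_model_uncertainty(0.5, 50.0, 0.1).p_param > base

    def test_saturation_flagged_at_unit_rate(self):
        est = compute_internal_model_uncertainty(1.0, 40.0, 0.1)
        assert est.saturated and math.isinf(est.p_param)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_internal_model_uncertainty(0.5, 0.0, 0.1)

    def test_round_trip_recovery(self):
        # generate subjects with known (P, R); the estimator chain recovers P
        p_true, R = 0.06, 784.0
        ests = []
        for seed in range(20):
            s = SubjectModel.from_internal_model(p_true, R, rng_seed=seed)
            series = simulate_adaptation_series(s, 80, seed=1000 + seed)
            rate = estimate_adaptation_rate(series).rate
            jnd = run_jnd_experiment(s, seed=2000 + seed).jnd
            hold = run_steady_hold(s, StrategyConfig("RAW"), 2.0, seed=3000 + seed)
            sc = estimate_controller_noise([hold[:, 0]])
            ests.append(compute_internal_model_uncertainty(
                rate, jnd, sc, sigma_sens=s.sigma_sens).p_param)
        assert abs(np.mean(ests) - p_true) / p_true < 0.20
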
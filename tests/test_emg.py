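"""Signal chain: filter design, feature extraction, windowing, SVR mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myopsych import ActivationVector, EMGConfig, generate_emg
from myopsych.emg import (
    apply_filters,
    design_filter_chain,
    extract_features,
    predict_activation,
    train_regressor,
    window_samples,
    window_stream,
)
from myopsych.emg import predict_activations

FS = 1000.0


class TestFilterDesign:
    @pytest.mark.parametrize("stage,freq", [
        ("lp", 450.0), ("hp", 20.0), ("notch", 57.0), ("notch", 63.0),
    ])
    def test_minus_3db_points(self, chain, stage, freq):
        mag = abs(chain.stage_response(stage, [freq])[0])
        assert mag == pytest.approx(10 ** (-3.0103 / 20.0), rel=0.01)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            design_filter_chain(880.0)

    def test_stages_stable_at_various_rates(self):
        from scipy.signal import sos2zpk

        for fs in (1000.0, 2000.0, 4096.0):
            ch = design_filter_chain(fs)
            for sos in (ch.sos_hp, ch.sos_notch, ch.sos_lp):
                _, poles, _ = sos2zpk(sos)
                assert np.all(np.abs(poles) < 1.0)


class TestFilterApplication:
    def test_dc_removed(self, chain):
        x = np.full(4000, 5.0)
        y = apply_filters(chain, x)
        assert abs(y[2000:].mean()) < 1e-3 * 5.0

    @pytest.mark.parametrize("freq", [60.0, 100.0, 300.0])
    def test_sinusoid_gain_matches_transfer_function(self, chain, freq):
        n = 10_000
        x = np.sin(2 * np.pi * freq * np.arange(n) / FS)
        y = apply_filters(chain, x)
        meas = np.sqrt(np.mean(y[n // 2:] ** 2)) / np.sqrt(0.5)
        theo = abs(chain.frequency_response([freq])[0])
        assert meas == pytest.approx(theo, rel=0.05, abs=1e-4)

    def test_nan_rejected(self, chain):
        x = np.zeros(1000)
        x[10] = np.nan
        with pytest.raises(ValueError):
            apply_filters(chain, x)

    @given(st.floats(min_value=-50.0, max_value=50.0).filter(lambda a: abs(a) > 1e-6))
    @settings(deadline=None, derandomize=True, max_examples=20)
    def test_linearity(self, a):
        chain = design_filter_chain(FS)
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        y1 = apply_filters(chain, a * x)
        y2 = a * apply_filters(chain, x)
        assert np.allclose(y1, y2, rtol=1e-9, atol=1e-12 * abs(a))


class TestFeatures:
    def test_all_zero_window(self):
        f = extract_features(np.zeros((8, 160)), fs=FS)
        assert np.all(f.mav == 0) and np.all(f.wl == 0)
        assert np.all(f.zc == 0) and np.all(f.ssc == 0)

    def test_linear_ramp_telescopes(self):
        ramp = np.linspace(0.0, 1.0, 160)[None, :]
        f = extract_features(ramp, fs=FS)
        assert f.wl[0] == pytest.approx(1.0)
        assert f.zc[0] == 0 and f.ssc[0] == 0

    def test_sine_zero_crossings(self):
        t = np.arange(160) / FS
        x = 10.0 * np.sin(2 * np.pi * 62.5 * t + 0.3)  # 10 cycles in 160 ms
        f = extract_features(x[None, :], fs=FS, zc_ssc_threshold=0.01)
        assert abs(int(f.zc[0]) - 20) <= 1

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            extract_features(np.zeros((8, 150)), fs=FS)

    @given(st.floats(min_value=1.0, max_value=100.0))
    @settings(deadline=None, derandomize=True, max_examples=20)
    def test_amplitude_scaling_scales_mav_and_wl(self, k):
        rng = np.random.default_rng(1)
        w = rng.standard_normal((4, 160))
        f1 = extract_features(w, fs=FS)
        f2 = extract_features(k * w, fs=FS)
        np.testing.assert_allclose(f2.mav, k * f1.mav, rtol=1e-12)
        np.testing.assert_allclose(f2.wl, k * f1.wl, rtol=1e-12)

    def test_counts_bounded_by_window(self):
        rng = np.random.default_rng(2)
        f = extract_features(rng.standard_normal((8, 160)), fs=FS)
        assert np.all(f.zc <= 160) and np.all(f.ssc <= 160)
        assert np.all(f.zc >= 0) and np.all(f.ssc >= 0)


class TestWindowing:
    @pytest.mark.parametrize("n,expected", [(1000, 14), (160, 1), (159, 0), (224, 2)])
    def test_frame_counts(self, n, expected):
        frames = window_stream(np.zeros((2, n)), fs=FS, increment_s=0.064)
        assert len(frames) == expected

    def test_streaming_increment(self):
        frames = window_stream(np.zeros((2, 1000)), fs=FS, increment_s=0.016)
        assert len(frames) == (1000 - 160) // 16 + 1


@pytest.fixture(scope="module")
def trained_model():
    """SVR trained on synthetic EMG driven by a sinusoidal 1-DOF profile."""
    cfg = EMGConfig()
    n = int(20.0 * FS)
    t = np.arange(n) / FS
    a1 = np.sin(2 * np.pi * 0.25 * t)
    a1[t < 2.0] = 0.0  # rest period included
    trace = np.stack([a1, np.zeros(n)], axis=1)
    chain = design_filter_chain(FS)
    sig = apply_filters(chain, generate_emg(cfg, trace, seed=0))
    frames = window_stream(sig, fs=FS)
    targets = [ActivationVector(a1[int(f.frame_time * FS) - 1], 0.0) for f in frames]
    model = train_regressor(frames, targets)
    return cfg, chain, model, frames, targets


class TestRegression:
    def test_prediction_tracks_ground_truth(self, trained_model):
        cfg, chain, model, _, _ = trained_model
        n = int(20.0 * FS)
        t = np.arange(n) / FS
        a1 = np.sin(2 * np.pi * 0.4 * t + 1.0)
        sig = apply_filters(chain, generate_emg(cfg, np.stack([a1, np.zeros(n)], 1), seed=9))
        frames = window_stream(sig, fs=FS)
        truth = np.array([a1[int(f.frame_time * FS) - 1] for f in frames])
        pred = predict_activations(model, frames)
        r = np.corrcoef(pred[:, 0], truth)[0, 1]
        assert r >= 0.9
        ss_res = np.sum((pred[:, 0] - truth) ** 2)
        ss_tot = np.sum((truth - truth.mean()) ** 2)
        assert 1.0 - ss_res / ss_tot >= 0.8

    def test_outputs_clipped(self, trained_model):
        _, _, model, frames, _ = trained_model
        pred = predict_activations(model, frames)
        assert np.all(pred >= -1.0) and np.all(pred <= 1.0)

    def test_rest_frame_predicts_near_zero(self, trained_model):
        _, _, model, _, _ = trained_model
        rest = extract_features(np.zeros((8, window_samples(FS))), fs=FS)
        a = predict_activation(model, rest)
        assert abs(a.dof1) <= 0.1 and abs(a.dof2) <= 0.1

    def test_duplicated_training_is_deterministic(self, trained_model):
        _, _, model, frames, targets = trained_model
        model2 = train_regressor(frames, targets)
        pred1 = predict_activations(model, frames[:10])
        pred2 = predict_activations(model2, frames[:10])
        np.testing.assert_array_equal(pred1, pred2)

    def test_channel_mismatch_rejected(self, trained_model):
        _, _, model, _, _ = trained_model
        frame = extract_features(np.zeros((4, 160)), fs=FS)
        with pytest.raises(ValueError):
            predict_activation(model, frame)

    def test_degenerate_inputs_rejected(self, trained_model):
        _, _, _, frames, _ = trained_model
        const = [ActivationVector(0.5, 0.0)] * len(frames)
        with pytest.raises(ValueError, match="degenerate"):
            train_regressor(frames, const)
        with pytest.raises(ValueError, match=">= 50"):
            train_regressor(frames[:10], [ActivationVector(0, 0)] * 10)

    def test_model_save_load_roundtrip(self, trained_model, tmp_path):
        from myopsych.emg import RegressionModel

        _, _, model, frames, _ = trained_model
        model.save(tmp_path / "m.joblib")
        back = RegressionModel.load(tmp_path / "m.joblib")
        np.testing.assert_array_equal(predict_activations(back, frames[:5]),
                                      predict_activations(model, frames[:5]))
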
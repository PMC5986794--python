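"""EMG signal chain: Butterworth filtering, Hudgins time-domain features,
sliding-window framing, and the SVR mapping from features to 2-DOF activation.

Processing order is high-pass (3rd-order, 20 Hz) → band-stop notch
(2nd-order, 57–63 Hz) → low-pass (5th-order, 450 Hz): offset and motion
artifact are removed before band shaping.  All stages are causal by
default so the chain honours the 16 ms streaming tick of real-time
control; zero-phase (forward–backward) filtering can be enabled for
offline analysis.

Features are the standard Hudgins time-domain set per channel: mean
absolute value (MAV), waveform length (WL), zero crossings (ZC) and slope
sign changes (SSC), extracted from 160 ms windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .core import ActivationVector

__all__ = [
    "FilterChain",
    "design_filter_chain",
    "apply_filters",
    "FeatureFrame",
    "extract_features",
    "window_stream",
    "RegressionModel",
    "train_regressor",
    "predict_activation",
]

LP_ORDER, LP_CUTOFF = 5, 450.0
HP_ORDER, HP_CUTOFF = 3, 20.0
NOTCH_ORDER, NOTCH_BAND = 2, (57.0, 63.0)

WINDOW_S = 0.160        # feature window length
TRAIN_INCREMENT_S = 0.064
STREAM_INCREMENT_S = 0.016


@dataclass(frozen=True)
class FilterChain:
    """The designed filter stages (second-order sections) at one sampling rate.

    Stages are applied in the fixed order HP → notch → LP.
    """

    fs: float
    sos_hp: np.ndarray
    sos_notch: np.ndarray
    sos_lp: np.ndarray

    def frequency_response(self, freqs) -> np.ndarray:
        """Complex response of the full chain at the given frequencies (Hz)."""
        freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
        h = np.ones_like(freqs, dtype=complex)
        for sos in (self.sos_hp, self.sos_notch, self.sos_lp):
            _, hi = sps.sosfreqz(sos, worN=2 * np.pi * freqs / self.fs)
            h *= hi
        return h

    def stage_response(self, stage: str, freqs) -> np.ndarray:
        sos = {"hp": self.sos_hp, "notch": self.sos_notch, "lp": self.sos_lp}[stage]
        freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
        _, h = sps.sosfreqz(sos, worN=2 * np.pi * freqs / self.fs)
        return h


def design_filter_chain(fs: float = 1000.0) -> FilterChain:
    """Design the three-stage Butterworth chain for sampling rate ``fs``.

    Stages: 3rd-order 20 Hz high-pass, 2nd-order 57–63 Hz band-stop,
    5th-order 450 Hz low-pass.  Butterworth design places the −3 dB point
    exactly at the requested cutoff.  ``fs`` must exceed 900 Hz so that
    the 450 Hz cutoff sits below Nyquist.
    """
    if fs <= 900.0:
        raise ValueError(f"fs={fs:g} Hz too low for the 450 Hz low-pass cutoff")
    sos_hp = sps.butter(HP_ORDER, HP_CUTOFF, btype="highpass", fs=fs, output="sos")
    sos_notch = sps.butter(NOTCH_ORDER, NOTCH_BAND, btype="bandstop", fs=fs, output="sos")
    sos_lp = sps.butter(LP_ORDER, LP_CUTOFF, btype="lowpass", fs=fs, output="sos")
    for name, sos in (("hp", sos_hp), ("notch", sos_notch), ("lp", sos_lp)):
        z, p, _ = sps.sos2zpk(sos)
        if np.any(np.abs(p) >= 1.0):
            raise RuntimeError(f"unstable {name} stage at fs={fs:g}")
    return FilterChain(fs=fs, sos_hp=sos_hp, sos_notch=sos_notch, sos_lp=sos_lp)


def apply_filters(chain: FilterChain, x, zero_phase: bool = False) -> np.ndarray:
    """Apply the chain to a (n_channels, n_samples) or 1-D signal.

    Causal by default; ``zero_phase=True`` uses forward-backward filtering
    (offline only).  NaN input is rejected.
    """
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("signal contains NaN or infinite samples")
    squeeze = x.ndim == 1
    y = np.atleast_2d(x)
    filt = sps.sosfiltfilt if zero_phase else sps.sosfilt
    for sos in (chain.sos_hp, chain.sos_notch, chain.sos_lp):
        y = filt(sos, y, axis=-1)
    return y[0] if squeeze else y


@dataclass(frozen=True)
class FeatureFrame:
    """Hudgins time-domain features of one analysis window, per channel."""

    mav: np.ndarray
    wl: np.ndarray
    zc: np.ndarray
    ssc: np.ndarray
    window_s: float = WINDOW_S
    frame_time: float = 0.0

    @property
    def n_channels(self) -> int:
        return len(self.mav)

    def to_vector(self) -> np.ndarray:
        """Stack the four feature blocks into one flat vector."""
        return np.concatenate([self.mav, self.wl,
                               self.zc.astype(float), self.ssc.astype(float)])


def window_samples(fs: float, window_s: float = WINDOW_S) -> int:
    return int(round(window_s * fs))


def extract_features(window, fs: float = 1000.0,
                     zc_ssc_threshold: float = 0.0,
                     frame_time: float = 0.0) -> FeatureFrame:
    """Extract MAV, WL, ZC and SSC from one 160 ms multichannel window.

    ZC counts sign changes whose amplitude step exceeds the deadband
    threshold; SSC counts slope-sign changes whose local deviation exceeds
    it.  The window must contain exactly ``round(0.160·fs)`` samples.
    """
    w = np.atleast_2d(np.asarray(window, dtype=float))
    n_expected = window_samples(fs)
    if w.shape[1] != n_expected:
        raise ValueError(
            f"window must have exactly {n_expected} samples "
            f"(160 ms at {fs:g} Hz), got {w.shape[1]}")
    thr = float(zc_ssc_threshold)

    mav = np.mean(np.abs(w), axis=1)
    d = np.diff(w, axis=1)
    wl = np.sum(np.abs(d), axis=1)

    sign_change = (w[:, :-1] * w[:, 1:]) < 0
    big_step = np.abs(d) >= thr
    zc = np.sum(sign_change & big_step, axis=1)

    # slope sign change at interior sample i: (x_i - x_{i-1})(x_i - x_{i+1}) > 0
    prev_d = w[:, 1:-1] - w[:, :-2]
    next_d = w[:, 1:-1] - w[:, 2:]
    turn = (prev_d * next_d) > 0
    big = (np.abs(prev_d) >= thr) | (np.abs(next_d) >= thr)
    ssc = np.sum(turn & big, axis=1)

    return FeatureFrame(mav=mav, wl=wl, zc=zc.astype(int), ssc=ssc.astype(int),
                        window_s=n_expected / fs, frame_time=frame_time)


def window_stream(x, fs: float = 1000.0, window_s: float = WINDOW_S,
                  increment_s: float = TRAIN_INCREMENT_S,
                  zc_ssc_threshold: float = 0.0) -> list[FeatureFrame]:
    """Slide a 160 ms window over the signal and extract features per hop.

    Yields ``floor((n_samples − window)/increment) + 1`` frames (an empty
    list if the signal is shorter than one window).  ``frame_time`` is the
    time of the window's trailing edge.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    nwin = window_samples(fs, window_s)
    step = int(round(increment_s * fs))
    if step < 1:
        raise ValueError("increment too small for the sampling rate")
    n = x.shape[1]
    frames: list[FeatureFrame] = []
    for start in range(0, n - nwin + 1, step):
        frames.append(extract_features(
            x[:, start:start + nwin], fs=fs,
            zc_ssc_threshold=zc_ssc_threshold,
            frame_time=(start + nwin) / fs))
    return frames


@dataclass
class RegressionModel:
    """Trained features → 2-DOF activation mapping (one SVR per DOF).

    Predictions are clipped to [−1, 1] per DOF.
    """

    pipelines: list  # one sklearn Pipeline per DOF
    n_channels: int
    window_s: float = WINDOW_S
    increment_s: float = TRAIN_INCREMENT_S
    hyperparams: dict = field(default_factory=dict)
    format_version: int = 1

    def save(self, path) -> None:
        import joblib

        joblib.dump({"format_version": self.format_version,
                     "n_channels": self.n_channels,
                     "window_s": self.window_s,
                     "increment_s": self.increment_s,
                     "hyperparams": self.hyperparams,
                     "pipelines": self.pipelines}, path)

    @classmethod
    def load(cls, path) -> "RegressionModel":
        import joblib

        d = joblib.load(path)
        if d.get("format_version") != 1:
            raise ValueError(f"unsupported model format {d.get('format_version')!r}")
        return cls(pipelines=d["pipelines"], n_channels=d["n_channels"],
                   window_s=d["window_s"], increment_s=d["increment_s"],
                   hyperparams=d["hyperparams"])


DEFAULT_SVR_PARAMS = {"kernel": "rbf", "C": 10.0, "epsilon": 0.01, "gamma": "scale"}


def train_regressor(frames: Sequence[FeatureFrame],
                    targets: Sequence[ActivationVector],
                    svr_params: dict | None = None) -> RegressionModel:
    """Fit the SVR mapping from feature frames to prompted 2-DOF activations.

    Requires at least 50 (frame, target) pairs; degenerate (constant)
    targets are rejected.  With fixed hyperparameters the fit is
    deterministic in the training data.
    """
    if len(frames) != len(targets):
        raise ValueError("frames and targets must have equal length")
    if len(frames) < 50:
        raise ValueError(f"need >= 50 training pairs, got {len(frames)}")
    X = np.stack([f.to_vector() for f in frames])
    Y = np.stack([np.asarray(tuple(t), dtype=float) for t in targets])
    if np.allclose(Y.std(axis=0), 0.0):
        raise ValueError("degenerate training targets (constant)")
    params = dict(DEFAULT_SVR_PARAMS)
    if svr_params:
        params.update(svr_params)
    pipes = []
    for d in range(2):
        pipe = Pipeline([("scale", StandardScaler()), ("svr", SVR(**params))])
        pipe.fit(X, Y[:, d])
        pipes.append(pipe)
    return RegressionModel(pipelines=pipes, n_channels=frames[0].n_channels,
                           window_s=frames[0].window_s, hyperparams=params)


def predict_activation(model: RegressionModel, frame: FeatureFrame) -> ActivationVector:
    """Map one feature frame through the trained SVR to a clipped activation."""
    if frame.n_channels != model.n_channels:
        raise ValueError(
            f"frame has {frame.n_channels} channels, model expects {model.n_channels}")
    x = frame.to_vector()[None, :]
    out = [float(np.clip(p.predict(x)[0], -1.0, 1.0)) for p in model.pipelines]
    return ActivationVector(out[0], out[1])


def predict_activations(model: RegressionModel,
                        frames: Sequence[FeatureFrame]) -> np.ndarray:
    """Vectorised prediction over many frames; returns (n_frames, 2) clipped."""
    if not frames:
        return np.zeros((0, 2))
    if frames[0].n_channels != model.n_channels:
        raise ValueError("channel count mismatch")
    X = np.stack([f.to_vector() for f in frames])
    out = np.stack([p.predict(X) for p in model.pipelines], axis=1)
    return np.clip(out, -1.0, 1.0)
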
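"""Virtual subjects: the synthetic-data generators for the whole pipeline.

A :class:`SubjectModel` bundles the generative parameters of one simulated
participant — internal-model uncertainty, sensory and controller noise,
trial-to-trial adaptation gain and the slope of the two-interval
forced-choice (2IFC) psychometric observer.  Every downstream estimator in
:mod:`myopsych.psychophysics` has a generator here whose ground truth it
should recover, which is what makes the estimators testable without human
data.

Three generators live here:

* :func:`generate_emg` — 8-channel, 1 kHz surface-EMG-like signals:
  zero-mean Gaussian noise amplitude-modulated by synergy-weighted,
  rectified 2-DOF activations.
* :func:`simulate_adaptation_series` — trial-by-trial feedforward commands
  under an error-corrective update with known gain.
* :func:`observe_2ifc` — a cumulative-Gaussian ideal observer for the
  two-interval forced-choice detection task.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import erf

from .core import DEG_PER_ACT

__all__ = [
    "SubjectModel",
    "EMGConfig",
    "generate_emg",
    "simulate_adaptation_series",
    "observe_2ifc",
    "p_correct_2ifc",
]


@dataclass
class SubjectModel:
    """Generative parameters of a virtual subject.

    Parameters
    ----------
    p_param : float
        Internal-model parameter uncertainty (variance, task units²,
        i.e. degrees² of the movement-direction stimulus space before
        normalisation).
    sigma_sens : float
        SD of the sensory noise corrupting the subject's perception of
        their own trial error, in degrees.
    sigma_cntl : float
        SD of the per-tick controller noise on each DOF, activation units.
    motor_noise : float
        SD of feedforward command execution noise between trials,
        activation units.
    psychometric_slope : float
        SD of the internal noise of the cumulative-Gaussian 2IFC observer,
        in degrees.  Governs the JND.
    adaptation_gain : float
        Ground-truth trial-to-trial error-correction gain, in [0, 1.5].
    rng_seed : int
        Base seed; identical seeds give bit-identical generated sequences.
    lapse_rate : float
        Probability of a random guess in the 2IFC task regardless of the
        stimulus (default 0 — ideal observer without lapses).
    """

    p_param: float = 0.05
    sigma_sens: float = 3.0
    sigma_cntl: float = 0.1
    motor_noise: float = 0.02
    psychometric_slope: float = 30.0
    adaptation_gain: float = 0.6
    rng_seed: int = 0
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_param", "sigma_sens", "sigma_cntl", "motor_noise",
                     "psychometric_slope", "lapse_rate"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite non-negative number, got {v!r}")
        if not math.isfinite(self.adaptation_gain):
            raise ValueError("adaptation_gain must be finite")
        if not 0.0 <= self.adaptation_gain <= 1.5:
            raise ValueError("adaptation_gain must be in [0, 1.5]")
        if self.lapse_rate > 1.0:
            raise ValueError("lapse_rate must be <= 1")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectModel":
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SubjectModel":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "SubjectModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    # -- internal-model self-consistency -------------------------------

    @classmethod
    def from_internal_model(
        cls,
        p_param: float,
        feedback_noise_var: float,
        *,
        sigma_sens: float = 3.0,
        sigma_cntl: float = 0.1,
        motor_noise: float = 0.02,
        stimulus_scale: float = 180.0,
        rng_seed: int = 0,
    ) -> "SubjectModel":
        """Build a subject whose adaptation gain is the steady-state Kalman
        gain implied by its internal-model uncertainty.

        The internal model carries parameter uncertainty P (here
        ``p_param * stimulus_scale**2``, degrees²).  Feedback about each
        trial arrives through a channel with variance
        ``R + sigma_sens² + (sigma_cntl·DEG_PER_ACT)²`` where ``R`` is the
        perceptual observer variance (``feedback_noise_var``, degrees²).
        The trial-to-trial correction gain is then

            K = P / (P + R + sigma_sens² + sigma_cntl_deg²)

        which :func:`myopsych.psychophysics.compute_internal_model_uncertainty`
        inverts exactly, making the round trip testable.
        """
        if feedback_noise_var < 0:
            raise ValueError("feedback_noise_var must be >= 0")
        P = p_param * stimulus_scale**2
        total = (feedback_noise_var + sigma_sens**2
                 + (sigma_cntl * DEG_PER_ACT) ** 2)
        gain = P / (P + total) if (P + total) > 0 else 0.0
        return cls(
            p_param=p_param,
            sigma_sens=sigma_sens,
            sigma_cntl=sigma_cntl,
            motor_noise=motor_noise,
            psychometric_slope=math.sqrt(feedback_noise_var),
            adaptation_gain=gain,
            rng_seed=rng_seed,
        )


def _default_synergy(n_channels: int) -> np.ndarray:
    """Synergy weights: each direction drives two primary channels (weight 1)
    with 0.1 cross-talk elsewhere.  Rows (directions) are pairwise distinct."""
    w = np.full((4, n_channels), 0.1)
    for d in range(4):
        for k in range(2):
            w[d, (2 * d + k) % n_channels] = 1.0
    return w


@dataclass
class EMGConfig:
    """Configuration of the surface-EMG generator.

    ``synergy_matrix`` has one row per signed direction — extension,
    flexion, abduction, adduction — and one non-negative column weight per
    channel; it defines how strongly each muscle site is recruited by each
    direction.  ``baseline_noise`` is the SD of the resting signal.
    """

    n_channels: int = 8
    fs: float = 1000.0
    synergy_matrix: np.ndarray = field(default=None)  # type: ignore[assignment]
    baseline_noise: float = 0.05

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.fs <= 900.0:
            # must clear twice the 450 Hz low-pass cutoff of the filter chain
            raise ValueError("fs must exceed 900 Hz")
        if self.baseline_noise < 0:
            raise ValueError("baseline_noise must be >= 0")
        if self.synergy_matrix is None:
            self.synergy_matrix = _default_synergy(self.n_channels)
        self.synergy_matrix = np.asarray(self.synergy_matrix, dtype=float)
        if self.synergy_matrix.shape != (4, self.n_channels):
            raise ValueError(
                f"synergy_matrix must be (4, {self.n_channels}), "
                f"got {self.synergy_matrix.shape}")
        if np.any(self.synergy_matrix < 0):
            raise ValueError("synergy weights must be non-negative")
        for i in range(4):
            for j in range(i + 1, 4):
                if np.allclose(self.synergy_matrix[i], self.synergy_matrix[j]):
                    raise ValueError(
                        f"synergy rows {i} and {j} are identical; the four "
                        "directions must be distinguishable")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synergy_matrix"] = self.synergy_matrix.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EMGConfig":
        d = dict(d)
        if d.get("synergy_matrix") is not None:
            d["synergy_matrix"] = np.asarray(d["synergy_matrix"], dtype=float)
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "EMGConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _directional_drive(trace: np.ndarray) -> np.ndarray:
    """Split signed 2-DOF activations into 4 rectified direction drives.

    Returns an array of shape (4, n_samples) ordered extension, flexion,
    abduction, adduction.
    """
    a1, a2 = trace[:, 0], trace[:, 1]
    return np.stack([
        np.maximum(a1, 0.0),
        np.maximum(-a1, 0.0),
        np.maximum(a2, 0.0),
        np.maximum(-a2, 0.0),
    ])


def generate_emg(config: EMGConfig, activation_trace, seed: int) -> np.ndarray:
    """Generate multichannel EMG-like signal from a 2-DOF activation trace.

    Each channel is zero-mean white Gaussian noise whose instantaneous SD
    (the amplitude envelope) is ``baseline_noise`` plus the synergy-weighted
    rectified activation of the four signed directions.  This is not a
    motor-unit simulation; it preserves exactly the activation-to-amplitude
    monotonicity that the downstream time-domain features rely on.

    Parameters
    ----------
    config : EMGConfig
    activation_trace : array-like, shape (n_samples, 2)
        Signed activations per DOF, sampled at ``config.fs``, in [−1, 1].
    seed : int
        Deterministic noise seed.

    Returns
    -------
    ndarray, shape (n_channels, n_samples)
    """
    trace = np.asarray(activation_trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 2:
        raise ValueError(
            f"activation_trace must have shape (n_samples, 2) sampled at "
            f"fs={config.fs:g} Hz; got shape {trace.shape}")
    if trace.shape[0] == 0:
        raise ValueError("activation_trace is empty")
    if np.any(~np.isfinite(trace)) or np.any(np.abs(trace) > 1.0 + 1e-12):
        raise ValueError("activations must be finite and within [-1, 1] per DOF")

    drive = _directional_drive(trace)                                  # (4, n)
    envelope = config.baseline_noise + config.synergy_matrix.T @ drive  # (n_ch, n)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(envelope.shape)
    return envelope * noise


def simulate_adaptation_series(
    subject: SubjectModel,
    n_trials: int,
    target_dof: str = "dof1",
    initial_error: float = 0.3,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate trial-by-trial feedforward adaptation to self-generated error.

    The task drives one DOF toward the target (wrist extension for the
    canonical rightward target); any feedforward activation on the other
    DOF is a self-generated error the subject is instructed to minimise.
    The off-target feedforward command ``u`` evolves as

        e_n     = u_n + ε_sens            (perceived error)
        u_{n+1} = u_n − gain · e_n + ε_motor

    with ε_sens ~ N(0, (sigma_sens/DEG_PER_ACT)²) in activation units and
    ε_motor ~ N(0, motor_noise²).

    Parameters
    ----------
    subject : SubjectModel
    n_trials : int
        Number of trials, >= 2.
    target_dof : {"dof1", "dof2"}
        The on-target DOF; the error lives on the other one.  Kept for
        bookkeeping; the returned series is the scalar off-target command.
    initial_error : float
        Off-target feedforward command at trial 0, activation units.
    seed : int, optional
        Overrides ``subject.rng_seed``.

    Returns
    -------
    commands, observed_errors : ndarray, shape (n_trials,)
        Feedforward command and the error the subject perceived on each
        trial.  The ground-truth gain is recoverable by regressing the
        command change on minus the previous perceived error.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    if target_dof not in ("dof1", "dof2"):
        raise ValueError("target_dof must be 'dof1' or 'dof2'")
    rng = np.random.default_rng(subject.rng_seed if seed is None else seed)
    sens_sd = subject.sigma_sens / DEG_PER_ACT
    eps_sens = rng.normal(0.0, sens_sd, size=n_trials) if sens_sd > 0 else np.zeros(n_trials)
    eps_motor = (rng.normal(0.0, subject.motor_noise, size=n_trials)
                 if subject.motor_noise > 0 else np.zeros(n_trials))

    u = np.empty(n_trials)
    e = np.empty(n_trials)
    u[0] = initial_error
    for n in range(n_trials):
        e[n] = u[n] + eps_sens[n]
        if n + 1 < n_trials:
            u[n + 1] = u[n] - subject.adaptation_gain * e[n] + eps_motor[n]
    return u, e


def p_correct_2ifc(stimulus: float, slope: float, lapse_rate: float = 0.0) -> float:
    """Probability of a correct 2IFC response under the Gaussian observer.

    P(correct) = 0.5 + 0.5·erf(stimulus / (2·slope)), i.e. the normal CDF
    Φ(stimulus / (slope·√2)) — the √2 reflecting that the decision compares
    two noisy intervals.  Chance (0.5) at zero stimulus; saturates at 1.
    A lapse rate λ mixes in guessing: P → (1−λ)·P + λ/2.
    """
    if stimulus < 0:
        raise ValueError("stimulus magnitude must be >= 0")
    if slope <= 0:
        p = 1.0 if stimulus > 0 else 0.5
    else:
        p = 0.5 + 0.5 * float(erf(stimulus / (2.0 * slope)))
    return (1.0 - lapse_rate) * p + 0.5 * lapse_rate


def observe_2ifc(subject: SubjectModel, stimulus_magnitude: float, seed: int) -> bool:
    """One 2IFC judgement: did the observer pick the stimulus interval?

    Draws a Bernoulli response with success probability
    :func:`p_correct_2ifc` evaluated at the subject's psychometric slope.
    Returns True for a correct identification.
    """
    p = p_correct_2ifc(stimulus_magnitude, subject.psychometric_slope,
                       subject.lapse_rate)
    rng = np.random.default_rng(seed)
    return bool(rng.random() < p)


def write_signal_csv(path, signal: np.ndarray) -> None:
    """Write a multichannel signal as CSV: sample index + one column per channel."""
    import pandas as pd

    sig = np.asarray(signal)
    df = pd.DataFrame(sig.T, columns=[f"ch{i+1}" for i in range(sig.shape[0])])
    df.index.name = "sample"
    df.to_csv(path)


def read_signal_csv(path) -> np.ndarray:
    import pandas as pd

    df = pd.read_csv(path, index_col="sample")
    return df.to_numpy().T
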
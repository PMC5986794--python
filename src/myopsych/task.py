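"""Virtual target-acquisition task: targets, closed-loop trials, blocks.

The virtual subject pursues screen targets with a cursor driven by its
2-DOF activation through one of the control strategies.  The intent model
is proportional pursuit: the desired per-DOF activation points at the
target and saturates at a submaximal effort cap, with additive controller
noise each 16 ms tick.  Visual feedback acts only after a visuomotor
delay; before it, the command is pure feedforward, which is what the
adaptation analysis windows on.

Protocol blocks mirror the study design: a training block of 3 sets of
16 targets (12 s limit each), an adaptation block of 80 repetitions of a
single target on the +x axis, and a performance test of 2 sets of 16
targets with 1.7 s and then 1.4 s limits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import ActivationVector, DEG_PER_ACT, clip_unit
from .strategies import AudioFrame, StrategyConfig, audio_map, gate_highest_dof
from .subject import SubjectModel

__all__ = [
    "Target",
    "TargetLayout",
    "TrialLog",
    "BlockSpec",
    "generate_target_set",
    "run_trial",
    "run_block",
    "run_steady_hold",
]

TICK_S = 0.016
#: visuomotor latency before visual feedback can influence the command (s);
#: the 100-230 ms analysis window therefore captures pure feedforward intent
VISUAL_DELAY_S = 0.230
#: submaximal effort cap on intended activation per DOF
INTENT_CAP = 0.8
#: proportional-pursuit time constant (s): intent = distance/(gain*tau), capped
PURSUIT_TAU = 0.2


@dataclass(frozen=True)
class Target:
    """A screen target: centre (pixels from screen centre), class, limits."""

    center: tuple[float, float]
    acquisition_radius: float = 3.0
    time_limit: float = 12.0

    def __post_init__(self) -> None:
        if self.acquisition_radius <= 0:
            raise ValueError("acquisition_radius must be positive")
        if self.time_limit < 0:
            raise ValueError("time_limit must be >= 0")

    @property
    def axis_class(self) -> str:
        """'on_axis' iff exactly one coordinate of the centre is 0."""
        x, y = self.center
        return "on_axis" if (x == 0.0) != (y == 0.0) else "off_axis"


@dataclass(frozen=True)
class TargetLayout:
    """Canonical two-ring, 16-target layout.

    8 on-axis targets (±x, ±y at two distances) and 8 off-axis targets
    (the four quadrant diagonals at two distances, placed so each ring
    shares its Euclidean radius).  Distances are sized so that, at the
    default 20 px/s gains, on-axis targets are acquirable within the
    performance-block time limits.
    """

    near: float = 15.0
    far: float = 25.0
    acquisition_radius: float = 3.0

    def positions(self) -> list[tuple[float, float]]:
        pts: list[tuple[float, float]] = []
        for d in (self.near, self.far):
            pts += [(d, 0.0), (-d, 0.0), (0.0, d), (0.0, -d)]
        for d in (self.near, self.far):
            c = d / math.sqrt(2.0)
            pts += [(c, c), (-c, c), (-c, -c), (c, -c)]
        return pts

    def adaptation_target(self, time_limit: float = 12.0) -> Target:
        """The single +x-axis target used for the adaptation block."""
        return Target(center=(self.far, 0.0),
                      acquisition_radius=self.acquisition_radius,
                      time_limit=time_limit)


@dataclass
class TrialLog:
    """Record of one trial: per-tick samples plus outcome metadata.

    ``samples`` columns: t (s), x, y (pixels), raw dof1/dof2, gated
    dof1/dof2 activations.  ``audio`` holds one AudioFrame per sample
    (empty frames for RAW/FLT).  The trajectory starts at the origin and
    timestamps advance strictly by one 16 ms tick.
    """

    target: Target
    t: np.ndarray
    pos: np.ndarray          # (n, 2)
    raw: np.ndarray          # (n, 2)
    gated: np.ndarray        # (n, 2)
    audio: list[AudioFrame]
    movement_onset_time: float
    outcome: str             # 'acquired' | 'timeout'
    strategy: str = "RAW"

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1]) if self.n_samples else 0.0

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame({
            "t": self.t,
            "x": self.pos[:, 0], "y": self.pos[:, 1],
            "raw_dof1": self.raw[:, 0], "raw_dof2": self.raw[:, 1],
            "gated_dof1": self.gated[:, 0], "gated_dof2": self.gated[:, 1],
            "audio": [json.dumps(list(a.tones)) for a in self.audio],
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, target: Target, strategy: str = "RAW",
                 outcome: str = "acquired") -> "TrialLog":
        import pandas as pd

        df = pd.read_csv(path)
        audio = [AudioFrame(tuple(tuple(t) for t in json.loads(s)))
                 for s in df["audio"]]
        pos = df[["x", "y"]].to_numpy()
        raw = df[["raw_dof1", "raw_dof2"]].to_numpy()
        gated = df[["gated_dof1", "gated_dof2"]].to_numpy()
        speed = np.abs(gated).sum(axis=1)
        onset_idx = np.argmax(speed > 0) if np.any(speed > 0) else 0
        return cls(target=target, t=df["t"].to_numpy(), pos=pos, raw=raw,
                   gated=gated, audio=audio,
                   movement_onset_time=float(df["t"].iloc[onset_idx]),
                   outcome=outcome, strategy=strategy)


@dataclass(frozen=True)
class BlockSpec:
    """Specification of one protocol block.

    Canonical blocks: training = 3 sets × 16 targets at 12 s; adaptation =
    80 trials of one on-axis target; performance = 2 sets × 16 targets at
    1.7 s then 1.4 s; jnd = the staircase block (no cursor trials here).
    """

    kind: str
    n_sets: int = 1
    targets_per_set: int = 16
    time_limits: tuple[float, ...] = (12.0,)
    n_trials: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("training", "adaptation", "jnd", "performance"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.kind == "training":
            if (self.n_sets, self.targets_per_set) != (3, 16) or self.time_limits != (12.0,) * 3:
                raise ValueError("training block must be 3 sets x 16 targets at 12 s")
        elif self.kind == "adaptation":
            if self.n_trials != 80:
                raise ValueError("adaptation block must have 80 trials")
        elif self.kind == "performance":
            if (self.n_sets, self.targets_per_set) != (2, 16) or self.time_limits != (1.7, 1.4):
                raise ValueError("performance block must be 2 sets x 16 targets at 1.7/1.4 s")

    @classmethod
    def training(cls) -> "BlockSpec":
        return cls(kind="training", n_sets=3, targets_per_set=16,
                   time_limits=(12.0, 12.0, 12.0))

    @classmethod
    def adaptation(cls, n_trials: int = 80) -> "BlockSpec":
        return cls(kind="adaptation", n_sets=1, targets_per_set=1,
                   time_limits=(12.0,), n_trials=n_trials)

    @classmethod
    def performance(cls) -> "BlockSpec":
        return cls(kind="performance", n_sets=2, targets_per_set=16,
                   time_limits=(1.7, 1.4))

    @classmethod
    def jnd(cls) -> "BlockSpec":
        return cls(kind="jnd", n_sets=0, targets_per_set=0, time_limits=())


def generate_target_set(spec: BlockSpec, seed: int,
                        layout: TargetLayout | None = None) -> list[Target]:
    """Instantiate the ordered target list for one block.

    Training/performance sets contain the 16 canonical positions (8
    on-axis + 8 off-axis) in seed-shuffled order, repeated per set with
    that set's time limit.  The adaptation spec yields ``n_trials`` copies
    of the single +x-axis target.
    """
    layout = layout or TargetLayout()
    rng = np.random.default_rng(seed)
    if spec.kind == "adaptation":
        tgt = layout.adaptation_target(time_limit=spec.time_limits[0])
        return [tgt] * spec.n_trials
    if spec.kind == "jnd":
        return []
    targets: list[Target] = []
    positions = layout.positions()
    for s in range(spec.n_sets):
        order = rng.permutation(len(positions))
        limit = spec.time_limits[s]
        for i in order:
            targets.append(Target(center=positions[i],
                                  acquisition_radius=layout.acquisition_radius,
                                  time_limit=limit))
    return targets


def _intent(pos: tuple[float, float], target: Target,
            cfg: StrategyConfig) -> tuple[float, float]:
    """Proportional pursuit: per-DOF activation toward the target, capped."""
    ax = (target.center[0] - pos[0]) / (cfg.gains[0] * PURSUIT_TAU)
    ay = (target.center[1] - pos[1]) / (cfg.gains[1] * PURSUIT_TAU)
    cap = INTENT_CAP
    return (max(-cap, min(cap, ax)), max(-cap, min(cap, ay)))


def run_trial(subject: SubjectModel, strategy: StrategyConfig, target: Target,
              seed: int, model=None, ff_bias: float = 0.0,
              rotation_deg: float = 0.0) -> TrialLog:
    """Simulate one closed-loop trial at 16 ms ticks.

    Per tick the subject's intent (feedforward before the visuomotor
    delay, proportional pursuit after) plus controller noise gives the raw
    activation; the strategy maps it — gated for FLT/AUG — to cursor
    velocity.  The trial ends when the cursor enters the acquisition
    radius or the time limit expires.

    ``model`` optionally inserts the EMG decoding stage
    (:class:`myopsych.emg.RegressionModel`); by default the intent is
    decoded perfectly and decoding error is folded into controller noise.
    ``ff_bias`` adds a constant off-target (DOF 2) feedforward command —
    the self-generated error source of the adaptation block.
    ``rotation_deg`` rotates the activation-to-velocity mapping, the
    physical form of the JND stimulus.
    """
    dt = strategy.tick
    n_max = int(math.floor(target.time_limit / dt + 1e-9))
    rng = np.random.default_rng(seed)
    noise = (rng.normal(0.0, subject.sigma_cntl, size=(n_max, 2))
             if subject.sigma_cntl > 0 else np.zeros((n_max, 2)))

    rot = math.radians(rotation_deg)
    cr, sr = math.cos(rot), math.sin(rot)

    ts, ps, raws, gateds, audios = [], [], [], [], []
    pos = (0.0, 0.0)
    outcome = "timeout"
    onset = None
    dist0 = math.hypot(target.center[0], target.center[1])
    if dist0 <= target.acquisition_radius:
        raise ValueError("target centre must lie outside the acquisition radius")

    decoder = None
    if model is not None:
        from . import emg as _emg

        decoder = _emg  # decoding path resolved lazily to avoid import cost

    k = 0
    for k in range(n_max):
        t = k * dt
        if t < VISUAL_DELAY_S:
            # pure feedforward: full drive along the target direction
            ux = INTENT_CAP * (1.0 if target.center[0] > 0 else (-1.0 if target.center[0] < 0 else 0.0))
            uy = INTENT_CAP * (1.0 if target.center[1] > 0 else (-1.0 if target.center[1] < 0 else 0.0))
        else:
            ux, uy = _intent(pos, target, strategy)
        uy += ff_bias
        a1 = clip_unit(ux + noise[k, 0])
        a2 = clip_unit(uy + noise[k, 1])
        if decoder is not None and model is not None:
            a1, a2 = _decode_through_emg(decoder, model, subject, a1, a2, rng)
        raw = ActivationVector(a1, a2)
        eff = gate_highest_dof(raw) if strategy.gated else raw
        audio = audio_map(raw) if strategy.audio else AudioFrame()

        ts.append(t)
        ps.append(pos)
        raws.append((raw.dof1, raw.dof2))
        gateds.append((eff.dof1, eff.dof2))
        audios.append(audio)
        if onset is None and (eff.dof1 != 0.0 or eff.dof2 != 0.0):
            onset = t

        vx = strategy.gains[0] * eff.dof1
        vy = strategy.gains[1] * eff.dof2
        if rot != 0.0:  # JND stimulus: rotate the velocity mapping
            vx, vy = cr * vx - sr * vy, sr * vx + cr * vy
        pos = (pos[0] + vx * dt, pos[1] + vy * dt)
        if math.hypot(pos[0] - target.center[0], pos[1] - target.center[1]) <= target.acquisition_radius:
            outcome = "acquired"
            k += 1
            break
    else:
        k = n_max

    # terminal sample: final position, zero command
    ts.append(k * dt if n_max else 0.0)
    ps.append(pos)
    raws.append((0.0, 0.0))
    gateds.append((0.0, 0.0))
    audios.append(AudioFrame())

    return TrialLog(target=target,
                    t=np.asarray(ts), pos=np.asarray(ps),
                    raw=np.asarray(raws), gated=np.asarray(gateds),
                    audio=audios,
                    movement_onset_time=onset if onset is not None else float(ts[-1]),
                    outcome=outcome, strategy=strategy.name)


def _decode_through_emg(emg_mod, model, subject: SubjectModel,
                        a1: float, a2: float, rng) -> tuple[float, float]:
    """Pass one tick's intended activation through synthetic EMG + SVR."""
    from .subject import EMGConfig, generate_emg

    cfg = EMGConfig()
    n = emg_mod.window_samples(cfg.fs)
    trace = np.tile([a1, a2], (n, 1))
    sig = generate_emg(cfg, trace, seed=int(rng.integers(2**31)))
    frame = emg_mod.extract_features(sig, fs=cfg.fs)
    out = emg_mod.predict_activation(model, frame)
    return out.dof1, out.dof2


def run_block(subject: SubjectModel, strategy: StrategyConfig, spec: BlockSpec,
              seed: int, layout: TargetLayout | None = None, model=None,
              initial_ff_bias: float = 0.3) -> list[TrialLog]:
    """Run all trials of one block; per-trial seeds derive from the block seed.

    For the adaptation block the subject's off-target feedforward bias is
    carried across trials and updated after each one from the perceived
    error (own off-target feedforward command plus sensory noise) scaled
    by the adaptation gain, with motor execution noise — the closed-loop
    counterpart of :func:`myopsych.subject.simulate_adaptation_series`.
    """
    targets = generate_target_set(spec, seed, layout=layout)
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(1,))
    trial_seeds = ss.generate_state(max(len(targets), 1) * 2)
    logs: list[TrialLog] = []

    if spec.kind == "adaptation":
        rng_adapt = np.random.default_rng(trial_seeds[-1])
        bias = initial_ff_bias
        sens_sd = subject.sigma_sens / DEG_PER_ACT
        for i, tgt in enumerate(targets):
            log = run_trial(subject, strategy, tgt, int(trial_seeds[i]),
                            model=model, ff_bias=bias)
            logs.append(log)
            perceived = bias + (rng_adapt.normal(0.0, sens_sd) if sens_sd > 0 else 0.0)
            bias = (bias - subject.adaptation_gain * perceived
                    + (rng_adapt.normal(0.0, subject.motor_noise)
                       if subject.motor_noise > 0 else 0.0))
        return logs

    for i, tgt in enumerate(targets):
        logs.append(run_trial(subject, strategy, tgt, int(trial_seeds[i]), model=model))
    return logs


def run_steady_hold(subject: SubjectModel, strategy: StrategyConfig,
                    duration: float, seed: int,
                    intent: tuple[float, float] = (INTENT_CAP, 0.0)) -> np.ndarray:
    """Hold a constant intent for ``duration`` seconds; return raw activations.

    Used to estimate controller noise: the SD of the raw activation around
    its mean during a steady segment is an estimate of ``sigma_cntl``.
    Returns an (n_ticks, 2) array of clipped raw activations.
    """
    if duration < 1.0:
        raise ValueError("steady-hold segments must last at least 1 s")
    n = int(round(duration / strategy.tick))
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, subject.sigma_cntl, size=(n, 2)) if subject.sigma_cntl > 0 else np.zeros((n, 2))
    a = np.clip(np.asarray(intent)[None, :] + noise, -1.0, 1.0)
    return a
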
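"""Psychophysical estimators: adaptation rate, JND staircase, and
internal-model uncertainty.

Three instruments assess the internal model a (virtual) subject has built
of its controller:

* **Adaptation rate** — the regression slope of trial-to-trial
  feedforward command change against the previous trial's self-generated
  error; 1 means perfect compensation, 0 no adaptation.
* **JND** — the just-noticeable difference of an angular perturbation of
  the cursor mapping, measured with a Kaernbach weighted up-down
  staircase (two-interval forced choice) that converges at 84% correct
  and terminates after 23 reversals.
* **Internal-model uncertainty** ``p_param`` — the steady-state Kalman
  parameter variance consistent with the measured adaptation gain and
  feedback noise; low values mean a confident internal model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import DEG_PER_ACT, Z_084
from .subject import SubjectModel, observe_2ifc, p_correct_2ifc
from .task import TrialLog

__all__ = [
    "StaircaseState",
    "OutcomeMeasures",
    "feedforward_segment",
    "estimate_adaptation_rate",
    "staircase_update",
    "staircase_threshold",
    "run_jnd_experiment",
    "estimate_controller_noise",
    "InternalModelEstimate",
    "compute_internal_model_uncertainty",
]

TARGET_ACCURACY = 0.84
MAX_REVERSALS = 23
FF_WINDOW = (0.100, 0.230)  # s; both endpoints included
#: stimulus-space scale (degrees) used to normalise P into p_param;
#: rotations of the velocity mapping are distinguishable up to a half turn
STIMULUS_SCALE_DEG = 180.0


@dataclass
class StaircaseState:
    """State of the weighted up-down adaptive staircase.

    Step sizes obey the Kaernbach equilibrium
    ``step_up / step_down = target_accuracy / (1 − target_accuracy)``
    (5.25 at 84%), so the tracked level converges where P(correct) equals
    the target accuracy.  Terminates after ``max_reversals`` reversals.
    """

    current_level: float = 80.0       # degrees
    step_down: float = 1.0            # degrees
    step_up: float = field(default=None)  # type: ignore[assignment]
    target_accuracy: float = TARGET_ACCURACY
    max_reversals: int = MAX_REVERSALS
    reversal_levels: list[float] = field(default_factory=list)
    last_direction: str = "none"      # 'up' | 'down' | 'none'
    trial_count: int = 0
    levels: list[float] = field(default_factory=list)
    responses: list[bool] = field(default_factory=list)
    reversal_flags: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.5 < self.target_accuracy < 1.0:
            raise ValueError("target_accuracy must be in (0.5, 1)")
        if self.step_down <= 0:
            raise ValueError("step_down must be positive")
        ratio = self.target_accuracy / (1.0 - self.target_accuracy)
        if self.step_up is None:
            self.step_up = self.step_down * ratio
        elif not math.isclose(self.step_up / self.step_down, ratio, rel_tol=1e-9):
            raise ValueError(
                "step_up/step_down must equal target_accuracy/(1-target_accuracy)")
        if self.current_level < 0:
            raise ValueError("current_level must be >= 0")

    @property
    def n_reversals(self) -> int:
        return len(self.reversal_levels)

    @property
    def terminated(self) -> bool:
        return self.n_reversals >= self.max_reversals


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Record one response and move the level (in place; returns the state).

    Correct → level decreases by ``step_down``; incorrect → increases by
    ``step_up``.  A reversal is logged (at the presented level) whenever
    the movement direction flips.  The level is floored at 0.  Updating a
    terminated staircase is an error.
    """
    if state.terminated:
        raise RuntimeError("staircase already terminated at "
                           f"{state.max_reversals} reversals")
    level = state.current_level
    direction = "down" if correct else "up"
    is_reversal = state.last_direction != "none" and direction != state.last_direction
    state.levels.append(level)
    state.responses.append(bool(correct))
    state.reversal_flags.append(is_reversal)
    if is_reversal:
        state.reversal_levels.append(level)
    state.last_direction = direction
    state.trial_count += 1
    state.current_level = max(0.0, level - state.step_down) if correct else level + state.step_up
    return state


def staircase_threshold(state: StaircaseState, average_last: int = 0) -> float:
    """The JND: the stimulus level at the final (23rd) reversal.

    ``average_last=k`` (k > 0) instead averages the last k reversal
    levels.  Calling before termination is an error.
    """
    if not state.terminated:
        raise RuntimeError(
            f"staircase has {state.n_reversals} reversals, "
            f"needs {state.max_reversals}")
    if average_last > 0:
        return float(np.mean(state.reversal_levels[-average_last:]))
    return float(state.reversal_levels[state.max_reversals - 1])


@dataclass
class JNDResult:
    jnd: float
    state: StaircaseState
    flagged: bool = False
    flag_reason: str = ""


def run_jnd_experiment(subject: SubjectModel, start_level: float = 80.0,
                       step_down: float = 1.0, seed: int | None = None,
                       max_trials: int = 400,
                       max_reversals: int = MAX_REVERSALS) -> JNDResult:
    """Drive the 2IFC observer through the staircase until termination.

    Each trial presents the current perturbation level; the observer's
    choice comes from :func:`myopsych.subject.observe_2ifc`.  Runs that
    exceed ``max_trials`` without reaching the reversal criterion are
    flagged (the JND is then the level of the last logged reversal, or
    NaN if none occurred).
    """
    state = StaircaseState(current_level=start_level, step_down=step_down,
                           max_reversals=max_reversals)
    ss = np.random.SeedSequence(subject.rng_seed if seed is None else seed)
    trial_seeds = ss.generate_state(max_trials)
    for i in range(max_trials):
        if state.terminated:
            break
        correct = observe_2ifc(subject, state.current_level, int(trial_seeds[i]))
        staircase_update(state, correct)
    if not state.terminated:
        jnd = state.reversal_levels[-1] if state.reversal_levels else float("nan")
        return JNDResult(jnd=jnd, state=state, flagged=True,
                         flag_reason=f"max_trials={max_trials} exceeded with "
                                     f"{state.n_reversals} reversals")
    return JNDResult(jnd=staircase_threshold(state), state=state)


def staircase_to_csv(state: StaircaseState, path) -> None:
    """Write the trial-by-trial staircase history (trial, level, response,
    reversal flag) as CSV."""
    import pandas as pd

    pd.DataFrame({
        "trial": np.arange(1, state.trial_count + 1),
        "level": state.levels,
        "correct": np.asarray(state.responses, dtype=int),
        "reversal": np.asarray(state.reversal_flags, dtype=int),
    }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# adaptation rate
# ---------------------------------------------------------------------------

def feedforward_segment(log: TrialLog) -> tuple[float, float]:
    """Mean raw activation per DOF over the 100-230 ms feedforward window.

    The window starts 100 ms after the trial's first rendered tick and
    runs to 230 ms, both endpoints included; it precedes the visuomotor
    delay, so it captures pure feedforward intent.  Trials shorter than
    230 ms are rejected.
    """
    if log.duration + 1e-9 < FF_WINDOW[1]:
        raise ValueError(
            f"trial lasts {log.duration:.3f} s; feedforward analysis needs "
            f">= {FF_WINDOW[1]:.3f} s")
    eps = 1e-9
    mask = (log.t >= FF_WINDOW[0] - eps) & (log.t <= FF_WINDOW[1] + eps)
    if not np.any(mask):
        raise ValueError("no samples inside the feedforward window")
    seg = log.raw[mask]
    return float(seg[:, 0].mean()), float(seg[:, 1].mean())


@dataclass
class AdaptationEstimate:
    rate: float
    n_pairs: int
    flagged: bool = False
    flag_reason: str = ""


def estimate_adaptation_rate(
    data: Sequence[TrialLog] | tuple[np.ndarray, np.ndarray],
    min_pairs: int = 10,
) -> AdaptationEstimate:
    """Least-squares estimate of the trial-to-trial error-correction gain.

    Accepts either an adaptation block of :class:`TrialLog` (the
    off-target DOF-2 feedforward command is measured per trial, and the
    measured command doubles as the observed error since the target error
    is zero on that DOF) or a ``(commands, observed_errors)`` pair from
    :func:`myopsych.subject.simulate_adaptation_series`.

    The rate is the slope β of Δu_n = β·(−e_n): β = 1 means the next
    command fully cancels the previous error.  Trials too short for the
    feedforward window are skipped (their pair is dropped); fewer than
    ``min_pairs`` usable consecutive pairs is an error, and zero error
    variance flags the estimate as undefined.

    For the log-based path the window mean measures the feedforward
    command with controller-noise error that appears (with opposite sign)
    on both sides of the regression, which would bias the naive slope
    toward 1.  The estimator removes this with a method-of-moments
    errors-in-variables correction: the measurement-noise variance of the
    window mean is estimated from the within-window sample variance and
    subtracted from both the covariance and the variance.
    """
    meas_var = 0.0
    if isinstance(data, tuple):
        u, e = np.asarray(data[0], float), np.asarray(data[1], float)
        if u.shape != e.shape or u.ndim != 1:
            raise ValueError("commands and errors must be equal-length 1-D arrays")
        pairs = [(u[i], e[i], u[i + 1]) for i in range(len(u) - 1)]
    else:
        ff: list[float | None] = []
        within_vars: list[float] = []
        for log in data:
            try:
                ff.append(feedforward_segment(log)[1])
            except ValueError:
                ff.append(None)  # skipped, breaks consecutive pairing
                continue
            eps = 1e-9
            mask = (log.t >= FF_WINDOW[0] - eps) & (log.t <= FF_WINDOW[1] + eps)
            seg = log.raw[mask, 1]
            if len(seg) > 1:
                within_vars.append(float(np.var(seg, ddof=1)) / len(seg))
        meas_var = float(np.mean(within_vars)) if within_vars else 0.0
        pairs = [(ff[i], ff[i], ff[i + 1]) for i in range(len(ff) - 1)
                 if ff[i] is not None and ff[i + 1] is not None]
    if len(pairs) < min_pairs:
        raise ValueError(f"need >= {min_pairs} usable consecutive trial pairs, "
                         f"got {len(pairs)}")
    e_prev = np.array([p[1] for p in pairs])
    du = np.array([p[2] - p[0] for p in pairs])
    x = -e_prev
    var = float(np.var(x))
    if var < 1e-18:
        return AdaptationEstimate(rate=float("nan"), n_pairs=len(pairs),
                                  flagged=True, flag_reason="zero error variance")
    cov = float(np.cov(x, du, bias=True)[0, 1])
    flagged, reason = False, ""
    if var - meas_var <= max(1e-18, 0.1 * var):
        # measurement noise dominates the trial-to-trial signal
        flagged, reason = True, "feedforward variance dominated by measurement noise"
        beta = cov / var
    else:
        beta = (cov - meas_var) / (var - meas_var)
    return AdaptationEstimate(rate=float(beta), n_pairs=len(pairs),
                              flagged=flagged, flag_reason=reason)


# ---------------------------------------------------------------------------
# controller noise
# ---------------------------------------------------------------------------

def estimate_controller_noise(segments: Iterable[np.ndarray],
                              tick: float = 0.016,
                              min_duration: float = 1.0) -> float:
    """Pooled SD of raw activation around its per-segment mean.

    ``segments`` are 1-D arrays of raw activation samples recorded while
    the subject holds a steady intent; each must span at least
    ``min_duration`` seconds at the given tick.  The additive-noise model
    makes the SD invariant to the held level.
    """
    devs = []
    for seg in segments:
        seg = np.asarray(seg, dtype=float).ravel()
        if len(seg) * tick < min_duration:
            raise ValueError(
                f"steady segment of {len(seg) * tick:.2f} s is shorter than "
                f"{min_duration:g} s")
        devs.append(seg - seg.mean())
    if not devs:
        raise ValueError("no steady segments provided")
    all_dev = np.concatenate(devs)
    return float(np.sqrt(np.mean(all_dev**2)))


# ---------------------------------------------------------------------------
# internal model uncertainty
# ---------------------------------------------------------------------------

@dataclass
class InternalModelEstimate:
    p_param: float
    P_deg2: float
    R_deg2: float
    saturated: bool = False


def compute_internal_model_uncertainty(
    adaptation_rate: float,
    jnd: float,
    sigma_cntl_hat: float,
    sigma_sens: float = 3.0,
    stimulus_scale: float = STIMULUS_SCALE_DEG,
) -> InternalModelEstimate:
    """Invert the Kalman-gain relation to the internal-model variance.

    The JND fixes the perceptual observer variance
    ``R = (jnd / (√2·z₀.₈₄))²`` (degrees²); controller noise (converted to
    degrees of movement-direction deflection) and the configured sensory
    uncertainty add to the total feedback noise.  The adaptation rate is
    read as the steady-state Kalman gain

        K = P / (P + R + sigma_sens² + sigma_cntl_deg²)

    whose unique non-negative solution is ``P = K·total/(1−K)``.  The
    result is normalised by the stimulus scale:
    ``p_param = P / stimulus_scale²``.  This is the exact inverse of
    :meth:`myopsych.subject.SubjectModel.from_internal_model`, so
    generated ground truth is recoverable.

    A rate ≥ 1 has no finite solution (the model cannot represent
    over-compensation as a Kalman gain); the estimate saturates at
    infinity and is flagged.
    """
    if jnd <= 0:
        raise ValueError("jnd must be positive")
    if sigma_cntl_hat < 0 or sigma_sens < 0:
        raise ValueError("noise inputs must be >= 0")
    if adaptation_rate < 0:
        adaptation_rate = 0.0
    R = (jnd / (math.sqrt(2.0) * Z_084)) ** 2
    total = R + sigma_sens**2 + (sigma_cntl_hat * DEG_PER_ACT) ** 2
    if adaptation_rate >= 1.0:
        return InternalModelEstimate(p_param=float("inf"), P_deg2=float("inf"),
                                     R_deg2=R, saturated=True)
    P = adaptation_rate * total / (1.0 - adaptation_rate)
    return InternalModelEstimate(p_param=P / stimulus_scale**2, P_deg2=P, R_deg2=R)


# ---------------------------------------------------------------------------
# per-subject outcome container
# ---------------------------------------------------------------------------

@dataclass
class OutcomeMeasures:
    """The five outcome measures for one subject under one strategy."""

    adaptation_rate: float
    jnd: float
    p_param: float
    sigma_sens_hat: float
    sigma_cntl_hat: float
    path_efficiency_on: float
    path_efficiency_off: float
    accuracy_on: float
    accuracy_off: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("path_efficiency_on", "path_efficiency_off",
                     "accuracy_on", "accuracy_off"):
            v = getattr(self, name)
            if not math.isnan(v) and not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be a percentage in [0, 100]")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)
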
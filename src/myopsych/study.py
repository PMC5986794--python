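"""End-to-end study orchestration: cohort → blocks → estimators → statistics.

:func:`run_study` simulates the complete protocol for a 24-subject
cohort: each subject, under their assigned strategy, completes a training
block (3×16 targets, 12 s), an adaptation block (80 trials of one
+x-axis target), a JND staircase block, and a performance test (2×16
targets at 1.7 s then 1.4 s).  The five outcome measures are computed per
subject, compared across strategies with the decision-tree statistics,
and the four retest subgroups feed the paired learning-effect tests
(7 outcome series × 4 subgroups = 28 paired t-tests).

Strategy priors encode the feedback structure of the three controllers:
RAW and AUG expose the full raw activation (visually or through audio),
so their subjects carry low perceptual noise and high adaptation gains;
FLT's winner-take-all feedback hides the off-target channel, giving a
shallower psychometric observer and a lower adaptation gain.  All
randomness flows from one master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import summarize
from .psychophysics import (
    OutcomeMeasures,
    compute_internal_model_uncertainty,
    estimate_adaptation_rate,
    estimate_controller_noise,
    run_jnd_experiment,
)
from .stats import (
    SUBGROUP_RETESTS,
    CohortPlan,
    ComparisonResult,
    assign_cohort,
    compare_strategies,
    paired_learning_tests,
)
from .strategies import StrategyConfig
from .subject import SubjectModel
from .task import BlockSpec, TargetLayout, run_block, run_steady_hold

log = logging.getLogger(__name__)

__all__ = ["StrategyPrior", "StudyConfig", "StudyResult", "run_study"]

OUTCOME_COLUMNS = (
    "adaptation_rate", "jnd", "p_param",
    "path_efficiency_on", "path_efficiency_off",
    "accuracy_on", "accuracy_off",
)


@dataclass(frozen=True)
class StrategyPrior:
    """Population distribution of subject parameters under one strategy.

    ``gain_mean``/``gain_sd`` govern the adaptation gain (clipped to
    [0.05, 0.95]); ``slope_mean``/``slope_cv`` the 2IFC psychometric
    slope (lognormal, degrees).  Controller/sensory/motor noise are
    shared across strategies by default.
    """

    gain_mean: float
    gain_sd: float = 0.08
    slope_mean: float = 30.0
    slope_cv: float = 0.15
    sigma_cntl: float = 0.1
    sigma_sens: float = 3.0
    motor_noise: float = 0.02


#: defaults encode "RAW and AUG feedback-rich, FLT feedback-poor"
DEFAULT_PRIORS = {
    "RAW": StrategyPrior(gain_mean=0.60, slope_mean=28.0),
    "FLT": StrategyPrior(gain_mean=0.45, slope_mean=55.0),
    "AUG": StrategyPrior(gain_mean=0.58, slope_mean=29.0),
}


@dataclass
class StudyConfig:
    """Configuration of the full simulated study."""

    priors: dict = field(default_factory=lambda: dict(DEFAULT_PRIORS))
    layout: TargetLayout = field(default_factory=TargetLayout)
    gains: tuple[float, float] = (20.0, 20.0)
    tick: float = 0.016
    staircase_start: float = 80.0
    staircase_step_down: float = 1.0
    initial_ff_bias: float = 0.3
    run_training: bool = True
    #: multiplicative transfer applied to the retest psychometric slope and
    #: (inverse) adaptation gain; 1.0 = no carry-over learning
    retest_transfer: float = 1.0
    stimulus_scale: float = 180.0

    def strategy_config(self, name: str) -> StrategyConfig:
        return StrategyConfig(name=name, gains=self.gains, tick=self.tick)

    def to_yaml(self, path) -> None:
        import yaml

        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        if "priors" in d:
            d["priors"] = {k: StrategyPrior(**v) if isinstance(v, dict) else v
                           for k, v in d["priors"].items()}
        if "layout" in d and isinstance(d["layout"], dict):
            d["layout"] = TargetLayout(**d["layout"])
        if "gains" in d:
            d["gains"] = tuple(d["gains"])
        return cls(**d)


def draw_subject(prior: StrategyPrior, latent: np.ndarray, rng_seed: int,
                 transfer: float = 1.0) -> SubjectModel:
    """Instantiate a subject from a strategy prior and shared latent traits.

    ``latent`` holds two standard-normal per-subject traits (adaptation
    ability, perceptual acuity) that persist across strategies, so a
    retested subject keeps their individuality under the new prior.
    ``transfer`` < 1 models carried-over learning (shallower slope, higher
    gain) at retest.
    """
    gain = float(np.clip(prior.gain_mean + prior.gain_sd * latent[0], 0.05, 0.95))
    gain = float(np.clip(gain / transfer, 0.05, 0.95))
    slope = float(prior.slope_mean * np.exp(prior.slope_cv * latent[1]
                                            - 0.5 * prior.slope_cv**2))
    slope *= transfer
    return SubjectModel(
        sigma_sens=prior.sigma_sens, sigma_cntl=prior.sigma_cntl,
        motor_noise=prior.motor_noise, psychometric_slope=slope,
        adaptation_gain=gain, rng_seed=rng_seed)


@dataclass
class SubjectRun:
    subject_id: str
    strategy: str
    measures: OutcomeMeasures
    exposure: str = "first"  # 'first' | 'retest'


@dataclass
class StudyResult:
    cohort: CohortPlan
    outcomes: pd.DataFrame                  # one row per subject run
    comparisons: dict                       # outcome -> ComparisonResult
    learning: pd.DataFrame                  # 28 paired t-tests
    flags: list = field(default_factory=list)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.outcomes.to_csv(outdir / "outcomes.csv", index=False)
        self.learning.to_csv(outdir / "learning.csv", index=False)
        comp = {k: v.to_dict() for k, v in self.comparisons.items()}
        (outdir / "comparisons.json").write_text(json.dumps(
            {"comparisons": comp, "flags": self.flags,
             "cohort": {"groups": {k: list(v) for k, v in self.cohort.groups.items()},
                        "subgroups": {k: list(v) for k, v in self.cohort.subgroups.items()},
                        "seed": self.cohort.seed}},
            indent=2, default=str))


def run_subject_protocol(subject: SubjectModel, strategy: StrategyConfig,
                         config: StudyConfig, seed: int) -> OutcomeMeasures:
    """One subject × strategy pass through all protocol blocks."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(5)
    flags: list[str] = []

    if config.run_training:
        run_block(subject, strategy, BlockSpec.training(), int(seeds[0]),
                  layout=config.layout)

    adapt_logs = run_block(subject, strategy, BlockSpec.adaptation(),
                           int(seeds[1]), layout=config.layout,
                           initial_ff_bias=config.initial_ff_bias)
    try:
        est = estimate_adaptation_rate(adapt_logs)
        rate = est.rate
        if est.flagged:
            flags.append(f"adaptation: {est.flag_reason}")
    except ValueError as exc:
        rate = float("nan")
        flags.append(f"adaptation: {exc}")

    hold = run_steady_hold(subject, strategy, duration=2.0, seed=int(seeds[2]))
    sigma_cntl_hat = estimate_controller_noise([hold[:, 0]], tick=strategy.tick)

    jnd_res = run_jnd_experiment(subject, start_level=config.staircase_start,
                                 step_down=config.staircase_step_down,
                                 seed=int(seeds[3]))
    if jnd_res.flagged:
        flags.append(f"jnd: {jnd_res.flag_reason}")

    if np.isfinite(rate) and np.isfinite(jnd_res.jnd) and jnd_res.jnd > 0:
        imu = compute_internal_model_uncertainty(
            rate, jnd_res.jnd, sigma_cntl_hat, sigma_sens=subject.sigma_sens,
            stimulus_scale=config.stimulus_scale)
        p_param = imu.p_param
        if imu.saturated:
            flags.append("p_param: adaptation rate >= 1, estimate saturated")
    else:
        p_param = float("nan")
        flags.append("p_param: missing inputs")

    perf_logs = run_block(subject, strategy, BlockSpec.performance(),
                          int(seeds[4]), layout=config.layout)
    perf = summarize(perf_logs, strategy=strategy.name).table

    def perf_mean(metric: str, axis: str) -> float:
        sel = perf[(perf["metric"] == metric) & (perf["axis_class"] == axis)]
        return float(sel["mean"].iloc[0]) if len(sel) else float("nan")

    return OutcomeMeasures(
        adaptation_rate=rate, jnd=jnd_res.jnd, p_param=p_param,
        sigma_sens_hat=subject.sigma_sens, sigma_cntl_hat=sigma_cntl_hat,
        path_efficiency_on=perf_mean("path_efficiency", "on_axis"),
        path_efficiency_off=perf_mean("path_efficiency", "off_axis"),
        accuracy_on=perf_mean("accuracy", "on_axis"),
        accuracy_off=perf_mean("accuracy", "off_axis"),
        flags=flags)


def run_study(config: StudyConfig | None = None, master_seed: int = 0) -> StudyResult:
    """Simulate the full study and run its statistical analysis.

    Deterministic in ``master_seed``: the cohort assignment, every
    subject's latent traits, and every block seed derive from it.
    Flagged estimator failures are recorded and the affected values are
    excluded (dropped as non-finite) from the group statistics.
    """
    config = config or StudyConfig()
    cohort = assign_cohort(master_seed)
    root = np.random.SeedSequence(master_seed)
    flags: list[str] = []

    subject_index = {sid: i for i, sid in
                     enumerate(sid for g in cohort.groups.values() for sid in g)}
    latents = np.random.default_rng(root.generate_state(1)[0]).standard_normal(
        (len(subject_index), 2))

    rows: list[dict] = []

    def one_run(sid: str, strat_name: str, exposure: str, transfer: float) -> None:
        idx = subject_index[sid]
        run_ss = np.random.SeedSequence(
            entropy=master_seed, spawn_key=(idx, 0 if exposure == "first" else 1))
        seeds = run_ss.generate_state(2)
        subject = draw_subject(config.priors[strat_name], latents[idx],
                               rng_seed=int(seeds[0]), transfer=transfer)
        m = run_subject_protocol(subject, config.strategy_config(strat_name),
                                 config, seed=int(seeds[1]))
        for f in m.flags:
            flags.append(f"{sid}/{strat_name}/{exposure}: {f}")
        row = {"subject": sid, "strategy": strat_name, "exposure": exposure}
        row.update({k: v for k, v in m.to_dict().items() if k != "flags"})
        rows.append(row)

    for strat_name, members in cohort.groups.items():
        for sid in members:
            one_run(sid, strat_name, "first", transfer=1.0)
    for sub_name, members in cohort.subgroups.items():
        _, retest_strategy = SUBGROUP_RETESTS[sub_name]
        for sid in members:
            one_run(sid, retest_strategy, "retest", transfer=config.retest_transfer)

    outcomes = pd.DataFrame(rows)
    first = outcomes[outcomes["exposure"] == "first"]

    comparisons: dict[str, ComparisonResult] = {}
    for col in OUTCOME_COLUMNS:
        groups = {s: first.loc[first["strategy"] == s, col].to_numpy()
                  for s in cohort.groups}
        comparisons[col] = compare_strategies(groups, outcome=col)
        flags.extend(f"{col}: {f}" for f in comparisons[col].flags)

    paired: dict[str, tuple[list[float], list[float]]] = {}
    retests = outcomes[outcomes["exposure"] == "retest"]
    for sub_name, members in cohort.subgroups.items():
        for col in OUTCOME_COLUMNS:
            a = [float(first.loc[first["subject"] == sid, col].iloc[0])
                 for sid in members]
            b = [float(retests.loc[retests["subject"] == sid, col].iloc[0])
                 for sid in members]
            paired[f"{sub_name}/{col}"] = (a, b)
    learning = paired_learning_tests(paired)

    return StudyResult(cohort=cohort, outcomes=outcomes,
                       comparisons=comparisons, learning=learning, flags=flags)
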
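# myopsych

Virtual-subject psychophysics for myoelectric prosthesis control.

Myoelectric prostheses are driven by surface EMG from residual muscles.
Regression-based ("raw") controllers expose the user's full 2-DOF
activation, which is rich feedback but noisy control; classifier-like
("filtered") controllers gate everything but the strongest DOF, which is
cleaner control but starves the user's *internal model* — the predictive
model the CNS builds of the plant.  A hybrid strategy keeps the filtered
control but plays the raw activations back as a 4-tone audio stream.
`myopsych` simulates the psychophysical assessment of these three
strategies — **RAW**, **FLT**, and **AUG** — on virtual subjects with
known ground-truth parameters, so every estimator in the pipeline can be
validated against the generator that produced its data.

The package is aimed at researchers in sensorimotor control and
prosthetics who want a testable, fully synthetic stand-in for human
psychophysics: estimator calibration, power exploration, and protocol
design without a cohort.

## What it computes

For each virtual subject the pipeline measures five outcomes:

- **Adaptation rate** β: the slope of the trial-to-trial feedforward
  command change Δu_n against the previous self-generated error −e_n,
  estimated by least squares over an 80-trial block; β = 1 is perfect
  compensation.  Commands are read from the 100–230 ms feedforward
  window of each trial, before visual feedback can act.
- **JND** (degrees): the just-noticeable angular perturbation of the
  cursor mapping, measured by a Kaernbach weighted up-down staircase
  (step_up/step_down = 0.84/0.16 = 5.25) driving a two-interval
  forced-choice observer, P(correct) = Φ(s/(σ√2)); the staircase
  converges at 84 % correct and terminates after 23 reversals.
- **Internal-model uncertainty** P_param: reading the adaptation rate as
  a steady-state Kalman gain K = P/(P + R + σ²_sens + σ²_cntl), with the
  feedback-noise variance R fixed by the JND, and solving for P.
- **Path efficiency** (%): shortest Manhattan path over the L1 path
  travelled, per trial.
- **Accuracy** (%): 1 − (final Manhattan error / optimal Manhattan
  path).

Group comparisons follow a fixed decision tree: Levene's test, then
one-way ANOVA with Tukey/Bonferroni post-hocs (homogeneous variances) or
Welch's ANOVA with Games-Howell (heterogeneous), at α = 0.05; retest
subgroups are analysed with paired t-tests.

## Worked example

```python
from myopsych import SubjectModel, simulate_adaptation_series
from myopsych.psychophysics import (estimate_adaptation_rate,
    run_jnd_experiment, compute_internal_model_uncertainty)

subject = SubjectModel(adaptation_gain=0.6, psychometric_slope=30.0, rng_seed=1)

series = simulate_adaptation_series(subject, n_trials=80, seed=1)
rate = estimate_adaptation_rate(series).rate
jnd = run_jnd_experiment(subject, seed=1).jnd
p = compute_internal_model_uncertainty(rate, jnd, sigma_cntl_hat=0.1).p_param
print(f"adaptation rate = {rate:.3f}")
print(f"JND             = {jnd:.1f} degrees")
print(f"P_param         = {p:.4f}")
```

prints

```
adaptation rate = 0.623
JND             = 38.0 degrees
P_param         = 0.0393
```

The subject was generated with a true adaptation gain of 0.6 and a
psychometric slope of 30°, whose 84 %-correct point is 42.2°: the
estimators recover both to within their sampling noise, and the Kalman
inversion turns them into a normalised internal-model variance.

A full simulated study — 24 subjects in three groups of 8, with
training, adaptation, JND and performance blocks, plus the 4×4 retest
subgroups and all statistics — runs from the command line:

```
myopsych simulate --seed 1 --out run/
myopsych analyze run/ --out results.json
myopsych report results.json
```

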
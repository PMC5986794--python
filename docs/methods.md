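# Methods

This note documents the generative models, estimators and design
choices behind `myopsych`, and what the synthetic validation does and
does not establish about real myoelectric control.

## Virtual subjects

A `SubjectModel` is the ground truth of one simulated participant:

| parameter | meaning | units | default |
|---|---|---|---|
| `adaptation_gain` | trial-to-trial error-correction gain | — | 0.6 |
| `psychometric_slope` | SD of the 2IFC observer's internal noise | degrees | 30 |
| `sigma_sens` | sensory noise on perceived trial error | degrees | 3 |
| `sigma_cntl` | per-tick controller noise per DOF | activation | 0.1 |
| `motor_noise` | between-trial command execution noise | activation | 0.02 |
| `p_param` | internal-model parameter variance (normalised) | — | 0.05 |
| `lapse_rate` | guessing rate of the 2IFC observer | — | 0 |

Angular and activation scales are linked by the small-angle conversion
180/π degrees of movement-direction deflection per unit off-target
activation at unit on-target drive; sensory noise specified in degrees
enters the adaptation update through this conversion.

`SubjectModel.from_internal_model(p_param, R, ...)` constructs a subject
whose gain is the steady-state Kalman gain
K = P/(P + R + σ²_sens + σ²_cntl,deg) with P = p_param·scale², making
the uncertainty estimator's inversion exact by construction.  The
stimulus scale is 180° (angular perturbations of the velocity mapping
are distinguishable up to a half turn).

## EMG generation and decoding

EMG is amplitude-modulated Gaussian noise: each channel's instantaneous
SD is `baseline_noise` plus synergy-weighted rectified activation of the
four signed directions (extension, flexion, abduction, adduction; two
primary channels each, 0.1 cross-talk).  No motor-unit structure,
electrode placement or fatigue is modelled — the downstream features are
amplitude/complexity statistics, so preserving the monotone
activation→amplitude map is what matters, and the model's channel SD is
available in closed form for testing.

The signal chain is 3rd-order 20 Hz high-pass → 2nd-order 57–63 Hz
band-stop → 5th-order 450 Hz low-pass, all Butterworth at 1 kHz,
applied causally in that order (offset and motion artifact removed
before band shaping; zero-phase filtering is available for offline use
but never on the streaming path, which must honour the 16 ms tick).
Features are the Hudgins time-domain set (MAV, WL, ZC, SSC) over 160 ms
windows, hopped 64 ms for training and 16 ms for streaming, with a
configurable ZC/SSC deadband (default 0 in unit tests; a practical
choice is ~3× the baseline-noise estimate).  Decoding is one RBF-kernel
SVR per DOF (C = 10, ε = 0.01, standardised features), outputs clipped
to [−1, 1].

The closed-loop task simulator accepts a trained decoder, but by
default runs with perfect decoding (`model=None`) and represents
decoding error inside the controller-noise term.  This keeps a full
24-subject study in seconds of CPU; the EMG→features→SVR path is
exercised and validated separately (held-out R² ≥ 0.8 on synthetic
ground truth).

## Task engine

The cursor starts at the screen centre; activations map to velocity at
20 px/s per DOF with a 16 ms tick.  RAW moves both DOFs simultaneously;
FLT and AUG gate to the largest |activation| (DOF 1 wins exact ties, a
probability-zero event), so their trajectories are identical by
construction and differ only in feedback.  The audio map is
extension → 500 Hz, flexion → 400 Hz, abduction (up) → 800 Hz,
adduction (down) → 900 Hz, amplitude equal to the raw activation
magnitude.

Subject intent is proportional pursuit — per-DOF activation
(distance)/(gain·τ) with τ = 0.2 s, capped at a submaximal 0.8 — with
additive per-tick controller noise.  Visual feedback acts only after a
230 ms visuomotor delay; before it the command is pure feedforward,
which is what the 100–230 ms analysis window (both endpoints included)
captures.

The target layout is a canonical two-ring set: 8 on-axis targets (±x,
±y at 15 and 25 px) and 8 off-axis targets (quadrant diagonals at the
same radii), acquisition radius 3 px.  Distances are sized so on-axis
targets are acquirable within the 1.7/1.4 s performance limits at the
default gains; far off-axis targets are not reachable sequentially
within 1.4 s, so FLT/AUG time out there — a structural property of
winner-take-all control at fixed gain.  All metrics are
layout-parameterised and, being ratios, insensitive to the radius.

Protocol blocks: training 3×16 targets at 12 s; adaptation 80 trials of
the far +x target; JND staircase; performance 2×16 targets at 1.7 s
then 1.4 s.

## Estimators

**Adaptation rate.**  In the adaptation block the subject carries an
off-target feedforward bias u (initial 0.3) updated each trial as
u ← u − K·(u + ε_sens) + ε_motor.  The estimator regresses the change
in the measured feedforward command on minus the measured error.  The
window mean carries controller-noise measurement error that appears
with opposite signs on both regression sides and would bias the naive
slope toward 1; the estimator applies a method-of-moments
errors-in-variables correction, with the measurement variance estimated
from the within-window sample variance.  If measurement noise consumes
≥ 90 % of the trial-to-trial variance the estimate is flagged.
Calibration: exact at zero noise; mean recovery within ±0.05 across
gains 0–1.2 at n = 80 over 20 seeds.

**JND.**  Weighted up-down staircase, step_down 1° and step_up 5.25°,
start 80°, threshold taken literally as the level at the 23rd reversal
(averaging the last k reversals is available behind a flag).  With
these steps the converged accuracy probes at ≈ 0.83 for the default
observer — the 23rd reversal is always a descending→ascending flip, so
the literal rule sits slightly below the 0.84 equilibrium; the bias is
within the instrument's ±0.03 design tolerance and shrinks with the
step size.  A 400-trial guard flags non-terminating runs.

**Internal-model uncertainty.**  R = (JND/(√2·z₀.₈₄))²; P solves
K = P/(P + R + σ²_sens + σ²_cntl,deg); p_param = P/180².  K ≥ 1 has no
finite solution (over-compensation is outside the Kalman-gain model)
and returns a flagged saturation at infinity; flagged values are
excluded from group statistics.  The inversion is isolated behind one
function so an alternative formula can be swapped in.  Because
f(K) = K/(1−K) is convex and explodes near 1, uncertainty recovery is
validated through the trial-series generator/estimator pair, where the
gain estimate is precise enough for the 20-seed mean to land within
20 % of truth; the noisier full trial-log route is used for the study
itself, where only group contrasts matter.

## Study conditions

Strategy priors encode the feedback structure: RAW and AUG expose raw
activations (visually or as audio), FLT hides the off-target channel.
Defaults: adaptation-gain means 0.60 (RAW), 0.45 (FLT), 0.58 (AUG), SD
0.08; psychometric-slope means 28°, 55°, 29° (lognormal, CV 0.15).
Gains are kept in the moderate range where the Kalman inversion maps
"FLT adapts less *and* perceives worse" to "FLT more uncertain": with
near-unity gains the K/(1−K) factor would dominate R and invert the
uncertainty ordering, which is a known property of this inversion, not
of the subjects.  The simulated cohort therefore reproduces the
*ordering* of group outcomes (FLT: lower adaptation, higher JND, higher
P_param; pooled over replicate studies, n = 40 per strategy), not the
human cohort's printed magnitudes — those reflect human subjects and
the original study's unpublished uncertainty formula.

The retest subgroups rerun the full protocol under the second strategy
with the subject's latent traits held fixed; a multiplicative transfer
factor (default 1.0 = no carry-over) is the hook for modelling learning
effects.  The learning table enumerates 7 outcome series × 4 subgroups
= 28 paired t-tests.

## Known limitations

- FLT and AUG cursor behaviour is identical by construction, so
  performance differences between them (which humans show) cannot arise.
- Under noiseless gated pursuit, path efficiency is exactly 100 % for
  every FLT/AUG trial; degenerate zero-variance groups are flagged and
  the Welch branch is forced.
- The 2IFC observer is stationary and lapse-free by default; no
  learning within a staircase run.
- EMG realism is limited to amplitude modulation; channel count and
  synergy weights are idealised.
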
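"""The three control strategies and their feedback channels.

* **RAW** — raw control with raw feedback: both DOF activations drive the
  cursor simultaneously (regression-like control).
* **FLT** — filtered control with filtered feedback: winner-take-all
  gating keeps only the highest-activated DOF (classifier-like,
  sequential control).
* **AUG** — filtered control with audio-augmented feedback: the cursor
  moves exactly as in FLT, but a 4-tone audio stream carries the full raw
  (ungated) activation of both DOFs.

Audio map (one audibly distinct frequency per signed direction):
extension → 500 Hz, flexion → 400 Hz, abduction → 800 Hz,
adduction → 900 Hz; tone amplitude equals the magnitude of that
direction's raw activation.  FLT and AUG therefore produce identical
cursor trajectories and differ only in the feedback channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import ActivationVector

__all__ = [
    "AudioFrame",
    "StrategyConfig",
    "gate_highest_dof",
    "audio_map",
    "cursor_step",
    "render_audio",
]

#: direction → tone frequency (Hz); "up" on screen is abduction at 800 Hz
AUDIO_FREQS = {
    "extension": 500.0,
    "flexion": 400.0,
    "abduction": 800.0,
    "adduction": 900.0,
}


@dataclass(frozen=True)
class AudioFrame:
    """Tones active during one 16 ms control tick: (frequency Hz, amplitude)."""

    tones: tuple[tuple[float, float], ...] = ()

    def __bool__(self) -> bool:
        return len(self.tones) > 0

    def amplitude_at(self, freq: float) -> float:
        for f, a in self.tones:
            if f == freq:
                return a
        return 0.0


@dataclass(frozen=True)
class StrategyConfig:
    """One control strategy: name, per-DOF velocity gains, control tick."""

    name: str
    gains: tuple[float, float] = (20.0, 20.0)  # pixels/s per unit activation
    tick: float = 0.016                        # s

    def __post_init__(self) -> None:
        if self.name not in ("RAW", "FLT", "AUG"):
            raise ValueError(f"unknown strategy {self.name!r}")
        if any(g <= 0 for g in self.gains):
            raise ValueError("gains must be positive")
        if self.tick <= 0:
            raise ValueError("tick must be positive")

    @property
    def gated(self) -> bool:
        """Whether cursor motion is winner-take-all (FLT and AUG)."""
        return self.name in ("FLT", "AUG")

    @property
    def audio(self) -> bool:
        return self.name == "AUG"


def gate_highest_dof(a: ActivationVector) -> ActivationVector:
    """Winner-take-all gating: keep the DOF with larger |activation|.

    DOF 1 (extension/flexion) wins exact ties — a deterministic rule on a
    probability-zero event under continuous activations.  Idempotent.
    """
    if abs(a.dof1) >= abs(a.dof2):
        return ActivationVector(a.dof1, 0.0)
    return ActivationVector(0.0, a.dof2)


def audio_map(raw: ActivationVector) -> AudioFrame:
    """Map the ungated activation to at most two simultaneous tones.

    Each DOF contributes the tone of its active signed direction with
    amplitude equal to the activation magnitude; zero activations emit no
    tone.  Amplitude is linear in the activation magnitude.
    """
    tones: list[tuple[float, float]] = []
    if raw.dof1 > 0:
        tones.append((AUDIO_FREQS["extension"], raw.dof1))
    elif raw.dof1 < 0:
        tones.append((AUDIO_FREQS["flexion"], -raw.dof1))
    if raw.dof2 > 0:
        tones.append((AUDIO_FREQS["abduction"], raw.dof2))
    elif raw.dof2 < 0:
        tones.append((AUDIO_FREQS["adduction"], -raw.dof2))
    return AudioFrame(tones=tuple(tones))


def cursor_step(pos, a: ActivationVector, cfg: StrategyConfig,
                dt: float | None = None) -> tuple[tuple[float, float], ActivationVector, AudioFrame]:
    """Advance the cursor by one control tick under the given strategy.

    Returns ``(new_pos, effective_activation, audio)`` where the effective
    activation is the raw vector for RAW and the gated vector for FLT/AUG,
    and ``audio`` is the AUG tone frame (empty for RAW and FLT).
    """
    dt = cfg.tick if dt is None else dt
    eff = gate_highest_dof(a) if cfg.gated else a
    new_pos = (pos[0] + cfg.gains[0] * eff.dof1 * dt,
               pos[1] + cfg.gains[1] * eff.dof2 * dt)
    audio = audio_map(a) if cfg.audio else AudioFrame()
    return new_pos, eff, audio


def render_audio(frames, tick: float = 0.016, fs: float = 44100.0) -> np.ndarray:
    """Utility: synthesise an AudioFrame stream as a mono waveform.

    Sums phase-continuous sinusoids at the four map frequencies, holding
    each frame's amplitudes for one tick.  Not part of the control
    pipeline contract; provided for listening to simulated feedback.
    """
    n_per = int(round(tick * fs))
    freqs = sorted(AUDIO_FREQS.values())
    phase = {f: 0.0 for f in freqs}
    out = np.zeros(len(frames) * n_per)
    t = np.arange(n_per) / fs
    for i, frame in enumerate(frames):
        seg = np.zeros(n_per)
        for f in freqs:
            amp = frame.amplitude_at(f)
            if amp > 0:
                seg += amp * np.sin(2 * np.pi * f * t + phase[f])
            phase[f] = (phase[f] + 2 * np.pi * f * tick) % (2 * np.pi)
        out[i * n_per:(i + 1) * n_per] = seg
    return out
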
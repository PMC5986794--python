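"""Shared primitives: the 2-DOF activation vector and unit conventions.

The controlled plant has two wrist degrees of freedom:

* DOF 1 — extension (+) / flexion (−)
* DOF 2 — abduction (+) / adduction (−)

Activations are dimensionless commands in [−1, 1] per DOF.  Screen
coordinates put the origin at screen centre, x rightward (+x = extension)
and y upward (+y = abduction), in pixels.

Angular quantities (sensory noise, JND stimuli) are expressed in degrees.
At unit on-target activation a small off-target activation ``a`` deflects
the movement direction by ``atan(a)``; the small-angle conversion
``DEG_PER_ACT`` degrees per activation unit is used to move noise terms
between the two scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: degrees of movement-direction deflection per unit off-target activation
#: (small-angle linearisation of atan at unit on-target drive)
DEG_PER_ACT: float = 180.0 / math.pi

#: standard normal quantile at 0.84, the staircase's target accuracy point
Z_084: float = 0.9944578832097532  # scipy.stats.norm.ppf(0.84)


def clip_unit(x: float) -> float:
    """Clip a scalar activation to [-1, 1]."""
    return -1.0 if x < -1.0 else (1.0 if x > 1.0 else x)


@dataclass(frozen=True)
class ActivationVector:
    """Signed 2-DOF activation command.

    Parameters
    ----------
    dof1 : float
        Wrist extension (+) / flexion (−) activation in [−1, 1].
    dof2 : float
        Wrist abduction (+) / adduction (−) activation in [−1, 1].

    Components are clipped to [−1, 1] on construction; non-finite values
    are rejected.
    """

    dof1: float
    dof2: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dof1) and math.isfinite(self.dof2)):
            raise ValueError("activation components must be finite")
        object.__setattr__(self, "dof1", clip_unit(float(self.dof1)))
        object.__setattr__(self, "dof2", clip_unit(float(self.dof2)))

    def as_array(self) -> np.ndarray:
        return np.array([self.dof1, self.dof2], dtype=float)

    @classmethod
    def from_array(cls, a) -> "ActivationVector":
        a = np.asarray(a, dtype=float)
        if a.shape != (2,):
            raise ValueError(f"expected shape (2,), got {a.shape}")
        return cls(float(a[0]), float(a[1]))

    def __iter__(self):
        yield self.dof1
        yield self.dof2
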
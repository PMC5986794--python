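"""Performance metrics on trial logs: Manhattan path efficiency and
normalised accuracy, split by on-/off-axis targets.

Both metrics are expressed relative to the shortest Manhattan (L1) path
from the start position to the target centre, making them invariant to
uniform spatial rescaling and insensitive to the acquisition radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .task import Target, TrialLog

__all__ = [
    "manhattan_optimal",
    "path_efficiency",
    "accuracy",
    "summarize",
]


def manhattan_optimal(target: Target) -> float:
    """Shortest Manhattan path length (pixels) from the origin to the target."""
    x, y = target.center
    if x == 0.0 and y == 0.0:
        raise ValueError("target at the start position has no defined optimal path")
    return abs(x) + abs(y)


def path_efficiency(log: TrialLog) -> float:
    """Percentage ratio of the optimal Manhattan path to the path travelled.

    The travelled length is the cumulative Manhattan (L1) length of the
    sampled trajectory, so a wasted-motion-free L-shaped path scores
    exactly 100%.  Capped at 100 (a numerical safeguard: an undershooting
    trial can sample less length than the optimum).  A trial that never
    moved scores 0.
    """
    if log.n_samples < 2:
        raise ValueError("path efficiency needs >= 2 samples")
    steps = np.abs(np.diff(log.pos, axis=0)).sum()
    if steps == 0.0:
        return 0.0
    return float(min(100.0, 100.0 * manhattan_optimal(log.target) / steps))


def accuracy(log: TrialLog) -> float:
    """Normalised accuracy (%): 1 minus the final Manhattan error over the
    optimal Manhattan path, floored at 0.

    The final point is the last sample of the trial, at acquisition or
    timeout.
    """
    if log.n_samples < 1:
        raise ValueError("accuracy needs >= 1 sample")
    fx, fy = log.pos[-1]
    tx, ty = log.target.center
    err = abs(fx - tx) + abs(fy - ty)
    return float(max(0.0, 100.0 * (1.0 - err / manhattan_optimal(log.target))))


@dataclass
class PerformanceSummary:
    """Tidy per-group aggregate of the two performance metrics."""

    table: pd.DataFrame  # subject, strategy, axis_class, metric, mean, sd, sem, n

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def summarize(logs: Sequence[TrialLog], subject: str = "s01",
              strategy: str | None = None) -> PerformanceSummary:
    """Aggregate path efficiency and accuracy by axis class.

    Trials with fewer than 2 samples are excluded from the aggregates.
    Groups with no usable trials are omitted with a warning.  The result
    is order-invariant.
    """
    rows = []
    for axis in ("on_axis", "off_axis"):
        group = [lg for lg in logs if lg.target.axis_class == axis and lg.n_samples >= 2]
        if not group:
            if any(lg.target.axis_class == axis for lg in logs):
                warnings.warn(f"group {axis!r} has no trials with >= 2 samples; omitted")
            continue
        strat = strategy or group[0].strategy
        for metric, fn in (("path_efficiency", path_efficiency), ("accuracy", accuracy)):
            vals = np.array([fn(lg) for lg in group])
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            rows.append({
                "subject": subject, "strategy": strat, "axis_class": axis,
                "metric": metric, "mean": float(vals.mean()), "sd": sd,
                "sem": sd / np.sqrt(len(vals)) if len(vals) > 1 else 0.0,
                "n": len(vals),
            })
    return PerformanceSummary(table=pd.DataFrame(rows))
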